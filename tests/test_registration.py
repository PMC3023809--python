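"""Landmark registration: rigid/affine/TPS fitting, resampling, the full
register pipeline, and the backend registry."""

import math

import numpy as np
import pytest

from atlaskit import registration as reg
from atlaskit import synthetic_fixtures as sf
from atlaskit.errors import BackendError, DegeneracyError, ValidationError
from atlaskit.registration import LandmarkSet, TransformModel
from atlaskit.volume_io import Image2D


def _random_rigid(rng):
    th = rng.uniform(-np.pi, np.pi)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    t = rng.uniform(-20, 20, size=2)
    return np.hstack([R, t[:, None]])


def _random_affine(rng):
    while True:
        A = rng.uniform(-2, 2, size=(2, 2))
        if abs(np.linalg.det(A)) > 0.1:
            return np.hstack([A, rng.uniform(-20, 20, size=(2, 1))])


def _apply(matrix, pts):
    return pts @ matrix[:, :2].T + matrix[:, 2]


# ---------------------------------------------------------------------------
# Rigid
# ---------------------------------------------------------------------------

def test_rigid_identity_on_equal_points(rng):
    pts = rng.uniform(0, 50, size=(6, 2))
    model = reg.fit_rigid(LandmarkSet(pts, pts))
    assert np.allclose(model.matrix[:, :2], np.eye(2), atol=1e-12)
    assert np.allclose(model.matrix[:, 2], 0, atol=1e-10)


def test_rigid_recovers_exact_90_degrees():
    src = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    R = np.array([[0.0, -1.0], [1.0, 0.0]])
    model = reg.fit_rigid(LandmarkSet(src, src @ R.T))
    assert model.rotation_degrees == pytest.approx(90.0, abs=1e-9)
    assert reg.landmark_residual(model, LandmarkSet(src, src @ R.T)) < 1e-12


def test_rigid_affine_recover_100_random_noise_free_transforms():
    rng = np.random.default_rng(42)
    for _ in range(100):
        src = rng.uniform(0, 100, size=(8, 2))
        rigid_truth = _random_rigid(rng)
        m = reg.fit_rigid(LandmarkSet(src, _apply(rigid_truth, src)))
        assert np.allclose(m.matrix, rigid_truth, atol=1e-9)
        affine_truth = _random_affine(rng)
        m = reg.fit_affine(LandmarkSet(src, _apply(affine_truth, src)))
        assert np.allclose(m.matrix, affine_truth, atol=1e-9)


def test_rigid_noisy_vs_grid_search_oracle():
    """The closed-form angle beats (or ties) a brute-force grid search over
    rotation angles at 0.1 degree resolution."""
    rng = np.random.default_rng(5)
    th = math.radians(30.0)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    src = rng.uniform(0, 100, size=(20, 2))
    tgt = src @ R.T + np.array([3.0, -2.0]) + rng.normal(0, 0.1, size=(20, 2))
    lm = LandmarkSet(src, tgt)
    model = reg.fit_rigid(lm)
    assert model.rotation_degrees == pytest.approx(30.0, abs=1.0)

    def residual_at_angle(deg):
        a = math.radians(deg)
        Ra = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        t = tgt.mean(axis=0) - Ra @ src.mean(axis=0)
        return np.sqrt(((src @ Ra.T + t - tgt) ** 2).sum(axis=1).mean())

    grid_best = min(residual_at_angle(d) for d in np.arange(0.0, 360.0, 0.1))
    assert reg.landmark_residual(model, lm) <= grid_best + 1e-12


def test_rigid_validation_and_degeneracy():
    with pytest.raises(ValidationError):
        reg.fit_rigid(LandmarkSet([[0, 0]], [[1, 1]]))
    same = np.tile([[2.0, 3.0]], (4, 1))
    with pytest.raises(DegeneracyError):
        reg.fit_rigid(LandmarkSet(same, np.arange(8.0).reshape(4, 2)))


# ---------------------------------------------------------------------------
# Affine
# ---------------------------------------------------------------------------

def test_affine_recovers_shear_exactly():
    src = np.array([[0, 0], [10, 0], [0, 10], [10, 10], [3, 7]], dtype=float)
    shear = np.array([[1.0, 0.5, 0.0], [0.0, 1.0, 0.0]])
    model = reg.fit_affine(LandmarkSet(src, _apply(shear, src)))
    assert np.allclose(model.matrix, shear, atol=1e-9)


def test_affine_collinear_sources_rejected():
    src = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
    with pytest.raises(DegeneracyError):
        reg.fit_affine(LandmarkSet(src, src))


def test_affine_least_squares_local_optimality():
    """On an overdetermined noisy system, no random perturbation of the
    solution achieves a lower residual."""
    rng = np.random.default_rng(9)
    src = rng.uniform(0, 50, size=(30, 2))
    truth = _random_affine(rng)
    tgt = _apply(truth, src) + rng.normal(0, 0.5, size=src.shape)
    lm = LandmarkSet(src, tgt)
    model = reg.fit_affine(lm)
    base = reg.landmark_residual(model, lm)
    for _ in range(1000):
        perturbed = TransformModel(
            "affine", model.matrix + rng.normal(0, 1e-3, size=(2, 3)))
        assert reg.landmark_residual(perturbed, lm) >= base - 1e-12


def test_rigid_residual_never_below_affine_residual():
    rng = np.random.default_rng(17)
    for _ in range(20):
        src = rng.uniform(0, 50, size=(10, 2))
        tgt = src + rng.normal(0, 2.0, size=src.shape)
        lm = LandmarkSet(src, tgt)
        assert (reg.landmark_residual(reg.fit_rigid(lm), lm)
                >= reg.landmark_residual(reg.fit_affine(lm), lm) - 1e-12)


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

def test_tps_interpolates_landmarks_exactly():
    rng = np.random.default_rng(13)
    src = rng.uniform(0, 60, size=(12, 2))
    tgt = src + rng.normal(0, 4.0, size=src.shape)
    model = reg.fit_tps(LandmarkSet(src, tgt), lam=0.0)
    assert np.abs(model.transform_points(src) - tgt).max() < 1e-6


def test_tps_side_conditions_hold():
    rng = np.random.default_rng(13)
    src = rng.uniform(0, 60, size=(10, 2))
    tgt = src + rng.normal(0, 3.0, size=src.shape)
    model = reg.fit_tps(LandmarkSet(src, tgt), lam=0.0)
    P = np.hstack([np.ones((10, 1)), src])
    assert np.abs(P.T @ model.weights).max() < 1e-8


def test_tps_degenerates_to_affine_on_affine_data():
    rng = np.random.default_rng(21)
    src = rng.uniform(0, 50, size=(9, 2))
    truth = _random_affine(rng)
    lm = LandmarkSet(src, _apply(truth, src))
    model = reg.fit_tps(lm, lam=0.0)
    assert np.linalg.norm(model.weights) < 1e-6
    assert np.allclose(model.matrix, truth, atol=1e-6)


def test_tps_large_lambda_approaches_affine():
    rng = np.random.default_rng(23)
    # a unit-scale landmark domain, so the tested regularization values
    # sweep from negligible to dominant relative to the kernel magnitude
    src = rng.uniform(0, 8, size=(15, 2))
    tgt = src + rng.normal(0, 0.5, size=src.shape)
    lm = LandmarkSet(src, tgt)
    affine = reg.fit_affine(lm)
    grid = np.array([(x, y) for x in np.linspace(1, 7, 7)
                     for y in np.linspace(1, 7, 7)])
    gaps = []
    for lam in (0.1, 10.0, 1000.0):
        model = reg.fit_tps(lm, lam=lam)
        gaps.append(np.abs(model.transform_points(grid)
                           - affine.transform_points(grid)).max())
    assert gaps[0] > gaps[1] > gaps[2]
    assert gaps[2] < 0.1


def test_tps_rejects_duplicates_and_negative_lambda():
    src = np.array([[0, 0], [1, 1], [0, 0]], dtype=float)
    with pytest.raises(DegeneracyError):
        reg.fit_tps(LandmarkSet(src, src + 1))
    good = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
    with pytest.raises(ValidationError):
        reg.fit_tps(LandmarkSet(good, good), lam=-1.0)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def test_apply_identity_transform_is_identity(rng):
    img = Image2D(rng.uniform(size=(5, 5)))
    ident = TransformModel("rigid", np.hstack([np.eye(2), np.zeros((2, 1))]))
    out = reg.apply_transform(img, ident)
    assert np.allclose(out.pixels, img.pixels)


def test_apply_translation_nearest_shifts_columns(rng):
    img = Image2D(rng.uniform(size=(5, 5)))
    shift = TransformModel("rigid", np.array([[1.0, 0.0, 3.0], [0.0, 1.0, 0.0]]))
    out = reg.apply_transform(img, shift, interpolation="nearest")
    assert np.allclose(out.pixels[:, 3:], img.pixels[:, :2])
    assert np.all(out.pixels[:, :3] == 0)


def test_apply_rotation_matches_per_pixel_remap_oracle():
    rng = np.random.default_rng(6)
    img = Image2D(rng.uniform(size=(5, 5)))
    c = 2.0  # rotate 90 degrees about the image center
    R = np.array([[0.0, -1.0], [1.0, 0.0]])
    t = np.array([c, c]) - R @ np.array([c, c])
    model = TransformModel("rigid", np.hstack([R, t[:, None]]))
    out = reg.apply_transform(img, model, interpolation="nearest")
    inv = model.inverse_matrix()
    oracle = np.zeros((5, 5))
    for y in range(5):
        for x in range(5):
            sx, sy = inv[:, :2] @ [x, y] + inv[:, 2]
            sxi, syi = int(round(sx)), int(round(sy))
            if 0 <= sxi < 5 and 0 <= syi < 5:
                oracle[y, x] = img.pixels[syi, sxi]
    assert np.allclose(out.pixels, oracle)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def test_register_identity_landmarks_returns_source(rng):
    img = Image2D(rng.uniform(size=(8, 8)))
    pts = np.array([[1, 1], [6, 1], [1, 6], [6, 6]], dtype=float)
    result = reg.register(img, img, LandmarkSet(pts, pts), "rigid")
    assert np.allclose(result.aligned.pixels, img.pixels)
    assert result.residual < 1e-12
    assert result.n_landmarks == 4


def test_register_translated_copy_recovers_template():
    spec = sf.FixtureSpec(seed=2)
    template = sf._template_image(spec, size=32)
    shift = TransformModel("rigid", np.array([[1.0, 0.0, 4.0], [0.0, 1.0, 2.0]]))
    inv = TransformModel("rigid", shift.inverse_matrix())
    source = reg.apply_transform(template, inv, template.shape)
    corners = np.array([[6, 6], [25, 6], [6, 25], [25, 25]], dtype=float)
    lm = LandmarkSet(corners, shift.transform_points(corners))
    result = reg.register(source, template, lm, "rigid")
    interior = np.s_[8:24, 8:24]
    mae = np.abs(result.aligned.pixels[interior] - template.pixels[interior]).mean()
    assert mae < 0.01


def test_register_tps_warp_brings_landmarks_home():
    spec = sf.FixtureSpec(seed=4)
    source, template, lm, truth = sf.make_warped_pair(spec, "tps", magnitude=2.0,
                                                      size=48, n_grid=3)
    result = reg.register(source, template, lm, "tps", lam=0.0)
    assert result.residual < 1e-6  # forward spline interpolates the 9 landmarks
    # reverse-warp consistency: template landmarks map back onto source ones
    reverse = reg.fit_tps(LandmarkSet(lm.template, lm.source), lam=0.0)
    assert np.abs(reverse.transform_points(lm.template) - lm.source).max() < 0.5


# ---------------------------------------------------------------------------
# Backend registry
# ---------------------------------------------------------------------------

def test_landmark_warp_backend_preregistered():
    assert "landmark_warp" in reg.list_backends()


def test_backend_roundtrip_and_errors(rng):
    img = Image2D(rng.uniform(size=(4, 4)))

    stub = reg.RegistrationBackend(name="stub", align=lambda s, t, o: (None, s))
    reg.register_backend(stub)
    try:
        _, out = reg.invoke_backend("stub", img, img)
        assert np.array_equal(out.pixels, img.pixels)
        with pytest.raises(BackendError):
            reg.register_backend(reg.RegistrationBackend(name="stub",
                                                         align=stub.align))
    finally:
        reg._REGISTRY.pop("stub", None)

    with pytest.raises(BackendError, match="landmark_warp"):
        reg.invoke_backend("no-such-backend", img, img)

    def crash(s, t, o):
        raise RuntimeError("internal failure")

    reg.register_backend(reg.RegistrationBackend(name="crashy", align=crash))
    try:
        with pytest.raises(BackendError, match="crashy"):
            reg.invoke_backend("crashy", img, img)
    finally:
        reg._REGISTRY.pop("crashy", None)


def test_landmark_file_roundtrip(tmp_path, rng):
    lm = LandmarkSet(rng.uniform(0, 50, (5, 2)), rng.uniform(0, 50, (5, 2)))
    p = tmp_path / "lm.txt"
    reg.write_landmarks(lm, p)
    back = reg.read_landmarks(p)
    assert np.allclose(back.source, lm.source)
    assert np.allclose(back.template, lm.template)
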