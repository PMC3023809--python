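"""Landmark-based 2D alignment: rigid, affine, and thin-plate spline.

Landmarks are (source, template) point pairs in image pixel coordinates
``(x, y) = (column, row)``.  The fitted map sends source coordinates to
template coordinates.

* **Rigid** — least-squares rotation + translation via the closed-form
  SVD solution on the centered cross-covariance (2D orthogonal Procrustes
  with the determinant corrected to +1).
* **Affine** — least-squares 2x3 matrix; exact when the pairs are generated
  by an affine map.
* **Thin-plate spline (TPS)** — the standard 2D biharmonic spline with
  kernel ``U(r) = r^2 log(r^2)`` (``U(0) = 0``), solved as a dense bordered
  system.  The side conditions make the kernel weights orthogonal to the
  constant and coordinate functions; regularization ``lambda >= 0`` trades
  landmark fidelity for smoothness: ``lambda = 0`` interpolates exactly and
  ``lambda -> inf`` approaches the affine fit.

Resampling for linear models inverts the fitted map; a TPS warp has no
closed-form inverse, so for resampling a reverse-direction spline (template
to source) is fitted and evaluated directly on the output grid.

Backends are pluggable: algorithms register by name behind a minimal
contract (source, template, options in; transform and aligned image out).
A built-in ``landmark_warp`` backend provides the three models above.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import ndimage

from .errors import BackendError, DegeneracyError, ValidationError
from .volume_io import Image2D

__all__ = [
    "LandmarkSet",
    "TransformModel",
    "RegistrationResult",
    "RegistrationBackend",
    "fit_rigid",
    "fit_affine",
    "fit_tps",
    "apply_transform",
    "register",
    "register_backend",
    "list_backends",
    "invoke_backend",
    "read_landmarks",
    "write_landmarks",
]


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Paired source/template points, each (n, 2) float arrays of (x, y)."""

    source: np.ndarray
    template: np.ndarray

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.template = np.atleast_2d(np.asarray(self.template, dtype=float))
        if self.source.shape != self.template.shape or self.source.shape[1] != 2:
            raise ValidationError(
                f"landmarks must be matching (n, 2) arrays, got "
                f"{self.source.shape} vs {self.template.shape}"
            )

    def __len__(self) -> int:
        return len(self.source)


def read_landmarks(path: str | os.PathLike) -> LandmarkSet:
    """Read a plain-text landmark table: one ``xs ys xt yt`` pair per line,
    ``#`` starts a comment."""
    rows = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        vals = [float(v) for v in ln.split()]
        if len(vals) != 4:
            raise ValidationError(f"landmark line needs 4 numbers, got {ln!r}")
        rows.append(vals)
    arr = np.asarray(rows, dtype=float)
    if arr.size == 0:
        raise ValidationError(f"no landmark pairs in {path}")
    return LandmarkSet(source=arr[:, :2], template=arr[:, 2:])


def write_landmarks(landmarks: LandmarkSet, path: str | os.PathLike) -> Path:
    lines = ["# xs ys xt yt"]
    for (xs, ys), (xt, yt) in zip(landmarks.source, landmarks.template):
        lines.append(f"{xs:.10g} {ys:.10g} {xt:.10g} {yt:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


# ---------------------------------------------------------------------------
# Transform models
# ---------------------------------------------------------------------------

@dataclass
class TransformModel:
    """A fitted source-to-template map.

    ``kind`` is ``rigid``, ``affine`` or ``tps``.  Linear kinds store a 2x3
    matrix ``[A | t]``; TPS additionally stores the landmark anchors, per-
    landmark kernel weights and the regularization used.
    """

    kind: str
    matrix: np.ndarray                       # (2, 3): [A | t]
    anchors: np.ndarray | None = None        # (n, 2), TPS only
    weights: np.ndarray | None = None        # (n, 2), TPS only
    lam: float = 0.0

    def transform_points(self, pts: np.ndarray) -> np.ndarray:
        """Map (m, 2) source-space points to template space."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = pts @ self.matrix[:, :2].T + self.matrix[:, 2]
        if self.kind == "tps":
            out = out + _tps_kernel(pts, self.anchors) @ self.weights
        return out

    @property
    def rotation_degrees(self) -> float:
        """Rotation angle of the linear part (meaningful for rigid fits)."""
        return float(np.degrees(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))

    def inverse_matrix(self) -> np.ndarray:
        """Inverse 2x3 matrix for linear kinds."""
        A = self.matrix[:, :2]
        t = self.matrix[:, 2]
        det = np.linalg.det(A)
        if abs(det) < 1e-12:
            raise DegeneracyError("transform matrix is singular and cannot be inverted")
        Ainv = np.linalg.inv(A)
        return np.hstack([Ainv, (-Ainv @ t)[:, None]])


@dataclass
class RegistrationResult:
    """A fitted model plus the aligned image and provenance numbers."""

    model: TransformModel
    aligned: Image2D
    residual: float           # RMS landmark error in template space (px)
    n_landmarks: int
    model_kind: str


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_rigid(landmarks: LandmarkSet) -> TransformModel:
    """Least-squares rotation + translation minimizing
    ``sum ||R s_i + t - t_i||^2`` (closed form via the SVD of the centered
    cross-covariance, determinant forced to +1)."""
    if len(landmarks) < 2:
        raise ValidationError(f"rigid fit needs >= 2 pairs, got {len(landmarks)}")
    S, T = landmarks.source, landmarks.template
    cs, ct = S.mean(axis=0), T.mean(axis=0)
    S0, T0 = S - cs, T - ct
    if np.allclose(S0, 0):
        raise DegeneracyError("all source landmarks coincide; rotation is undefined")
    H = S0.T @ T0
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = ct - R @ cs
    return TransformModel(kind="rigid", matrix=np.hstack([R, t[:, None]]))


def fit_affine(landmarks: LandmarkSet) -> TransformModel:
    """Least-squares 2x3 affine map; exact on affine-consistent pairs."""
    if len(landmarks) < 3:
        raise ValidationError(f"affine fit needs >= 3 pairs, got {len(landmarks)}")
    S, T = landmarks.source, landmarks.template
    X = np.hstack([S, np.ones((len(S), 1))])
    if np.linalg.matrix_rank(X) < 3:
        raise DegeneracyError("source landmarks are collinear; affine fit is rank-deficient")
    coef, *_ = np.linalg.lstsq(X, T, rcond=None)
    return TransformModel(kind="affine", matrix=coef.T)


def _tps_kernel(pts: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    d2 = ((pts[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = d2 * np.log(d2)
    K[d2 == 0] = 0.0
    return K


def fit_tps(landmarks: LandmarkSet, lam: float = 0.0) -> TransformModel:
    """Thin-plate spline with kernel ``U(r) = r^2 log(r^2)``.

    Solves the bordered system ``[[K + lam*I, P], [P^T, 0]]`` so the kernel
    weights satisfy the side conditions (orthogonal to constants and
    coordinates).  ``lam = 0`` interpolates the landmarks exactly.
    """
    if len(landmarks) < 3:
        raise ValidationError(f"TPS fit needs >= 3 pairs, got {len(landmarks)}")
    if lam < 0:
        raise ValidationError(f"TPS regularization must be >= 0, got {lam}")
    S, T = landmarks.source, landmarks.template
    n = len(S)
    d2 = ((S[:, None, :] - S[None, :, :]) ** 2).sum(axis=2)
    if np.any(d2[np.triu_indices(n, 1)] == 0):
        raise DegeneracyError("duplicate source landmarks make the TPS system singular")
    K = _tps_kernel(S, S) + lam * np.eye(n)
    P = np.hstack([np.ones((n, 1)), S])
    L = np.zeros((n + 3, n + 3))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = T
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegeneracyError(f"TPS system is singular: {exc}") from exc
    w = sol[:n]
    a = sol[n:]  # rows: [const; x; y] coefficients per output dim
    A = np.vstack([a[1], a[2]]).T  # (2, 2) linear part: rows are output dims
    matrix = np.hstack([A, a[0][:, None]])
    return TransformModel(kind="tps", matrix=matrix, anchors=S.copy(), weights=w, lam=lam)


_FITTERS: dict[str, Callable] = {
    "rigid": lambda lm, **kw: fit_rigid(lm),
    "affine": lambda lm, **kw: fit_affine(lm),
    "tps": lambda lm, **kw: fit_tps(lm, kw.get("lam", 0.0)),
}


def landmark_residual(model: TransformModel, landmarks: LandmarkSet) -> float:
    """RMS distance between mapped source landmarks and template landmarks."""
    mapped = model.transform_points(landmarks.source)
    return float(np.sqrt(((mapped - landmarks.template) ** 2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _sample(image: Image2D, src_xy: np.ndarray, out_shape: tuple[int, int],
            interpolation: str) -> np.ndarray:
    order = {"nearest": 0, "bilinear": 1}.get(interpolation)
    if order is None:
        raise ValidationError(f"interpolation must be 'nearest' or 'bilinear', got {interpolation!r}")
    coords = np.stack([src_xy[:, 1], src_xy[:, 0]])  # (row, col)
    px = image.pixels
    if px.ndim == 2:
        out = ndimage.map_coordinates(px, coords, order=order, mode="constant", cval=0.0)
        return out.reshape(out_shape)
    chans = [
        ndimage.map_coordinates(px[:, :, c], coords, order=order, mode="constant", cval=0.0)
        .reshape(out_shape)
        for c in range(px.shape[2])
    ]
    return np.dstack(chans)


def apply_transform(
    image: Image2D,
    transform: TransformModel,
    output_shape: tuple[int, int] | None = None,
    interpolation: str = "bilinear",
) -> Image2D:
    """Resample ``image`` (source space) into template space.

    For linear models each output pixel ``p`` is sampled at
    ``transform^-1(p)``.  A ``tps`` model passed here must be the
    reverse-direction (template-to-source) spline, which is evaluated
    directly at the output grid — a forward TPS has no closed-form inverse.
    """
    out_shape = tuple(output_shape) if output_shape else image.shape
    h, w = out_shape
    ys, xs = np.mgrid[0:h, 0:w]
    grid = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    if transform.kind == "tps":
        src_xy = transform.transform_points(grid)
    else:
        inv = transform.inverse_matrix()
        src_xy = grid @ inv[:, :2].T + inv[:, 2]
    return Image2D(
        pixels=np.clip(_sample(image, src_xy, (h, w), interpolation), 0.0, 1.0),
        pixel_size=image.pixel_size,
    )


def register(
    source: Image2D,
    template: Image2D,
    landmarks: LandmarkSet,
    model_kind: str = "affine",
    interpolation: str = "bilinear",
    lam: float = 0.0,
) -> RegistrationResult:
    """Fit the requested model on the landmarks and resample the source into
    the template geometry; the result carries the model kind, RMS landmark
    residual and landmark count for provenance."""
    if model_kind not in _FITTERS:
        raise ValidationError(
            f"model_kind must be one of {sorted(_FITTERS)}, got {model_kind!r}"
        )
    model = _FITTERS[model_kind](landmarks, lam=lam)
    if model_kind == "tps":
        # reverse-direction spline for direct resampling on the template grid
        reverse = fit_tps(LandmarkSet(landmarks.template, landmarks.source), lam=lam)
        aligned = apply_transform(source, reverse, template.shape, interpolation)
    else:
        aligned = apply_transform(source, model, template.shape, interpolation)
    return RegistrationResult(
        model=model,
        aligned=aligned,
        residual=landmark_residual(model, landmarks),
        n_landmarks=len(landmarks),
        model_kind=model_kind,
    )


# ---------------------------------------------------------------------------
# Backend registry
# ---------------------------------------------------------------------------

@dataclass
class RegistrationBackend:
    """A pluggable registration algorithm.

    The core imposes only the call contract: ``align(source, template,
    options) -> (TransformModel | None, Image2D)``.  Anything may happen
    behind it (native code, remote execution, ...).
    """

    name: str
    align: Callable[[Image2D, Image2D, dict], tuple[TransformModel | None, Image2D]]
    capabilities: dict = field(default_factory=lambda: {"dims": "2D-2D", "models": []})


_REGISTRY: dict[str, RegistrationBackend] = {}


def register_backend(backend: RegistrationBackend) -> None:
    if backend.name in _REGISTRY:
        raise BackendError(f"backend {backend.name!r} is already registered")
    _REGISTRY[backend.name] = backend


def list_backends() -> list[str]:
    return sorted(_REGISTRY)


def invoke_backend(name: str, source: Image2D, template: Image2D, options: dict | None = None):
    if name not in _REGISTRY:
        raise BackendError(
            f"unknown backend {name!r}; available backends: {list_backends()}"
        )
    try:
        return _REGISTRY[name].align(source, template, options or {})
    except BackendError:
        raise
    except Exception as exc:
        raise BackendError(f"backend {name!r} failed: {exc}") from exc


def _landmark_warp_align(source: Image2D, template: Image2D, options: dict):
    landmarks = options.get("landmarks")
    if landmarks is None:
        raise ValidationError("landmark_warp backend requires options['landmarks']")
    result = register(
        source, template, landmarks,
        model_kind=options.get("model_kind", "affine"),
        interpolation=options.get("interpolation", "bilinear"),
        lam=options.get("lam", 0.0),
    )
    return result.model, result.aligned


register_backend(RegistrationBackend(
    name="landmark_warp",
    align=_landmark_warp_align,
    capabilities={"dims": "2D-2D", "models": ["rigid", "affine", "tps"]},
))
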