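"""Volume and 2D image I/O, orthogonal slicing, and out-of-core streaming.

3D volumes are read and written through nibabel in NIfTI-1 (``.nii`` /
``.nii.gz``) and Analyze 7.5 (``.hdr``/``.img``) formats.  Only the
permutation/flip part of a NIfTI orientation matrix is honored: voxel sizes
come from the header zooms and the origin from the affine translation;
oblique resampling is out of scope.

2D images (PNG/TIFF/JPEG) are loaded through Pillow and normalized to
``[0, 1]`` floats.

Large volumes can be opened out of core: slices are streamed from disk on
demand under a bounded LRU cache whose unit is one whole plane along the
file's fastest-varying (contiguous) axis.  Raw volumes use a small text
descriptor (``.lvol``) naming dtype, shape and the data file; uncompressed
NIfTI files are also supported directly.
"""

from __future__ import annotations

import os
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .errors import BoundsError, ConfigurationError, FormatError, ValidationError

__all__ = [
    "ImageVolume",
    "Image2D",
    "ImageSeries",
    "SliceSpec",
    "OutOfCoreVolume",
    "read_volume",
    "write_volume",
    "read_image2d",
    "read_series",
    "extract_slice",
    "reorient",
    "voxel_to_world",
    "world_to_voxel",
    "open_large_volume",
    "write_lvol",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageVolume:
    """A 3D scalar volume with voxel geometry.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units); any scalar dtype.
    voxel_size
        Physical voxel extent along each array axis, in mm; all > 0.
    origin
        World position (mm) of the *center* of voxel (0, 0, 0).
    axis_labels
        Three orientation codes for the array axes (e.g. ``('R','A','S')``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(
                f"volume data must be 3D with all dims >= 1, got shape {self.data.shape}"
            )
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValidationError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        self.voxel_size = vs
        self.origin = tuple(float(v) for v in self.origin)
        self.axis_labels = tuple(self.axis_labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def value_range(self) -> tuple[float, float]:
        """Actual (min, max) of the data; recomputed so it survives mutation."""
        return float(self.data.min()), float(self.data.max())


@dataclass
class Image2D:
    """A 2D image: grayscale ``(h, w)`` or ``(h, w, c)`` with c in {3, 4}.

    Pixel values live in ``[0, 1]``; any adjustment clamps back into range.
    """

    pixels: np.ndarray
    pixel_size: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 3 and self.pixels.shape[2] not in (3, 4):
            raise ValidationError(
                f"channel count must be 1, 3 or 4, got {self.pixels.shape[2]}"
            )
        if self.pixels.ndim not in (2, 3):
            raise ValidationError(f"pixels must be 2D or 3D, got ndim={self.pixels.ndim}")
        ps = tuple(float(v) for v in self.pixel_size)
        if any(v <= 0 for v in ps):
            raise ValidationError(f"pixel_size must be positive, got {self.pixel_size}")
        self.pixel_size = ps

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass
class ImageSeries:
    """An ordered stack of same-shaped 2D frames with a current index."""

    frames: list[Image2D]
    current_index: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("series must contain at least one frame")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValidationError(f"series frames differ in shape: {sorted(shapes)}")
        if not (0 <= self.current_index < len(self.frames)):
            raise BoundsError(
                f"current_index {self.current_index} out of range [0, {len(self.frames)})"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def current(self) -> Image2D:
        return self.frames[self.current_index]


@dataclass(frozen=True)
class SliceSpec:
    """An orthogonal slice: array ``axis`` in {0,1,2} and 0-based ``index``."""

    axis: int
    index: int

    def __post_init__(self) -> None:
        if self.axis not in (0, 1, 2):
            raise ValidationError(f"axis must be 0, 1 or 2, got {self.axis}")


# ---------------------------------------------------------------------------
# Volume file I/O (nibabel)
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_ANALYZE_SUFFIXES = (".hdr", ".img")


def _geometry_from_affine(affine: np.ndarray, zooms) -> tuple[tuple, tuple, tuple]:
    """Extract voxel size, origin and axis codes, honoring only the
    permutation/flip part of the affine (oblique terms are dropped)."""
    voxel_size = tuple(float(abs(z)) for z in zooms[:3])
    origin = tuple(float(v) for v in affine[:3, 3])
    try:
        labels = tuple(nib.aff2axcodes(affine))
    except Exception:
        labels = ("R", "A", "S")
    return voxel_size, origin, labels


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI-1 or Analyze 7.5 volume, preserving the stored dtype."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise FormatError(f"unrecognized volume format: {path} ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim > 3:
        data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume in {path}, got shape {data.shape}")
    voxel_size, origin, labels = _geometry_from_affine(img.affine, img.header.get_zooms())
    return ImageVolume(data=data, voxel_size=voxel_size, origin=origin, axis_labels=labels)


def write_volume(volume: ImageVolume, path: str | os.PathLike, format: str | None = None) -> Path:
    """Write a volume as NIfTI (``nifti``) or Analyze 7.5 (``analyze``).

    When ``format`` is None it is inferred from the path suffix.  Round-trips
    with :func:`read_volume` bit-exactly for integer and float32 dtypes.
    """
    path = Path(path)
    if format is None:
        name = path.name.lower()
        if name.endswith(_NIFTI_SUFFIXES):
            format = "nifti"
        elif name.endswith(_ANALYZE_SUFFIXES):
            format = "analyze"
        else:
            raise ValidationError(f"cannot infer volume format from suffix of {path}")
    if format not in ("nifti", "analyze"):
        raise ValidationError(f"format must be 'nifti' or 'analyze', got {format!r}")

    affine = np.diag(list(volume.voxel_size) + [1.0])
    affine[:3, 3] = volume.origin
    data = volume.data
    if data.dtype == np.float64:  # NIfTI stores float64 fine, Analyze prefers float32
        data = data if format == "nifti" else data.astype(np.float32)
    if format == "nifti":
        img = nib.Nifti1Image(data, affine)
    else:
        img = nib.AnalyzeImage(data, affine)
    img.header.set_zooms(volume.voxel_size)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# 2D image I/O (Pillow)
# ---------------------------------------------------------------------------

def read_image2d(path: str | os.PathLike, pixel_size: tuple[float, float] = (1.0, 1.0)) -> Image2D:
    """Read a PNG/TIFF/JPEG image, normalized to ``[0, 1]`` floats."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(float) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(arr.astype(float), 0.0, 1.0)
    else:
        info = np.iinfo(arr.dtype)
        arr = (arr.astype(float) - info.min) / (info.max - info.min)
    if arr.ndim == 3 and arr.shape[2] == 2:  # LA -> drop alpha-less combos to gray+alpha
        arr = np.dstack([arr[:, :, 0]] * 3 + [arr[:, :, 1]])
    return Image2D(pixels=arr, pixel_size=pixel_size)


def read_series(paths: list[str | os.PathLike]) -> ImageSeries:
    """Read an ordered list of images as a cine series; all must share shape."""
    frames = [read_image2d(p) for p in paths]
    shapes = [f.shape for f in frames]
    ref = shapes[0]
    offenders = [str(p) for p, s in zip(paths, shapes) if s != ref]
    if offenders:
        raise ValidationError(
            f"series frames must share shape {ref}; mismatched: {', '.join(offenders)}"
        )
    return ImageSeries(frames=frames)


def write_image2d(image: Image2D, path: str | os.PathLike) -> Path:
    """Write an image to PNG (or any Pillow-supported suffix) as 8-bit."""
    arr = np.clip(image.pixels, 0.0, 1.0)
    arr8 = np.round(arr * 255.0).astype(np.uint8)
    Image.fromarray(arr8).save(str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# Slicing, reorientation, coordinates
# ---------------------------------------------------------------------------

def _check_slice(shape: tuple[int, int, int], spec: SliceSpec) -> None:
    if not (0 <= spec.index < shape[spec.axis]):
        raise BoundsError(
            f"slice index {spec.index} out of range for axis {spec.axis} "
            f"(limit {shape[spec.axis]})"
        )


def _normalize_plane(plane: np.ndarray, value_range: tuple[float, float]) -> np.ndarray:
    lo, hi = value_range
    plane = plane.astype(float)
    if hi > lo:
        return (plane - lo) / (hi - lo)
    return np.zeros_like(plane)


def extract_slice(volume: ImageVolume | "OutOfCoreVolume", spec: SliceSpec) -> Image2D:
    """Extract the orthogonal plane at ``spec``, rescaled to [0,1] by the
    volume's *global* value range (stable across cine navigation)."""
    if isinstance(volume, OutOfCoreVolume):
        return volume.extract_slice(spec)
    _check_slice(volume.shape, spec)
    plane = np.take(volume.data, spec.index, axis=spec.axis)
    rest = [volume.voxel_size[a] for a in range(3) if a != spec.axis]
    return Image2D(
        pixels=_normalize_plane(plane, volume.value_range),
        pixel_size=(rest[0], rest[1]),
    )


def extract_slice_raw(volume: ImageVolume, spec: SliceSpec) -> np.ndarray:
    """The un-normalized plane (original dtype); used for label volumes."""
    _check_slice(volume.shape, spec)
    return np.take(volume.data, spec.index, axis=spec.axis)


def reorient(
    volume: ImageVolume,
    axis_permutation: tuple[int, int, int],
    flips: tuple[bool, bool, bool] = (False, False, False),
) -> ImageVolume:
    """Permute and/or flip the array axes; geometry metadata follows.

    ``axis_permutation[new_axis] = old_axis``; ``flips`` apply per new axis.
    """
    perm = tuple(int(a) for a in axis_permutation)
    if sorted(perm) != [0, 1, 2]:
        raise ValidationError(f"axis_permutation must be a permutation of (0,1,2), got {perm}")
    if len(flips) != 3:
        raise ValidationError("flips must be 3 booleans")
    data = np.transpose(volume.data, perm)
    for ax, f in enumerate(flips):
        if f:
            data = np.flip(data, axis=ax)
    return ImageVolume(
        data=np.ascontiguousarray(data),
        voxel_size=tuple(volume.voxel_size[a] for a in perm),
        origin=volume.origin,
        axis_labels=tuple(volume.axis_labels[a] for a in perm),
    )


def voxel_to_world(volume, ijk) -> np.ndarray:
    """World position (mm) of a voxel center: ``origin + ijk * voxel_size``."""
    ijk = np.asarray(ijk, dtype=float)
    return np.asarray(volume.origin) + ijk * np.asarray(volume.voxel_size)


def world_to_voxel(volume, xyz) -> tuple[np.ndarray, bool]:
    """Nearest voxel index for a world point, plus an in-bounds flag."""
    xyz = np.asarray(xyz, dtype=float)
    cont = (xyz - np.asarray(volume.origin)) / np.asarray(volume.voxel_size)
    ijk = np.round(cont).astype(int)
    in_bounds = bool(np.all(ijk >= 0) and np.all(ijk < np.asarray(volume.shape)))
    return ijk, in_bounds


# ---------------------------------------------------------------------------
# Out-of-core volumes
# ---------------------------------------------------------------------------

@dataclass
class _LargeHeader:
    dtype: np.dtype
    shape: tuple[int, int, int]
    order: str               # 'F' or 'C' layout of the data file
    data_path: Path
    data_offset: int = 0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def plane_axis(self) -> int:
        """The axis whose planes are contiguous on disk: axis 2 for
        Fortran layout, axis 0 for C layout."""
        return 2 if self.order == "F" else 0

    @property
    def plane_shape(self) -> tuple[int, int]:
        s = self.shape
        return (s[0], s[1]) if self.plane_axis == 2 else (s[1], s[2])

    @property
    def plane_bytes(self) -> int:
        return int(np.prod(self.plane_shape)) * self.dtype.itemsize


class OutOfCoreVolume:
    """A volume streamed plane-by-plane from disk under an LRU byte budget.

    Any read is bit-identical to an in-memory load of the same file; the
    resident cache never exceeds ``cache_budget`` bytes.  ``disk_reads``
    counts on-demand plane fetches (cache misses) so tests can observe
    hit/miss behavior.
    """

    def __init__(self, header: _LargeHeader, cache_budget: int):
        if cache_budget < header.plane_bytes:
            raise ConfigurationError(
                f"cache_budget {cache_budget} is smaller than one plane "
                f"({header.plane_bytes} bytes)"
            )
        self.header = header
        self.cache_budget = int(cache_budget)
        self._cache: OrderedDict[int, np.ndarray] = OrderedDict()
        self.disk_reads = 0
        self._fh = open(header.data_path, "rb")
        self._value_range = self._scan_value_range()

    # -- geometry passthrough so coordinate ops work uniformly
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.header.shape

    @property
    def voxel_size(self):
        return self.header.voxel_size

    @property
    def origin(self):
        return self.header.origin

    @property
    def value_range(self) -> tuple[float, float]:
        return self._value_range

    @property
    def max_cached_planes(self) -> int:
        return self.cache_budget // self.header.plane_bytes

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- plane cache ------------------------------------------------------
    def _read_plane_from_disk(self, index: int) -> np.ndarray:
        h = self.header
        self._fh.seek(h.data_offset + index * h.plane_bytes)
        buf = self._fh.read(h.plane_bytes)
        if len(buf) != h.plane_bytes:
            raise FormatError(f"truncated data file {h.data_path} at plane {index}")
        flat = np.frombuffer(buf, dtype=h.dtype)
        # a contiguous plane block is itself laid out in the file's order
        return flat.reshape(h.plane_shape, order=h.order)

    def _get_plane(self, index: int) -> np.ndarray:
        if index in self._cache:
            self._cache.move_to_end(index)
            return self._cache[index]
        plane = self._read_plane_from_disk(index)
        self.disk_reads += 1
        self._cache[index] = plane
        while len(self._cache) * self.header.plane_bytes > self.cache_budget:
            self._cache.popitem(last=False)
        return plane

    def _scan_value_range(self) -> tuple[float, float]:
        n_planes = self.shape[self.header.plane_axis]
        lo, hi = np.inf, -np.inf
        for i in range(n_planes):
            p = self._read_plane_from_disk(i)
            lo = min(lo, float(p.min()))
            hi = max(hi, float(p.max()))
        return lo, hi

    # -- slicing ----------------------------------------------------------
    def _plane_as_volume_plane(self, index: int) -> np.ndarray:
        """The cached plane, oriented as data.take(index, axis=plane_axis)."""
        return self._get_plane(index)

    def extract_slice(self, spec: SliceSpec) -> Image2D:
        _check_slice(self.shape, spec)
        plane = self.read_slice_raw(spec)
        rest = [self.voxel_size[a] for a in range(3) if a != spec.axis]
        return Image2D(
            pixels=_normalize_plane(plane, self._value_range),
            pixel_size=(rest[0], rest[1]),
        )

    def read_slice_raw(self, spec: SliceSpec) -> np.ndarray:
        """The raw plane at ``spec`` (original dtype), streamed through the
        plane cache.  Slices orthogonal to the cached plane axis are
        assembled one cached plane at a time."""
        _check_slice(self.shape, spec)
        pax = self.header.plane_axis
        if spec.axis == pax:
            return self._plane_as_volume_plane(spec.index).copy()
        n_planes = self.shape[pax]
        rows = []
        for i in range(n_planes):
            plane = self._plane_as_volume_plane(i)
            # plane has the two non-pax axes in ascending order
            if pax == 2:
                # plane: (dim0, dim1); requested axis is 0 or 1
                rows.append(plane[spec.index, :] if spec.axis == 0 else plane[:, spec.index])
            else:
                # pax == 0 -> plane: (dim1, dim2); requested axis is 1 or 2
                rows.append(plane[spec.index, :] if spec.axis == 1 else plane[:, spec.index])
        stacked = np.stack(rows, axis=-1 if pax == 2 else 0)
        if pax == 0:
            return stacked  # (n_planes=dim0, other) with axis order preserved
        return stacked

    def load_full(self) -> np.ndarray:
        """Materialize the whole array (oracle/debug path; bypasses budget)."""
        pax = self.header.plane_axis
        planes = [self._read_plane_from_disk(i) for i in range(self.shape[pax])]
        return np.stack(planes, axis=pax)


def write_lvol(
    path: str | os.PathLike,
    data: np.ndarray,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> Path:
    """Write a raw large-volume pair: ``<path>`` text descriptor + ``.dat``
    data file in Fortran order (axis-2 planes contiguous)."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValidationError(f"lvol data must be 3D, got shape {data.shape}")
    data_path = path.with_suffix(".dat")
    data.flatten(order="F").tofile(data_path)
    lines = [
        "lvol 1",
        f"dtype: {data.dtype.name}",
        f"shape: {data.shape[0]} {data.shape[1]} {data.shape[2]}",
        "order: F",
        f"data: {data_path.name}",
        f"voxel_size: {voxel_size[0]} {voxel_size[1]} {voxel_size[2]}",
        f"origin: {origin[0]} {origin[1]} {origin[2]}",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_lvol(path: Path) -> _LargeHeader:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("lvol"):
        raise FormatError(f"not an lvol descriptor: {path}")
    fields: dict[str, str] = {}
    for ln in lines[1:]:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        key, _, val = ln.partition(":")
        fields[key.strip()] = val.strip()
    try:
        shape = tuple(int(v) for v in fields["shape"].split())
        dtype = np.dtype(fields["dtype"])
        order = fields.get("order", "F")
        data_path = path.parent / fields["data"]
        voxel_size = tuple(float(v) for v in fields.get("voxel_size", "1 1 1").split())
        origin = tuple(float(v) for v in fields.get("origin", "0 0 0").split())
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed lvol descriptor {path}: {exc}") from exc
    if order not in ("F", "C"):
        raise FormatError(f"lvol order must be F or C, got {order!r}")
    if not data_path.exists():
        raise FileNotFoundError(f"lvol data file not found: {data_path}")
    return _LargeHeader(
        dtype=dtype, shape=shape, order=order, data_path=data_path,
        voxel_size=voxel_size, origin=origin,
    )


def _nifti_large_header(path: Path) -> _LargeHeader:
    img = nib.load(str(path))
    if path.name.endswith(".gz"):
        raise FormatError("out-of-core access requires an uncompressed .nii file")
    hdr = img.header
    slope, inter = hdr.get_slope_inter()
    if (slope not in (None, 1.0)) or (inter not in (None, 0.0)):
        raise FormatError("out-of-core NIfTI with intensity scaling is not supported")
    voxel_size, origin, _ = _geometry_from_affine(img.affine, hdr.get_zooms())
    return _LargeHeader(
        dtype=np.dtype(hdr.get_data_dtype()),
        shape=tuple(int(s) for s in hdr.get_data_shape()[:3]),
        order="F",  # NIfTI data block is Fortran-ordered
        data_path=path,
        data_offset=int(img.dataobj.offset),
        voxel_size=voxel_size,
        origin=origin,
    )


def open_large_volume(path: str | os.PathLike, cache_budget: int) -> OutOfCoreVolume:
    """Open a volume for on-demand streaming from disk.

    Supports the ``.lvol`` raw descriptor and uncompressed ``.nii`` files.
    ``cache_budget`` is in bytes and must hold at least one plane.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"large volume not found: {path}")
    if path.suffix == ".lvol":
        header = _parse_lvol(path)
    elif path.name.endswith(".nii"):
        header = _nifti_large_header(path)
    else:
        raise FormatError(f"unsupported out-of-core format: {path}")
    return OutOfCoreVolume(header, cache_budget)
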