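"""Layer-based compositing onto a virtual canvas.

The canvas renders an ordered bottom-to-top stack of layers.  Every layer
can be panned, rotated, scaled, made (in)visible, and photometrically
adjusted (opacity, brightness, contrast, optional color lookup table).
Layers can be linked into master/slave groups: transform actions applied to
the master are mirrored by every slave, while slave-initiated actions move
only the slave.

Rendering is a pure function of canvas state.  Each visible layer is
resampled into canvas space by inverse-mapped bilinear sampling under its
transform (scale, then rotation about the layer center, then pan), with
transparent out-of-bounds, then blended with the straight-alpha *over*
operator:  C <- C_layer * a_eff + C * (1 - a_eff), a_eff = opacity * sample
alpha.  A dual-view mode composites two disjoint layer subsets side by side
for juxtaposition.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .volume_io import Image2D, ImageSeries, write_image2d

__all__ = [
    "LayerTransform",
    "Layer",
    "Canvas",
    "adjust_photometry",
    "apply_lut",
    "transform_layer",
    "composite",
    "dual_view",
    "step_cine",
    "save_scene",
    "load_scene",
    "export_png",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LayerTransform:
    """Pan (canvas px), rotation (degrees CCW) and uniform scale.

    Composition order is fixed: scale, then rotate about the layer image
    center, then pan.
    """

    pan: tuple[float, float] = (0.0, 0.0)
    rotation: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError(f"scale must be positive, got {self.scale}")
        self.pan = (float(self.pan[0]), float(self.pan[1]))

    def copy(self) -> "LayerTransform":
        return LayerTransform(pan=self.pan, rotation=self.rotation, scale=self.scale)


@dataclass
class Layer:
    """One composited layer: content + transform + photometric state."""

    content: Image2D | ImageSeries
    name: str = "layer"
    transform: LayerTransform = field(default_factory=LayerTransform)
    opacity: float = 1.0
    brightness: float = 0.0
    contrast: float = 1.0
    lut: np.ndarray | None = None  # (256, 3) ints 0-255
    visible: bool = True
    link_group: str | None = None
    is_master: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.opacity <= 1.0):
            raise ValidationError(f"opacity must be in [0,1], got {self.opacity}")
        if not (-1.0 <= self.brightness <= 1.0):
            raise ValidationError(f"brightness must be in [-1,1], got {self.brightness}")
        if self.contrast <= 0:
            raise ValidationError(f"contrast must be > 0, got {self.contrast}")
        if self.lut is not None:
            self.lut = np.asarray(self.lut)
            if self.lut.shape != (256, 3):
                raise ValidationError(f"lut must have shape (256,3), got {self.lut.shape}")

    @property
    def image(self) -> Image2D:
        return self.content.current if isinstance(self.content, ImageSeries) else self.content

    def adjusted_rgba(self) -> np.ndarray:
        """The layer image after photometry + LUT, as (h, w, 4) straight RGBA
        with alpha 1 inside the image (an existing alpha channel is kept)."""
        img = self.image
        px = img.pixels
        if px.ndim == 2:
            adj = _photometry(px, self.brightness, self.contrast)
            if self.lut is not None:
                rgb = _lut_lookup(adj, self.lut)
            else:
                rgb = np.dstack([adj] * 3)
            alpha = np.ones(adj.shape)
        else:
            rgb = _photometry(px[:, :, :3], self.brightness, self.contrast)
            if self.lut is not None:
                gray = rgb.mean(axis=2)
                rgb = _lut_lookup(gray, self.lut)
            alpha = px[:, :, 3] if px.shape[2] == 4 else np.ones(px.shape[:2])
        return np.dstack([rgb, alpha])


@dataclass
class Canvas:
    """An ordered bottom-to-top layer stack rendered at a fixed pixel size."""

    size: tuple[int, int]  # (width, height)
    layers: list[Layer] = field(default_factory=list)
    background_color: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def layer_by_name(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(f"no layer named {name!r} (have {[l.name for l in self.layers]})")

    def group_members(self, group: str) -> list[Layer]:
        return [l for l in self.layers if l.link_group == group]


# ---------------------------------------------------------------------------
# Photometry and LUTs
# ---------------------------------------------------------------------------

def _photometry(values: np.ndarray, brightness: float, contrast: float) -> np.ndarray:
    # mid-gray pivot: out = clamp(contrast*(in - 0.5) + 0.5 + brightness)
    return np.clip(contrast * (values - 0.5) + 0.5 + brightness, 0.0, 1.0)


def adjust_photometry(image: Image2D, brightness: float = 0.0, contrast: float = 1.0) -> Image2D:
    """Brightness/contrast about a mid-gray pivot, clamped to [0,1]:
    ``out = clamp(contrast * (in - 0.5) + 0.5 + brightness, 0, 1)``."""
    if contrast <= 0:
        raise ValidationError(f"contrast must be > 0, got {contrast}")
    px = image.pixels
    if px.ndim == 3 and px.shape[2] == 4:
        out = np.dstack([_photometry(px[:, :, :3], brightness, contrast), px[:, :, 3]])
    else:
        out = _photometry(px, brightness, contrast)
    return Image2D(pixels=out, pixel_size=image.pixel_size)


def _lut_lookup(gray: np.ndarray, lut: np.ndarray) -> np.ndarray:
    idx = np.clip(np.round(gray * 255.0).astype(int), 0, 255)
    return lut[idx].astype(float) / 255.0


def apply_lut(image: Image2D, lut: np.ndarray) -> Image2D:
    """Map grayscale values through a 256-entry RGB table:
    ``out = lut[round(v * 255)] / 255``."""
    lut = np.asarray(lut)
    if lut.shape != (256, 3):
        raise ValidationError(f"lut must have 256 RGB entries, got shape {lut.shape}")
    px = image.pixels
    gray = px if px.ndim == 2 else px[:, :, :3].mean(axis=2)
    return Image2D(pixels=_lut_lookup(gray, lut), pixel_size=image.pixel_size)


# ---------------------------------------------------------------------------
# Transforms and linking
# ---------------------------------------------------------------------------

def _apply_delta(t: LayerTransform, delta: dict) -> LayerTransform:
    pan = t.pan
    if "pan" in delta:
        pan = (pan[0] + float(delta["pan"][0]), pan[1] + float(delta["pan"][1]))
    rotation = t.rotation + float(delta.get("rotate", 0.0))
    scale = t.scale * float(delta.get("scale", 1.0))
    return LayerTransform(pan=pan, rotation=rotation, scale=scale)


def transform_layer(canvas: Canvas, layer_name: str, delta: dict) -> None:
    """Apply a pan/rotate/scale delta to a layer.

    ``delta`` keys: ``pan`` (dx, dy), ``rotate`` (degrees, additive),
    ``scale`` (factor, multiplicative).  If the layer is the *master* of a
    link group, the identical delta is mirrored to every group member;
    slave-initiated deltas move only the slave.
    """
    target = canvas.layer_by_name(layer_name)
    unknown = set(delta) - {"pan", "rotate", "scale"}
    if unknown:
        raise ValidationError(f"unknown transform delta keys: {sorted(unknown)}")
    if target.link_group is not None and target.is_master:
        members = canvas.group_members(target.link_group)
    else:
        members = [target]
    for layer in members:
        layer.transform = _apply_delta(layer.transform, delta)


def step_cine(layer: Layer, delta: int) -> int:
    """Advance a series layer's frame index by ``delta``, clamped to the
    valid range; returns the new index."""
    if not isinstance(layer.content, ImageSeries):
        raise ValidationError(f"layer {layer.name!r} has no image series content")
    series = layer.content
    series.current_index = max(0, min(len(series) - 1, series.current_index + delta))
    return series.current_index


# ---------------------------------------------------------------------------
# Compositing
# ---------------------------------------------------------------------------

def _inverse_map_coords(
    transform: LayerTransform, canvas_shape: tuple[int, int], layer_shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Layer-space (row, col) coordinates for every canvas pixel under the
    inverse of (scale -> rotate about layer center -> pan)."""
    h, w = canvas_shape
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    cy = (layer_shape[0] - 1) / 2.0
    cx = (layer_shape[1] - 1) / 2.0
    # forward: p' = R S (p - c) + c + pan  =>  p = S^-1 R^-1 (p' - c - pan) + c
    dx = xs - cx - transform.pan[0]
    dy = ys - cy - transform.pan[1]
    th = math.radians(transform.rotation)
    ct, st = math.cos(th), math.sin(th)
    # inverse rotation (CCW by -th in image coords with y down)
    rx = ct * dx + st * dy
    ry = -st * dx + ct * dy
    return ry / transform.scale + cy, rx / transform.scale + cx


def _bilinear_sample_rgba(rgba: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear sampling of straight RGBA with transparent out-of-bounds."""
    h, w = rgba.shape[:2]
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    out = np.zeros(rows.shape + (4,), dtype=float)
    for dr in (0, 1):
        for dc in (0, 1):
            rr = r0 + dr
            cc = c0 + dc
            weight = (fr if dr else 1 - fr) * (fc if dc else 1 - fc)
            inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            rri = np.clip(rr, 0, h - 1)
            cci = np.clip(cc, 0, w - 1)
            vals = rgba[rri, cci] * (weight * inside)[..., None]
            out += vals
    return out


def alpha_over(top: np.ndarray, bottom: np.ndarray) -> np.ndarray:
    """Straight-alpha *over* of two (h, w, 4) rasters (associative)."""
    a_t = top[:, :, 3:]
    a_b = bottom[:, :, 3:]
    a_out = a_t + a_b * (1.0 - a_t)
    color = top[:, :, :3] * a_t + bottom[:, :, :3] * a_b * (1.0 - a_t)
    safe = np.where(a_out > 0, a_out, 1.0)
    return np.dstack([color / safe, a_out])


def composite(canvas: Canvas) -> np.ndarray:
    """Render the canvas to an (h, w, 4) float RGBA raster.

    Starts from the opaque background color, then for each visible layer
    bottom-to-top resamples its adjusted image into canvas space and applies
    the straight-alpha over operator.  Deterministic: identical canvas state
    yields a bit-identical raster.
    """
    w, h = canvas.size
    out = np.empty((h, w, 4), dtype=float)
    out[:, :, :3] = np.asarray(canvas.background_color, dtype=float)
    out[:, :, 3] = 1.0
    for layer in canvas.layers:
        if not layer.visible or layer.opacity == 0.0:
            continue
        rgba = layer.adjusted_rgba()
        rows, cols = _inverse_map_coords(layer.transform, (h, w), rgba.shape[:2])
        sample = _bilinear_sample_rgba(rgba, rows, cols)
        a_eff = (layer.opacity * sample[:, :, 3])[..., None]
        out[:, :, :3] = sample[:, :, :3] * a_eff + out[:, :, :3] * (1.0 - a_eff)
        out[:, :, 3:] = a_eff + out[:, :, 3:] * (1.0 - a_eff)
    return out


def dual_view(canvas: Canvas, left_names: list[str], right_names: list[str]) -> np.ndarray:
    """Two half-width composites side by side, each rendering only its own
    (disjoint) layer subset."""
    overlap = set(left_names) & set(right_names)
    if overlap:
        raise ValidationError(f"dual-view layer subsets overlap: {sorted(overlap)}")
    w, h = canvas.size
    half = w // 2

    def sub(names: list[str]) -> np.ndarray:
        layers = [canvas.layer_by_name(n) for n in names]
        return composite(Canvas(size=(half, h), layers=layers,
                                background_color=canvas.background_color))

    return np.concatenate([sub(left_names), sub(right_names)], axis=1)


def export_png(raster: np.ndarray, path: str | os.PathLike) -> Path:
    """Write a float RGBA raster to an 8-bit PNG."""
    return write_image2d(Image2D(pixels=np.clip(raster, 0, 1)), path)


# ---------------------------------------------------------------------------
# Scene serialization
# ---------------------------------------------------------------------------

def save_scene(canvas: Canvas, path: str | os.PathLike, image_paths: dict[str, str]) -> Path:
    """Serialize canvas state (layers, transforms, adjustments) to YAML.

    ``image_paths`` maps layer names to the image files backing them, so a
    scene can be re-rendered reproducibly from disk.
    """
    doc = {
        "size": list(canvas.size),
        "background_color": list(canvas.background_color),
        "layers": [],
    }
    for layer in canvas.layers:
        doc["layers"].append({
            "name": layer.name,
            "image": image_paths.get(layer.name),
            "pan": list(layer.transform.pan),
            "rotation": layer.transform.rotation,
            "scale": layer.transform.scale,
            "opacity": layer.opacity,
            "brightness": layer.brightness,
            "contrast": layer.contrast,
            "visible": layer.visible,
            "link_group": layer.link_group,
            "is_master": layer.is_master,
        })
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
    return Path(path)


def load_scene(path: str | os.PathLike) -> Canvas:
    """Rebuild a canvas from a scene file (images loaded from their paths)."""
    from .volume_io import read_image2d

    doc = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent
    layers = []
    for entry in doc.get("layers", []):
        img_path = Path(entry["image"])
        if not img_path.is_absolute():
            img_path = base / img_path
        layers.append(Layer(
            content=read_image2d(img_path),
            name=entry["name"],
            transform=LayerTransform(
                pan=tuple(entry.get("pan", (0, 0))),
                rotation=entry.get("rotation", 0.0),
                scale=entry.get("scale", 1.0),
            ),
            opacity=entry.get("opacity", 1.0),
            brightness=entry.get("brightness", 0.0),
            contrast=entry.get("contrast", 1.0),
            visible=entry.get("visible", True),
            link_group=entry.get("link_group"),
            is_master=entry.get("is_master", False),
        ))
    return Canvas(
        size=tuple(doc["size"]),
        layers=layers,
        background_color=tuple(doc.get("background_color", (0, 0, 0))),
    )
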