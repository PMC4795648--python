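"""Synthetic face stimuli and the transforms used by the three experiments.

Faces are schematic: six anti-aliased geometric parts (two brows, two eyes,
a nose ridge and a mouth) drawn inside an 80x120 px oval centered on a
256x256 black field. Identity is carried by Gaussian jitter of part
positions, sizes and intensities. After drawing, in-oval pixels are
normalized to a common mean and variance so that no identity is
distinguishable by global pixel statistics; the background stays exactly 0.

Transforms: top/bottom composites with a 2 px gap (aligned or horizontally
misaligned), attentional down-weighting with optional recentering, vertical
inversion, and whole/part eye-region blends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .config import PartDistribution, StimulusConfig

__all__ = [
    "PartSpec",
    "FaceSpec",
    "StimulusImage",
    "generate_identity",
    "generate_identities",
    "render",
    "make_composite",
    "apply_attention",
    "invert",
    "make_whole_part_pair",
    "crop_to_region",
    "shift_image",
    "save_png",
    "load_png",
    "load_image_directory",
]


@dataclass(frozen=True)
class PartSpec:
    """One rendered part: an ellipse at (cy, cx) with semi-axes (ry, rx)."""

    cy: float
    cx: float
    ry: float
    rx: float
    intensity: float


@dataclass(frozen=True)
class FaceSpec:
    identity_id: int
    parts: Dict[str, PartSpec]
    oval: Tuple[float, float, float, float]  # (cy, cx, ry, rx)
    norm_mean: float
    norm_std: float
    #: identity-specific multi-scale albedo fields: list of (grid, rel_amp)
    #: pairs, each grid bilinearly upsampled at render time
    texture: Optional[list] = None
    texture_amp: float = 0.0
    #: radial darkening toward the oval boundary (intensity units)
    shading: float = 0.0


@dataclass
class StimulusImage:
    """A 256x256 grayscale image in [0, 1] plus provenance metadata."""

    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def copy(self) -> "StimulusImage":
        return StimulusImage(self.pixels.copy(), json.loads(json.dumps(self.meta)))

    @property
    def shape(self):
        return self.pixels.shape


def _rng_for_identity(identity_id: int, seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, identity_id]))


def generate_identity(
    identity_id: int, seed: int, config: Optional[StimulusConfig] = None
) -> FaceSpec:
    """Draw one identity's part parameters; deterministic in (identity, seed).

    Every part receives independent Gaussian jitter on position, semi-axes
    and intensity, so two identities differ (almost surely) in both the top
    half (eyes/brows) and the bottom half (nose/mouth).
    """
    if identity_id < 0:
        raise ValueError("identity_id must be >= 0")
    config = config or StimulusConfig()
    rng = _rng_for_identity(identity_id, seed)
    cy, cx = config.oval_center
    ory, orx = config.oval_semi_axes
    lam = (
        float(np.exp(rng.normal(0.0, config.distinctiveness_sigma)))
        if config.distinctiveness_sigma > 0
        else 1.0
    )
    parts: Dict[str, PartSpec] = {}
    for name in sorted(config.parts):
        dist: PartDistribution = config.parts[name]
        # rejection-sample until the part lies inside the oval, so any
        # jitter scale yields a valid spec; deterministic per identity RNG
        for attempt in range(200):
            dy = dist.dy + lam * rng.normal(0.0, dist.pos_sd)
            dx = dist.dx + lam * rng.normal(0.0, dist.pos_sd)
            ry = max(1.0, dist.ry + lam * rng.normal(0.0, dist.size_sd))
            rx = max(1.0, dist.rx + lam * rng.normal(0.0, dist.size_sd))
            if _bbox_inside_oval(cy + dy, cx + dx, ry, rx, cy, cx, ory, orx):
                break
        else:
            raise ValueError(
                f"part {name!r}: no in-oval placement found; check part "
                f"layout against the oval geometry"
            )
        inten = float(
            np.clip(dist.intensity + lam * rng.normal(0.0, dist.intensity_sd), 0.0, 1.0)
        )
        parts[name] = PartSpec(cy + dy, cx + dx, ry, rx, inten)
    texture = (
        [(rng.normal(0.0, 1.0, (g, g)), amp) for g, amp in config.texture_grids]
        if config.texture_amp > 0
        else None
    )
    shading = max(0.0, config.shading_amp + rng.normal(0.0, config.shading_sd))
    return FaceSpec(
        identity_id=identity_id,
        parts=parts,
        oval=(float(cy), float(cx), float(config.oval_semi_axes[0]), float(config.oval_semi_axes[1])),
        norm_mean=config.norm_mean,
        norm_std=config.norm_std,
        texture=texture,
        texture_amp=config.texture_amp * lam,
        shading=shading,
    )


def generate_identities(
    n: int, seed: int, config: Optional[StimulusConfig] = None, start: int = 0
) -> List[FaceSpec]:
    return [generate_identity(i, seed, config) for i in range(start, start + n)]


def _ellipse_mask(size: int, cy, cx, ry, rx, supersample: int = 2) -> np.ndarray:
    """Anti-aliased ellipse coverage in [0, 1] via supersampled hard mask."""
    s = supersample
    hi = size * s
    yy = (np.arange(hi) + 0.5) / s - 0.5
    xx = yy
    fy = ((yy - cy) / ry) ** 2
    fx = ((xx - cx) / rx) ** 2
    hard = (fy[:, None] + fx[None, :]) <= 1.0
    return hard.reshape(size, s, size, s).mean(axis=(1, 3))


def _bbox_inside_oval(cy, cx, ry, rx, ocy, ocx, ory, orx) -> bool:
    # conservative: the part's bounding-box corners must lie inside the oval
    for sy in (-1.0, 1.0):
        for sx in (-1.0, 1.0):
            y = cy + sy * ry
            x = cx + sx * rx
            if ((y - ocy) / ory) ** 2 + ((x - ocx) / orx) ** 2 > 1.0:
                return False
    return True


def _check_part_inside_oval(spec: FaceSpec, name: str, part: PartSpec) -> None:
    ocy, ocx, ory, orx = spec.oval
    if not _bbox_inside_oval(part.cy, part.cx, part.ry, part.rx, ocy, ocx, ory, orx):
        raise ValueError(
            f"part {name!r} of identity {spec.identity_id} extends "
            f"outside the face oval"
        )


def render(spec: FaceSpec, config: Optional[StimulusConfig] = None) -> StimulusImage:
    """Rasterize a FaceSpec to a normalized 256x256 stimulus.

    In-oval pixels are standardized to (norm_mean, norm_std); pixels outside
    the oval are exactly 0. Raises on degenerate (near-constant) images or
    parts escaping the oval.
    """
    config = config or StimulusConfig()
    size = config.image_size
    ocy, ocx, ory, orx = spec.oval
    oval_cov = _ellipse_mask(size, ocy, ocx, ory, orx)
    canvas = config.base_intensity * oval_cov
    for name, part in spec.parts.items():
        _check_part_inside_oval(spec, name, part)
        cov = _ellipse_mask(size, part.cy, part.cx, part.ry, part.rx)
        canvas = canvas * (1.0 - cov) + part.intensity * cov
    mask = oval_cov > 0.0
    if spec.texture is not None and spec.texture_amp > 0:
        from skimage.transform import resize

        tex = np.zeros((size, size))
        for grid, rel_amp in spec.texture:
            tex += rel_amp * resize(np.asarray(grid, dtype=float), (size, size), order=1)
        canvas = canvas + spec.texture_amp * tex * mask
    if spec.shading > 0:
        yy = np.arange(size)[:, None]
        xx = np.arange(size)[None, :]
        r2 = ((yy - ocy) / ory) ** 2 + ((xx - ocx) / orx) ** 2
        canvas = canvas - spec.shading * r2 * mask
    vals = canvas[mask]
    if vals.std() < config.min_std_floor:
        raise ValueError("degenerate face: in-oval contrast below the norm floor")
    # standardize to (norm_mean, norm_std); rare extreme identities can
    # push single pixels outside [0, 1], in which case outliers are clipped
    # and the standardization repeated (documented renormalization rule)
    for _ in range(6):
        sd = vals.std()
        if sd < config.min_std_floor:
            raise ValueError("degenerate face: contrast collapsed during renormalization")
        vals = (vals - vals.mean()) / sd * spec.norm_std + spec.norm_mean
        if vals.min() >= 0.0 and vals.max() <= 1.0:
            break
        vals = np.clip(vals, 0.005, 0.995)
    else:
        raise ValueError("normalized intensities escape [0, 1]; reduce norm_std")
    out = np.zeros((size, size))
    out[mask] = vals
    return StimulusImage(
        out,
        meta={"identity_ids": [spec.identity_id], "transforms": ["render"]},
    )


def _require_same_shape(a: StimulusImage, b: StimulusImage) -> None:
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(f"image shapes differ: {a.pixels.shape} vs {b.pixels.shape}")


def make_composite(
    top_src: StimulusImage,
    bottom_src: StimulusImage,
    aligned: bool = True,
    config: Optional[StimulusConfig] = None,
) -> StimulusImage:
    """Pair the top half of one face with the bottom half of another.

    The split line is the horizontal midline of the face oval; a 2 px
    background-colored gap is centered on it. Misaligned composites shift
    the bottom half horizontally by ``misalign_offset`` px (default 40,
    half the face width).
    """
    config = config or StimulusConfig()
    _require_same_shape(top_src, bottom_src)
    cy = config.oval_center[0]
    gap0 = cy - config.gap_px // 2
    gap1 = gap0 + config.gap_px
    out = np.zeros_like(top_src.pixels)
    out[:gap0] = top_src.pixels[:gap0]
    bottom = bottom_src.pixels[gap1:]
    if not aligned:
        shifted = np.zeros_like(bottom)
        off = config.misalign_offset
        if off > 0:
            shifted[:, off:] = bottom[:, : bottom.shape[1] - off]
        elif off < 0:
            shifted[:, :off] = bottom[:, -off:]
        else:
            shifted = bottom
        bottom = shifted
    out[gap1:] = bottom
    meta = {
        "identity_ids": top_src.meta.get("identity_ids", []) + bottom_src.meta.get("identity_ids", []),
        "transforms": [f"composite(aligned={aligned})"],
        "top_identity": top_src.meta.get("identity_ids", [None])[0],
        "bottom_identity": bottom_src.meta.get("identity_ids", [None])[0],
    }
    return StimulusImage(out, meta)


def shift_image(pixels: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with zero fill."""
    out = np.zeros_like(pixels)
    h, w = pixels.shape
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = pixels[ys_src, xs_src]
    return out


def apply_attention(
    img: StimulusImage,
    region: Tuple[int, int, int, int],
    factor: float,
    recenter: bool = False,
    soften_px: int = 0,
) -> StimulusImage:
    """Down-weight everything outside ``region`` (r0, r1, c0, c1) by ``factor``.

    ``soften_px`` > 0 ramps the weighting linearly over that many pixels
    just outside the region, so the attentional window has a graded edge
    instead of cutting a brightness step across the face. With ``recenter``
    the whole image is translated so the region's center lands on the image
    center; the returned metadata carries the shifted region rectangle for
    downstream cropping.
    """
    r0, r1, c0, c1 = region
    h, w = img.pixels.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"attention region {region} outside image bounds {(h, w)}")
    if not 0.0 <= factor <= 1.0:
        raise ValueError("attention factor must be in [0, 1]")
    if soften_px > 0:
        rr = np.arange(h)[:, None]
        cc = np.arange(w)[None, :]
        # distance outside the rectangle (0 inside)
        dy = np.maximum(np.maximum(r0 - rr, rr - (r1 - 1)), 0)
        dx = np.maximum(np.maximum(c0 - cc, cc - (c1 - 1)), 0)
        d_out = np.maximum(dy, dx)
        wgt = factor + (1.0 - factor) * np.clip(1.0 - d_out / soften_px, 0.0, 1.0)
        out = img.pixels * wgt
    else:
        out = img.pixels * factor
        out[r0:r1, c0:c1] = img.pixels[r0:r1, c0:c1]
    new_region = (r0, r1, c0, c1)
    if recenter:
        dy = int(round(h / 2 - (r0 + r1) / 2))
        dx = int(round(w / 2 - (c0 + c1) / 2))
        out = shift_image(out, dy, dx)
        new_region = (r0 + dy, r1 + dy, c0 + dx, c1 + dx)
    meta = dict(img.meta)
    meta["transforms"] = meta.get("transforms", []) + [
        f"attention(factor={factor}, recenter={recenter})"
    ]
    meta["attended_region"] = list(new_region)
    return StimulusImage(out, meta)


def invert(img: StimulusImage) -> StimulusImage:
    """Upside-down presentation: reverse rows of the full field (involution)."""
    meta = dict(img.meta)
    meta["transforms"] = meta.get("transforms", []) + ["invert"]
    return StimulusImage(img.pixels[::-1].copy(), meta)


def make_whole_part_pair(
    eye_donor: StimulusImage,
    base: StimulusImage,
    config: Optional[StimulusConfig] = None,
) -> Tuple[StimulusImage, StimulusImage]:
    """Blend the donor's eye region into the base face; also crop that region.

    Returns (whole, part). ``whole`` is the base face whose eye-region
    rectangle is replaced by the donor's, with a ``feather_px``-wide linear
    blend just inside the boundary. ``part`` keeps the (replaced) eye region
    in place and zeroes everything else.
    """
    config = config or StimulusConfig()
    _require_same_shape(eye_donor, base)
    r0, r1, c0, c1 = config.derived_eye_region()
    h, w = base.pixels.shape
    weight = np.zeros((h, w))
    weight[r0:r1, c0:c1] = 1.0
    f = config.feather_px
    if f > 0:
        # linear ramp over the outermost f pixels inside the rectangle
        rr = np.arange(h)[:, None]
        cc = np.arange(w)[None, :]
        d_edge = np.minimum(
            np.minimum(rr - r0, (r1 - 1) - rr),
            np.minimum(cc - c0, (c1 - 1) - cc),
        )
        inside = weight > 0
        ramp = np.clip((d_edge + 1) / (f + 1), 0.0, 1.0)
        weight = np.where(inside, ramp, 0.0)
    whole_px = base.pixels * (1.0 - weight) + eye_donor.pixels * weight
    whole = StimulusImage(
        whole_px,
        meta={
            "identity_ids": eye_donor.meta.get("identity_ids", [])
            + base.meta.get("identity_ids", []),
            "transforms": ["whole(eye_donor, base)"],
            "eye_identity": eye_donor.meta.get("identity_ids", [None])[0],
            "rest_identity": base.meta.get("identity_ids", [None])[0],
            "eye_region": [r0, r1, c0, c1],
        },
    )
    part = crop_to_region(whole, (r0, r1, c0, c1))
    return whole, part


def crop_to_region(img: StimulusImage, region: Tuple[int, int, int, int]) -> StimulusImage:
    """Zero all pixels outside the rectangle, keeping the region in place."""
    r0, r1, c0, c1 = region
    out = np.zeros_like(img.pixels)
    out[r0:r1, c0:c1] = img.pixels[r0:r1, c0:c1]
    meta = dict(img.meta)
    meta["transforms"] = meta.get("transforms", []) + [f"crop({region})"]
    return StimulusImage(out, meta)


# ---------------------------------------------------------------------------
# PNG I/O and the loader hook for user-supplied face images


def save_png(img: StimulusImage, path) -> None:
    from PIL import Image

    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(img.meta, fh)


def load_png(path) -> StimulusImage:
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    meta = {}
    try:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        pass
    return StimulusImage(arr, meta)


def load_image_directory(directory, manifest: str = "manifest.json") -> List[StimulusImage]:
    """Loader hook: a directory of 256x256 grayscale PNGs with a manifest
    mapping filename -> identity id may replace the synthetic generator."""
    import os

    with open(os.path.join(directory, manifest)) as fh:
        entries = json.load(fh)
    images = []
    for fname, identity in sorted(entries.items()):
        img = load_png(os.path.join(directory, fname))
        img.meta.setdefault("identity_ids", [int(identity)])
        img.meta.setdefault("transforms", ["loaded"])
        images.append(img)
    return images
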