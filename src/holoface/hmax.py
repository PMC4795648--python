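"""Four-layer feedforward model of the ventral stream (HMAX architecture).

S1: a 10-scale image pyramid (factor 2^(1/4), bilinear) convolved with
    zero-mean unit-norm Gabor filters at 4 orientations; responses are the
    absolute normalized dot product, in [0, 1].
C1: max pooling over an 8x8 S1 window (stride 3) from 2 adjacent scales
    (128 values per unit); 10 S1 scales give 9 C1 bands, fine to coarse.
S2: Gaussian radial-basis-function match between stored C1 templates and
    every C1 patch (all positions, all bands that fit), sigma = 1/3 on the
    RMS-normalized Euclidean distance.
C2: global max over each template's entire S2 pyramid — one response per
    template, selective for appearance but invariant to position and scale.

Besides the literal ``s2_layer``/``c2_layer`` pair, the module provides a
fused ``c2_responses`` path that computes the same C2 vector via one im2col
matrix product per band without materializing S2 pyramids; experiments use
the fused path, tests assert the two agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import oaconvolve

from .config import C1Params, GaborParams, ModelConfig, PyramidSpec, S2Params
from .stimuli import StimulusImage

__all__ = [
    "ResponsePyramid",
    "C2Vector",
    "gabor_filters",
    "pyramid_sizes",
    "build_pyramid",
    "s1_layer",
    "c1_layer",
    "compute_c1",
    "compute_c1_band",
    "s2_layer",
    "c2_layer",
    "c2_responses",
    "extract_c2",
    "extract_c2_batch",
    "dissimilarity",
]

_EPS = 1e-12


@dataclass
class ResponsePyramid:
    """Per-scale (or per-band) grids of model-neuron responses.

    ``grids[i]`` has shape (h_i, w_i, n_orientations) for S1/C1, or
    (h_i, w_i) for a single S2 template's response maps.
    """

    stage: str
    grids: List[np.ndarray]
    meta: dict = field(default_factory=dict)


@dataclass
class C2Vector:
    """One response in (0, 1] per template, aligned with the bank order."""

    responses: np.ndarray
    template_ids: Optional[np.ndarray] = None

    def __len__(self):
        return len(self.responses)


# ---------------------------------------------------------------------------
# S1: Gabor pyramid


def gabor_filters(params: Optional[GaborParams] = None) -> np.ndarray:
    """Zero-mean, unit-norm Gabor bank, shape (n_orientations, size, size)."""
    params = params or GaborParams()
    half = params.size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    filters = []
    for k in range(params.n_orientations):
        theta = np.pi * k / params.n_orientations
        xr = x * np.cos(theta) + y * np.sin(theta)
        yr = -x * np.sin(theta) + y * np.cos(theta)
        g = np.exp(-(xr**2 + (params.aspect * yr) ** 2) / (2 * params.sigma**2))
        g *= np.cos(2 * np.pi * xr / params.wavelength)
        g -= g.mean()
        g /= np.linalg.norm(g)
        filters.append(g)
    return np.asarray(filters)


def pyramid_sizes(base: int, spec: Optional[PyramidSpec] = None) -> List[int]:
    """Image sizes round(base * 2^(-(i-1)/4)) with floor rounding, i=1..n."""
    spec = spec or PyramidSpec()
    return [int(np.floor(base * spec.scale_factor ** (-i))) for i in range(spec.n_scales)]


def _resize_bilinear(img: np.ndarray, size: int) -> np.ndarray:
    from skimage.transform import resize

    return resize(img, (size, size), order=1, anti_aliasing=False, preserve_range=True)


def build_pyramid(
    img, spec: Optional[PyramidSpec] = None, gabor_size: int = 11
) -> List[np.ndarray]:
    """Downscale the input to a multi-scale pyramid; scale 1 is the input.

    Every scale is resized directly from the base image (no cascading), so
    any scale can be recomputed independently.
    """
    spec = spec or PyramidSpec()
    pixels = img.pixels if isinstance(img, StimulusImage) else np.asarray(img, dtype=float)
    base = pixels.shape[0]
    sizes = pyramid_sizes(base, spec)
    if sizes[-1] < gabor_size:
        raise ValueError(
            f"coarsest pyramid scale ({sizes[-1]} px) is smaller than the "
            f"{gabor_size} px Gabor filter"
        )
    out = [pixels.astype(np.float64)]
    for s in sizes[1:]:
        out.append(_resize_bilinear(pixels, s))
    return out


def _s1_scale(
    image: np.ndarray, filters: np.ndarray, norm_epsilon: float = 0.0
) -> np.ndarray:
    """Absolute normalized dot product of each filter with each valid patch.

    With ``norm_epsilon`` > 0 the divisor is sqrt(eps^2 + ||x||^2), a
    contrast-saturation rule: responses in high-brightness patches are
    unchanged while low-brightness patches are gradedly suppressed.
    """
    size = filters.shape[-1]
    ones = np.ones((size, size))
    energy = oaconvolve(image**2, ones, mode="valid")
    norm = np.sqrt(np.maximum(energy, 0.0) + norm_epsilon**2)
    maps = []
    for g in filters:
        num = oaconvolve(image, g[::-1, ::-1], mode="valid")  # correlation
        resp = np.abs(num) / np.maximum(norm, _EPS)
        resp[norm < 1e-9] = 0.0
        resp[resp < 1e-10] = 0.0  # FFT round-off on structureless patches
        maps.append(np.clip(resp, 0.0, 1.0))
    return np.stack(maps, axis=-1)


def s1_layer(
    pyramid: Sequence[np.ndarray], params: Optional[GaborParams] = None
) -> ResponsePyramid:
    params = params or GaborParams()
    filters = gabor_filters(params)
    grids = [_s1_scale(im, filters, params.norm_epsilon) for im in pyramid]
    return ResponsePyramid("S1", grids, {"n_orientations": params.n_orientations})


# ---------------------------------------------------------------------------
# C1: local max pooling over position and scale


def _pool_spatial(grid: np.ndarray, pool: int, stride: int) -> np.ndarray:
    """Max over pool x pool windows with the given stride (valid windows)."""
    if grid.shape[0] < pool or grid.shape[1] < pool:
        raise ValueError("grid smaller than the pooling window")
    win = sliding_window_view(grid, (pool, pool), axis=(0, 1))[::stride, ::stride]
    return win.max(axis=(-2, -1))


def _c1_centers(n_units: int, s1_size: int, pool: int, stride: int, gabor: int) -> np.ndarray:
    """Normalized image coordinates of C1 unit centers on one scale."""
    # C1 unit i pools S1 units [stride*i, stride*i + pool); an S1 unit at j
    # covers pixels [j, j + gabor); center of the pooled field:
    idx = np.arange(n_units)
    center_px = stride * idx + (pool - 1) / 2 + (gabor - 1) / 2
    return (center_px + 0.5) / s1_size


def c1_layer(
    s1: ResponsePyramid,
    params: Optional[C1Params] = None,
    gabor_size: int = 11,
) -> ResponsePyramid:
    """Pool adjacent-scale pairs: 9 bands from 10 S1 scales, fine to coarse.

    Within a band the two scales are first max-pooled spatially on their own
    grids; the coarser pooled map is then registered to the finer grid by
    nearest-neighbor matching of unit centers in image coordinates and the
    two are combined by elementwise max, so each C1 unit reflects the 128
    S1 values of its pooled region.
    """
    params = params or C1Params()
    if len(s1.grids) < params.pool_scales:
        raise ValueError("need at least 2 S1 scales for C1 pooling")
    bands = []
    for b in range(len(s1.grids) - params.pool_scales + 1):
        fine = s1.grids[b]
        pooled_fine = _pool_spatial(fine, params.pool_size, params.stride)
        if pooled_fine.shape[0] == 0 or pooled_fine.shape[1] == 0:
            raise ValueError(f"C1 band {b + 1}: pooling produced an empty grid")
        combined = pooled_fine
        for extra in range(1, params.pool_scales):
            coarse = s1.grids[b + extra]
            pooled_coarse = _pool_spatial(coarse, params.pool_size, params.stride)
            # register coarse units to fine units via image-coordinate centers
            uf = _c1_centers(
                pooled_fine.shape[0], fine.shape[0] + gabor_size - 1,
                params.pool_size, params.stride, gabor_size,
            )
            uc = _c1_centers(
                pooled_coarse.shape[0], coarse.shape[0] + gabor_size - 1,
                params.pool_size, params.stride, gabor_size,
            )
            ri = np.clip(np.searchsorted(uc, uf), 0, len(uc) - 1)
            ri = np.where(
                (ri > 0) & (np.abs(uc[np.maximum(ri - 1, 0)] - uf) <= np.abs(uc[ri] - uf)),
                np.maximum(ri - 1, 0),
                ri,
            )
            combined = np.maximum(combined, pooled_coarse[ri][:, ri])
        bands.append(combined)
    return ResponsePyramid("C1", bands, dict(s1.meta))


def compute_c1(img, config: Optional[ModelConfig] = None) -> ResponsePyramid:
    """Full S1 -> C1 chain for one image."""
    config = config or ModelConfig()
    pyr = build_pyramid(img, config.pyramid, config.gabor.size)
    s1 = s1_layer(pyr, config.gabor)
    return c1_layer(s1, config.c1, config.gabor.size)


def compute_c1_band(img, band: int, config: Optional[ModelConfig] = None) -> np.ndarray:
    """C1 responses of a single band (1-indexed, fine to coarse).

    Only the two S1 scales feeding that band are computed; the result is
    identical to ``compute_c1(img).grids[band - 1]``.
    """
    config = config or ModelConfig()
    pixels = img.pixels if isinstance(img, StimulusImage) else np.asarray(img, dtype=float)
    sizes = pyramid_sizes(pixels.shape[0], config.pyramid)
    n_bands = len(sizes) - config.c1.pool_scales + 1
    if not 1 <= band <= n_bands:
        raise ValueError(f"band must be in 1..{n_bands}")
    scales = [pixels if i == 0 else _resize_bilinear(pixels, sizes[i])
              for i in range(band - 1, band - 1 + config.c1.pool_scales)]
    s1 = s1_layer(scales, config.gabor)
    c1 = c1_layer(s1, config.c1, config.gabor.size)
    return c1.grids[0]


# ---------------------------------------------------------------------------
# S2 / C2: RBF template match and global max


def _rbf(d2_per_entry: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-d2_per_entry / (2.0 * sigma**2))


def s2_layer(
    c1: ResponsePyramid,
    bank,
    s2_params: Optional[S2Params] = None,
) -> List[ResponsePyramid]:
    """Literal S2: one response pyramid per template (reference path).

    response = exp(-d^2 / (2 sigma^2)) where d is the Euclidean distance
    between the template and the C1 patch, divided by sqrt(#entries) when
    ``normalize_distance`` is set. Bands smaller than the template are
    skipped, never padded.
    """
    s2_params = s2_params or S2Params()
    pyramids = []
    for t in bank.templates:
        patch = np.asarray(t.patch, dtype=np.float64)
        ph, pw, po = patch.shape
        n_entries = patch.size
        maps = []
        for grid in c1.grids:
            if grid.shape[0] < ph or grid.shape[1] < pw or grid.shape[2] != po:
                continue
            win = sliding_window_view(grid, (ph, pw, po))[..., 0, :, :, :]
            d2 = ((win - patch) ** 2).sum(axis=(-3, -2, -1))
            if s2_params.normalize_distance:
                d2 = d2 / n_entries
            maps.append(_rbf(d2, s2_params.sigma))
        if not maps:
            raise ValueError(f"template {t.template_id} fits no C1 band")
        pyramids.append(ResponsePyramid("S2", maps, {"template_id": t.template_id}))
    return pyramids


def c2_layer(s2_pyramids: Sequence[ResponsePyramid]) -> C2Vector:
    """Global max over each template's entire S2 pyramid."""
    if len(s2_pyramids) == 0:
        raise ValueError("no S2 pyramids")
    vals, ids = [], []
    for p in s2_pyramids:
        if not p.grids:
            raise ValueError("empty S2 pyramid")
        vals.append(max(float(g.max()) for g in p.grids))
        ids.append(p.meta.get("template_id"))
    return C2Vector(np.asarray(vals), np.asarray(ids))


def _active_bbox(grid: np.ndarray) -> Optional[Tuple[int, int, int, int]]:
    act = grid.max(axis=-1) > 0.0
    rows = np.flatnonzero(act.any(axis=1))
    if rows.size == 0:
        return None
    cols = np.flatnonzero(act.any(axis=0))
    return rows[0], rows[-1] + 1, cols[0], cols[-1] + 1


def c2_responses(
    c1: ResponsePyramid,
    patch_stack: np.ndarray,
    s2_params: Optional[S2Params] = None,
) -> np.ndarray:
    """Fused S2+C2 for a stack of same-size templates, shape (n, ph, pw, o).

    Computes min-over-positions squared distance per band via an im2col
    matrix product. Patch positions are restricted to the dilated bounding
    box of nonzero C1 activity; patches wholly outside it are all-zero (the
    background is exactly black), so their distance to template t is
    ||t|| and is accounted for in closed form whenever such positions exist.
    """
    s2_params = s2_params or S2Params()
    patch_stack = np.ascontiguousarray(patch_stack, dtype=np.float32)
    n_t, ph, pw, po = patch_stack.shape
    tmat = patch_stack.reshape(n_t, -1)
    tmat64 = tmat.astype(np.float64)
    tn2 = (tmat**2).sum(axis=1)
    best_d2 = np.full(n_t, np.inf, dtype=np.float64)
    for grid in c1.grids:
        if grid.shape[0] < ph or grid.shape[1] < pw or grid.shape[2] != po:
            continue
        bbox = _active_bbox(grid)
        if bbox is None:
            best_d2 = np.minimum(best_d2, tn2)
            continue
        r0, r1, c0, c1_ = bbox
        rr0, rr1 = max(0, r0 - ph + 1), min(grid.shape[0], r1 + ph - 1)
        cc0, cc1 = max(0, c0 - pw + 1), min(grid.shape[1], c1_ + pw - 1)
        sub = np.ascontiguousarray(grid[rr0:rr1, cc0:cc1], dtype=np.float32)
        if (rr1 - rr0, cc1 - cc0) != grid.shape[:2]:
            # at least one patch position lies fully on background
            best_d2 = np.minimum(best_d2, tn2)
        if sub.shape[0] < ph or sub.shape[1] < pw:
            continue
        win = sliding_window_view(sub, (ph, pw, po))[..., 0, :, :, :]
        pm = np.ascontiguousarray(win).reshape(-1, ph * pw * po)
        pn2 = (pm**2).sum(axis=1)
        cross = pm @ tmat.T
        d2 = pn2[:, None] - 2.0 * cross + tn2[None, :]
        # the expansion cancels catastrophically in float32 near d = 0;
        # recompute each template's in-band argmin directly in float64
        arg = d2.argmin(axis=0)
        refined = ((pm[arg].astype(np.float64) - tmat64) ** 2).sum(axis=1)
        best_d2 = np.minimum(best_d2, refined)
    if not np.all(np.isfinite(best_d2)):
        raise ValueError("templates fit no C1 band")
    if s2_params.normalize_distance:
        best_d2 = best_d2 / (ph * pw * po)
    return _rbf(best_d2, s2_params.sigma)


def extract_c2(img, banks, config: Optional[ModelConfig] = None) -> Dict[str, C2Vector]:
    """C2 vectors of one image for one or several template banks.

    ``banks`` maps size-class name to a TemplateBank (a single bank is also
    accepted). The S1/C1 stages are shared across banks.
    """
    config = config or ModelConfig()
    if hasattr(banks, "templates"):
        banks = {getattr(banks, "size_class", "bank"): banks}
    c1 = compute_c1(img, config)
    out = {}
    for name, bank in banks.items():
        resp = c2_responses(c1, bank.patch_stack(), config.s2)
        out[name] = C2Vector(resp, np.asarray([t.template_id for t in bank.templates]))
    return out


def extract_c2_batch(
    images: Sequence, banks, config: Optional[ModelConfig] = None
) -> Dict[str, np.ndarray]:
    """C2 matrices (n_images x n_templates) per size class, shared pipeline."""
    config = config or ModelConfig()
    if hasattr(banks, "templates"):
        banks = {getattr(banks, "size_class", "bank"): banks}
    mats: Dict[str, list] = {name: [] for name in banks}
    for img in images:
        c1 = compute_c1(img, config)
        for name, bank in banks.items():
            mats[name].append(c2_responses(c1, bank.patch_stack(), config.s2))
    return {name: np.asarray(rows) for name, rows in mats.items()}


def dissimilarity(a, b, indices=None) -> float:
    """Euclidean distance between two C2 vectors (optionally an index subset)."""
    av = a.responses if isinstance(a, C2Vector) else np.asarray(a, dtype=float)
    bv = b.responses if isinstance(b, C2Vector) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"C2 lengths differ: {av.shape} vs {bv.shape}")
    if indices is not None:
        av, bv = av[indices], bv[indices]
    return float(np.linalg.norm(av - bv))
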