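"""Configuration dataclasses for the model, stimuli and experiments.

All tunable parameters live here so that a single serialized config plus the
seed streams reproduces every output. ``RunConfig.to_dict`` round-trips
through YAML/JSON; ``config_hash`` gives a stable digest embedded in result
files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import yaml

__all__ = [
    "PartDistribution",
    "StimulusConfig",
    "GaborParams",
    "PyramidSpec",
    "C1Params",
    "S2Params",
    "ModelConfig",
    "ExperimentConfig",
    "RunConfig",
    "config_hash",
]


@dataclass(frozen=True)
class PartDistribution:
    """Sampling distribution for one face part.

    Positions are offsets (dy, dx) from the oval center in pixels; sizes are
    ellipse semi-axes (ry, rx); intensities are gray levels in [0, 1] before
    the global pixel normalization. Each ``*_sd`` is the standard deviation
    of identity-specific Gaussian jitter.
    """

    dy: float
    dx: float
    ry: float
    rx: float
    intensity: float
    pos_sd: float = 4.0
    size_sd: float = 2.0
    intensity_sd: float = 0.12


def _default_parts() -> dict:
    # Layout in image coordinates relative to the oval center (y down).
    # Two eyes + brows in the top half, nose + mouth in the bottom half.
    return {
        "left_brow": PartDistribution(dy=-34.0, dx=-18.0, ry=2.5, rx=9.0, intensity=0.25),
        "right_brow": PartDistribution(dy=-34.0, dx=18.0, ry=2.5, rx=9.0, intensity=0.25),
        "left_eye": PartDistribution(dy=-20.0, dx=-18.0, ry=4.5, rx=7.5, intensity=0.12),
        "right_eye": PartDistribution(dy=-20.0, dx=18.0, ry=4.5, rx=7.5, intensity=0.12),
        "nose": PartDistribution(dy=6.0, dx=0.0, ry=13.0, rx=5.0, intensity=0.72),
        "mouth": PartDistribution(dy=32.0, dx=0.0, ry=4.5, rx=14.0, intensity=0.18),
    }


@dataclass(frozen=True)
class StimulusConfig:
    """Geometry and statistics of the synthetic face stimuli.

    Faces are anti-aliased geometric primitives inside an 80x120 px oval on
    a 256x256 black field; in-oval pixels are normalized to a common mean
    and standard deviation (the background stays exactly 0).
    """

    image_size: int = 256
    oval_center: tuple = (128, 128)  # (row, col)
    oval_semi_axes: tuple = (60, 40)  # (ry, rx) -> 80 wide x 120 tall face
    base_intensity: float = 0.55
    norm_mean: float = 0.5
    norm_std: float = 0.08
    min_std_floor: float = 1e-4
    # identity-specific multi-scale albedo texture (skin shading variation)
    # and a radial darkening toward the oval boundary. The texture carries
    # identity information at BOTH coarse and fine spatial scales — the
    # scale-distinctive statistics real face photographs have — so that
    # templates match best at their native pyramid band instead of finding
    # spurious cross-scale matches in smooth content.
    texture_amp: float = 0.05
    texture_grids: tuple = ((12, 1.0), (96, 0.9))  # (grid size, rel. amp)
    shading_amp: float = 0.10
    shading_sd: float = 0.02
    #: per-identity distinctiveness: all part jitters and the texture are
    #: scaled by a lognormal factor exp(N(0, sigma^2)), so some identities
    #: stay close to the prototype (yielding broadly-matching templates)
    #: while others are highly distinctive — the spread real face
    #: populations show
    distinctiveness_sigma: float = 0.7
    parts: dict = field(default_factory=_default_parts)
    # composite construction
    gap_px: int = 2
    misalign_offset: int = 40  # half the face width
    # eye region: upper part of the oval, full oval width (r0, r1, c0, c1)
    eye_region: Optional[tuple] = None  # None -> derived from oval geometry
    eye_region_fraction: float = 0.4  # fraction of oval height covered
    feather_px: int = 1
    # attention factors
    cfe_attention_factor: float = 0.1
    wpe_attention_factor: float = 0.5
    #: linear ramp width (px) of the attentional window's edge; 0 = hard
    attention_soften_px: int = 8

    def derived_eye_region(self) -> tuple:
        """Eye-region rectangle (r0, r1, c0, c1), half-open, image coords."""
        if self.eye_region is not None:
            return tuple(self.eye_region)
        cy, cx = self.oval_center
        ry, rx = self.oval_semi_axes
        r0 = cy - ry
        r1 = r0 + int(round(2 * ry * self.eye_region_fraction))
        return (r0, r1, cx - rx, cx + rx)

    def top_half_region(self) -> tuple:
        """Top-half rectangle above the composite gap (r0, r1, c0, c1)."""
        cy, cx = self.oval_center
        ry, rx = self.oval_semi_axes
        gap0 = cy - self.gap_px // 2
        return (cy - ry, gap0, cx - rx, cx + rx)


@dataclass(frozen=True)
class GaborParams:
    """S1 Gabor filter bank: 11x11 px, 4 orientations, zero-mean, unit-norm."""

    size: int = 11
    wavelength: float = 5.6
    sigma: float = 4.5
    aspect: float = 0.3
    n_orientations: int = 4
    #: optional contrast-saturation constant in the S1 normalization,
    #: |G.x| / sqrt(eps^2 + ||x||^2); 0 gives the pure normalized dot
    #: product, under which attentional pixel weighting acts through the
    #: relative within-patch amplitude of bright vs dimmed content
    norm_epsilon: float = 0.0


@dataclass(frozen=True)
class PyramidSpec:
    """Multi-scale image pyramid: 10 scales, factor 2^(1/4), bilinear."""

    n_scales: int = 10
    scale_factor: float = 2.0 ** 0.25
    interpolation: str = "bilinear"


@dataclass(frozen=True)
class C1Params:
    """C1 pools an 8x8 S1 window from 2 adjacent scales (128 values), stride 3."""

    pool_size: int = 8
    pool_scales: int = 2
    stride: int = 3


@dataclass(frozen=True)
class S2Params:
    """Gaussian RBF template match, sigma = 1/3 on the Euclidean distance.

    The raw (unnormalized) distance is the default. Because C2 reports the
    best match over every position and scale, best-match distances stay
    moderate and responses spread over (0, 1] with a graded ordering by
    template size — the regime the response-band analyses presuppose.
    ``normalize_distance`` instead divides the distance by sqrt(#entries);
    at realistic C1 energies this compresses all responses above ~0.9, so
    it is off by default.
    """

    sigma: float = 1.0 / 3.0
    normalize_distance: bool = False


TEMPLATE_SHAPES = {"large": (12, 12), "medium": (8, 8), "small": (4, 4)}
SIZE_CLASSES = ("large", "medium", "small")

#: Nominal face footprint at the template band, in C1 units (width x height
#: is quoted in the literature as 17x22 for an 80x120 px face).
NOMINAL_FOOTPRINT_C1 = (17, 22)


@dataclass(frozen=True)
class ModelConfig:
    gabor: GaborParams = field(default_factory=GaborParams)
    pyramid: PyramidSpec = field(default_factory=PyramidSpec)
    c1: C1Params = field(default_factory=C1Params)
    s2: S2Params = field(default_factory=S2Params)
    template_band: int = 7  # C1 scale band (1..9, fine -> coarse) for templates
    footprint_threshold: float = 1e-3


@dataclass(frozen=True)
class ExperimentConfig:
    n_train_identities: int = 50
    templates_per_image: int = 20
    n_cfe_identities: int = 20
    n_fie_identities: int = 50
    n_wpe_identities: int = 20
    n_resamples: int = 1000
    target_hit_rate: float = 0.75
    fie_subsample: dict = field(
        default_factory=lambda: {"large": 100, "medium": 150, "small": None}
    )
    #: response band for the neural inversion analysis; None = use every
    #: neuron (the synthetic population's per-size response distributions
    #: are disjoint, so no band intersects all three size classes)
    neural_band: Optional[tuple] = None
    cfe_max_trials: Optional[int] = None
    wpe_max_trials: Optional[int] = None
    #: the study face is re-presented as one of the test faces, so the
    #: attentional weighting applied to test faces applies to it as well
    weight_wpe_study_face: bool = True


@dataclass(frozen=True)
class RunConfig:
    """Top-level config: three independent seed streams plus all parameters."""

    stimulus_seed: int = 1
    template_seed: int = 2
    experiment_seed: int = 3
    stimuli: StimulusConfig = field(default_factory=StimulusConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    experiments: ExperimentConfig = field(default_factory=ExperimentConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stimuli" in d:
            sd = dict(d["stimuli"])
            if "parts" in sd:
                sd["parts"] = {
                    k: PartDistribution(**v) if isinstance(v, dict) else v
                    for k, v in sd["parts"].items()
                }
            for key in ("oval_center", "oval_semi_axes", "eye_region"):
                if sd.get(key) is not None:
                    sd[key] = tuple(sd[key])
            d["stimuli"] = StimulusConfig(**sd)
        if "model" in d:
            md = dict(d["model"])
            for key, klass in (
                ("gabor", GaborParams),
                ("pyramid", PyramidSpec),
                ("c1", C1Params),
                ("s2", S2Params),
            ):
                if key in md and isinstance(md[key], dict):
                    md[key] = klass(**md[key])
            d["model"] = ModelConfig(**md)
        if "experiments" in d:
            ed = dict(d["experiments"])
            if ed.get("neural_band") is not None:
                ed["neural_band"] = tuple(ed["neural_band"])
            d["experiments"] = ExperimentConfig(**ed)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def with_seed(self, seed: int) -> "RunConfig":
        """Derive the three seed streams from a single master seed."""
        return replace(
            self,
            stimulus_seed=(seed * 3 + 0) % (2**31 - 1),
            template_seed=(seed * 3 + 1) % (2**31 - 1),
            experiment_seed=(seed * 3 + 2) % (2**31 - 1),
        )


def config_hash(config: RunConfig) -> str:
    """Stable sha256 digest of a canonical JSON rendering of the config."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
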