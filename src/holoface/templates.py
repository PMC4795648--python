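"""Unsupervised template learning: stored C1 patches at three tuning sizes.

Learning is nothing more than storing patterns of C1 responses from
training faces. All templates come from the relatively coarse C1 scale
band 7 (of 9). A "large" template spans 12x12 C1 units (x4 orientations) —
multiple face parts but less than half a face, whose footprint at that band
is about 17x22 units; "medium" (8x8) and "small" (4x4) templates are the
central sub-blocks of their parent large template, so the three size
classes differ only in tuning size, never in content or provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import ModelConfig, SIZE_CLASSES, TEMPLATE_SHAPES
from .hmax import compute_c1_band
from .stimuli import StimulusImage

__all__ = ["Template", "TemplateBank", "face_footprint_c1", "learn_bank",
           "save_banks", "load_banks"]


@dataclass
class Template:
    template_id: int
    size_class: str
    patch: np.ndarray  # (h, w, 4) C1 responses
    source_image_id: int
    source_position: Tuple[int, int]  # top-left (row, col) in band coords
    source_scale_band: int
    parent_id: Optional[int] = None


@dataclass
class TemplateBank:
    size_class: str
    templates: List[Template]
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.templates)

    def patch_stack(self) -> np.ndarray:
        """All patches as one (n, h, w, 4) float32 array (cached)."""
        if "_stack" not in self.meta:
            self.meta["_stack"] = np.ascontiguousarray(
                np.stack([t.patch for t in self.templates]), dtype=np.float32
            )
        return self.meta["_stack"]


def face_footprint_c1(
    img: StimulusImage,
    config: Optional[ModelConfig] = None,
    band: Optional[int] = None,
) -> Tuple[int, int, int, int]:
    """Bounding region (r0, r1, c0, c1) of above-threshold C1 activity.

    Measured at the template band; for the default 80x120 px face geometry
    the region spans roughly 17x22 C1 units (width x height). S1 responses
    are contrast-normalized, so the footprint is invariant to global
    intensity scaling of the face.
    """
    config = config or ModelConfig()
    band = band or config.template_band
    grid = compute_c1_band(img, band, config)
    act = grid.max(axis=-1) > config.footprint_threshold
    rows = np.flatnonzero(act.any(axis=1))
    cols = np.flatnonzero(act.any(axis=0))
    if rows.size == 0:
        raise ValueError("blank image: no above-threshold C1 activity")
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def learn_bank(
    train_images: Sequence[StimulusImage],
    per_image: int = 20,
    seed: int = 0,
    config: Optional[ModelConfig] = None,
    allow_background_patches: bool = False,
) -> Dict[str, TemplateBank]:
    """Store ``per_image`` random C1 patches per training face.

    Large (12x12) patches are sampled at uniformly random positions such
    that the whole patch lies inside the face's C1 footprint (so templates
    never memorize pure background; disable with
    ``allow_background_patches``). Medium and small banks are the central
    8x8 / 4x4 crops of each large patch, linked by ``parent_id``. Returns
    {"large": bank, "medium": bank, "small": bank}.
    """
    if per_image < 1:
        raise ValueError("per_image must be >= 1")
    config = config or ModelConfig()
    band = config.template_band
    rng = np.random.default_rng(seed)
    lh, lw = TEMPLATE_SHAPES["large"]
    banks: Dict[str, List[Template]] = {sc: [] for sc in SIZE_CLASSES}
    tid = 0
    for img_idx, img in enumerate(train_images):
        image_id = img.meta.get("identity_ids", [img_idx])[0]
        grid = compute_c1_band(img, band, config)
        if allow_background_patches:
            r0, r1, c0, c1 = 0, grid.shape[0], 0, grid.shape[1]
        else:
            act = grid.max(axis=-1) > config.footprint_threshold
            rows = np.flatnonzero(act.any(axis=1))
            cols = np.flatnonzero(act.any(axis=0))
            if rows.size == 0:
                raise ValueError(f"image {image_id}: blank at C1 band {band}")
            r0, r1, c0, c1 = rows[0], rows[-1] + 1, cols[0], cols[-1] + 1
        max_r, max_c = r1 - lh, c1 - lw
        if max_r < r0 or max_c < c0:
            raise ValueError(
                f"image {image_id}: face footprint {(r1 - r0, c1 - c0)} at "
                f"band {band} cannot contain a {lh}x{lw} template"
            )
        for _ in range(per_image):
            pr = int(rng.integers(r0, max_r + 1))
            pc = int(rng.integers(c0, max_c + 1))
            large = np.array(grid[pr : pr + lh, pc : pc + lw], dtype=np.float32)
            parent = Template(tid, "large", large, image_id, (pr, pc), band)
            banks["large"].append(parent)
            for sc in ("medium", "small"):
                sh, sw = TEMPLATE_SHAPES[sc]
                dr, dc = (lh - sh) // 2, (lw - sw) // 2
                banks[sc].append(
                    Template(
                        tid,
                        sc,
                        np.array(large[dr : dr + sh, dc : dc + sw], dtype=np.float32),
                        image_id,
                        (pr + dr, pc + dc),
                        band,
                        parent_id=tid,
                    )
                )
            tid += 1
    return {
        sc: TemplateBank(sc, tlist, seed=seed, meta={"per_image": per_image, "band": band})
        for sc, tlist in banks.items()
    }


# ---------------------------------------------------------------------------
# serialization: one .npz per bank trio with a JSON header


def save_banks(banks: Dict[str, TemplateBank], path) -> None:
    arrays, header = {}, {}
    for sc, bank in banks.items():
        arrays[f"{sc}_patches"] = bank.patch_stack()
        header[sc] = {
            "seed": bank.seed,
            "meta": {k: v for k, v in bank.meta.items() if not k.startswith("_")},
            "templates": [
                {
                    "template_id": t.template_id,
                    "source_image_id": int(t.source_image_id),
                    "source_position": list(t.source_position),
                    "source_scale_band": t.source_scale_band,
                    "parent_id": t.parent_id,
                }
                for t in bank.templates
            ],
        }
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_banks(path) -> Dict[str, TemplateBank]:
    data = np.load(path)
    header = json.loads(bytes(data["header"]).decode())
    banks = {}
    for sc, info in header.items():
        patches = data[f"{sc}_patches"]
        templates = [
            Template(
                rec["template_id"],
                sc,
                patches[i],
                rec["source_image_id"],
                tuple(rec["source_position"]),
                rec["source_scale_band"],
                rec["parent_id"],
            )
            for i, rec in enumerate(info["templates"])
        ]
        banks[sc] = TemplateBank(sc, templates, seed=info["seed"], meta=info["meta"])
    return banks
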