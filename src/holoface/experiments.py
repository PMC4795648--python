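"""The three psychophysics simulations: composite-face, inversion and
whole-part effects, driven entirely by C2 responses.

Decision rules follow the simulated observer: "same/different" judgements
threshold the Euclidean distance between C2 vectors (threshold calibrated
so the aligned upright hit-rate is as close to 75% as possible), and 2AFC
memory trials pick the choice whose C2 vector is closer to the study face.
Statistical inference is a one-sided paired bootstrap over the C2 neuron
population plus Wilcoxon signed-rank tests; see :mod:`holoface.stats`.

All heavy lifting is vectorized over neurons: each experiment precomputes a
(trials x neurons) matrix of per-neuron squared response differences, so a
bootstrap resample reduces to one matrix-vector product with the resample's
neuron-count vector.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ExperimentConfig, ModelConfig, StimulusConfig
from .hmax import extract_c2_batch
from .stimuli import (
    FaceSpec,
    StimulusImage,
    apply_attention,
    crop_to_region,
    invert,
    make_composite,
    make_whole_part_pair,
    render,
)

__all__ = [
    "ExperimentResult",
    "calibrate_threshold",
    "run_cfe",
    "run_fie_behavioral",
    "run_fie_neural",
    "run_wpe",
]


@dataclass
class ExperimentResult:
    """Per-condition estimates, effect sizes and resampling summaries."""

    experiment: str
    sizes: Dict[str, dict]
    comparisons: Dict[str, float] = field(default_factory=dict)
    n_trials: int = 0
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)
    trials: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "sizes": self.sizes,
            "comparisons": self.comparisons,
            "n_trials": int(self.n_trials),
            "seed": self.seed,
            "meta": self.meta,
        }


def calibrate_threshold(distances, target: float = 0.75) -> Tuple[float, float]:
    """Pick the distance threshold whose hit-rate is closest to ``target``.

    Candidates are the midpoints between consecutive distinct sorted
    distances plus one candidate below the minimum and one above the
    maximum; the hit-rate (fraction of distances strictly below the
    threshold) is non-decreasing in the threshold, and ties in closeness
    resolve to the lower threshold. Raises if all distances are equal.
    """
    d = np.sort(np.asarray(distances, dtype=float))
    if d.size == 0:
        raise ValueError("no distances to calibrate on")
    uniq = np.unique(d)
    if uniq.size == 1:
        raise ValueError("degenerate distances: all trials identical, no "
                         "calibratable threshold")
    span = uniq[-1] - uniq[0]
    cands = np.concatenate(
        [[uniq[0] - 0.01 * span], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 0.01 * span]]
    )
    hits = np.searchsorted(d, cands, side="left") / d.size
    k = int(np.argmin(np.abs(hits - target)))  # first minimum -> lower threshold
    return float(cands[k]), float(hits[k])


def _counts(idx: np.ndarray, n: int) -> np.ndarray:
    return np.bincount(idx, minlength=n).astype(np.float32)


def _resample_indices(rng, n: int, subsample: Optional[int]) -> np.ndarray:
    if subsample is not None and subsample < n:
        pool = rng.choice(n, size=subsample, replace=False)
    else:
        pool = np.arange(n)
    return rng.choice(pool, size=pool.size, replace=True)


def _bootstrap_summary(stats: np.ndarray, point: float) -> dict:
    return {
        "point_estimate": float(point),
        "sem": float(stats.std(ddof=1)) if stats.size > 1 else 0.0,
        "p_value": float(np.mean(stats <= 0.0)),
        "n_resamples": int(stats.size),
    }


# ---------------------------------------------------------------------------
# Composite Face Effect


def _cfe_images(
    specs: Sequence[FaceSpec], stim: StimulusConfig
) -> Tuple[List[StimulusImage], Dict[Tuple[int, int, bool], int]]:
    faces = {s.identity_id: render(s, stim) for s in specs}
    region = stim.top_half_region()
    images, index = [], {}
    ids = sorted(faces)
    for t in ids:
        for b in ids:
            if b == t:
                continue
            for aligned in (True, False):
                comp = make_composite(faces[t], faces[b], aligned=aligned, config=stim)
                comp = apply_attention(
                    comp, region, stim.cfe_attention_factor, recenter=True,
                    soften_px=stim.attention_soften_px,
                )
                index[(t, b, aligned)] = len(images)
                images.append(comp)
    return images, index


def run_cfe(
    banks,
    face_specs: Sequence[FaceSpec],
    seed: int = 0,
    n_resamples: int = 1000,
    target_hit_rate: float = 0.75,
    max_trials: Optional[int] = None,
    stim_config: Optional[StimulusConfig] = None,
    model_config: Optional[ModelConfig] = None,
    per_neuron: bool = True,
) -> ExperimentResult:
    """Composite-face experiment on "same" trials (identical top halves).

    For every top identity T and unordered pair of distinct bottom
    identities {B1, B2} (all != T), the two composites share the top half
    and differ in the bottom half. Both are attention-weighted (bottom-half
    pixels x 0.1, image recentered on the top half). A trial is judged
    "same" when the C2 distance between the two composites falls below a
    threshold calibrated per tuning size so the aligned hit-rate is as
    close to 75% as possible; the effect is the misaligned - aligned
    hit-rate difference, tested by one-sided neuron bootstrap. The
    per-neuron variant treats each C2 neuron as a 1-D classifier with its
    own calibrated threshold and applies a Wilcoxon signed-rank test across
    neurons.
    """
    stim = stim_config or StimulusConfig()
    model = model_config or ModelConfig()
    if hasattr(banks, "templates"):
        banks = {banks.size_class: banks}
    if len(face_specs) < 3:
        raise ValueError("CFE needs at least 3 identities")
    rng = np.random.default_rng(seed)
    images, index = _cfe_images(face_specs, stim)
    c2 = extract_c2_batch(images, banks, model)

    ids = sorted(s.identity_id for s in face_specs)
    triples = [
        (t, b1, b2)
        for t in ids
        for b1, b2 in itertools.combinations([b for b in ids if b != t], 2)
    ]
    if max_trials is not None and max_trials < len(triples):
        keep = rng.choice(len(triples), size=max_trials, replace=False)
        triples = [triples[k] for k in sorted(keep)]

    sizes, comparisons = {}, {}
    trials_rows = []
    for sc, mat in c2.items():
        n_neurons = mat.shape[1]
        d2 = {}
        for aligned in (True, False):
            a_idx = np.array([index[(t, b1, aligned)] for t, b1, _ in triples])
            b_idx = np.array([index[(t, b2, aligned)] for t, _, b2 in triples])
            delta = mat[a_idx].astype(np.float32) - mat[b_idx].astype(np.float32)
            d2[aligned] = delta**2
        d_ali = np.sqrt(d2[True].sum(axis=1))
        d_mis = np.sqrt(d2[False].sum(axis=1))
        tau, hit_ali = calibrate_threshold(d_ali, target_hit_rate)
        hit_mis = float(np.mean(d_mis < tau))

        def stat_fn(idx, _d2=d2):
            c = _counts(idx, n_neurons)
            da = np.sqrt(_d2[True] @ c)
            dm = np.sqrt(_d2[False] @ c)
            t_, ha = calibrate_threshold(da, target_hit_rate)
            return float(np.mean(dm < t_)) - ha

        boot_stats = np.empty(n_resamples)
        brng = np.random.default_rng([seed, 1])
        for r in range(n_resamples):
            boot_stats[r] = stat_fn(_resample_indices(brng, n_neurons, None))

        entry = {
            "threshold": tau,
            "aligned_hit_rate": hit_ali,
            "misaligned_hit_rate": hit_mis,
            "effect": hit_mis - hit_ali,
            "bootstrap": _bootstrap_summary(boot_stats, hit_mis - hit_ali),
        }
        if per_neuron:
            from .stats import wilcoxon_signed_rank

            diffs = np.empty(n_neurons)
            for j in range(n_neurons):
                da = np.sqrt(d2[True][:, j])
                dm = np.sqrt(d2[False][:, j])
                try:
                    tj, haj = calibrate_threshold(da, target_hit_rate)
                    diffs[j] = float(np.mean(dm < tj)) - haj
                except ValueError:
                    diffs[j] = 0.0
            try:
                _, p_two = wilcoxon_signed_rank(diffs)
                p_one = p_two / 2 if np.median(diffs) > 0 else 1 - p_two / 2
            except ValueError:
                p_one = np.nan
            entry["per_neuron"] = {
                "median_effect": float(np.median(diffs)),
                "wilcoxon_p_one_sided": float(p_one),
            }
        sizes[sc] = entry
        for (t, b1, b2), da_, dm_ in zip(triples, d_ali, d_mis):
            trials_rows.append(
                {
                    "experiment": "CFE",
                    "size_class": sc,
                    "top": t,
                    "bottom_1": b1,
                    "bottom_2": b2,
                    "d_aligned": float(da_),
                    "d_misaligned": float(dm_),
                    "same_aligned": bool(da_ < tau),
                    "same_misaligned": bool(dm_ < tau),
                }
            )
    if "large" in sizes and "small" in sizes:
        comparisons["small_effect_fraction_of_large"] = (
            sizes["small"]["effect"] / sizes["large"]["effect"]
            if sizes["large"]["effect"] != 0
            else np.nan
        )
    return ExperimentResult(
        "CFE",
        sizes,
        comparisons,
        n_trials=len(triples),
        seed=seed,
        meta={"n_identities": len(face_specs), "target_hit_rate": target_hit_rate},
        trials=pd.DataFrame(trials_rows),
    )


# ---------------------------------------------------------------------------
# Face Inversion Effect


def _fie_c2(banks, face_specs, stim, model):
    faces = [render(s, stim) for s in face_specs]
    images = faces + [invert(f) for f in faces]
    c2 = extract_c2_batch(images, banks, model)
    n = len(faces)
    return {sc: (m[:n], m[n:]) for sc, m in c2.items()}


def _pair_d2(mat: np.ndarray, pairs) -> np.ndarray:
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    delta = mat[i].astype(np.float32) - mat[j].astype(np.float32)
    return delta**2


def run_fie_behavioral(
    banks,
    face_specs: Sequence[FaceSpec],
    seed: int = 0,
    n_resamples: int = 1000,
    subsample: Optional[Dict[str, Optional[int]]] = None,
    stim_config: Optional[StimulusConfig] = None,
    model_config: Optional[ModelConfig] = None,
) -> ExperimentResult:
    """Behavioral inversion effect: pairwise C2 dissimilarity drop.

    For each tuning size, the mean C2 Euclidean distance over all C(n, 2)
    pairs of faces, upright and inverted; the effect is upright - inverted.
    The neuron bootstrap first subsamples without replacement (100 large /
    150 medium by default, compensating for coverage area), then resamples
    with replacement; tuning sizes are compared on paired resamples.
    """
    stim = stim_config or StimulusConfig()
    model = model_config or ModelConfig()
    if hasattr(banks, "templates"):
        banks = {banks.size_class: banks}
    if len(face_specs) < 2:
        raise ValueError("FIE needs at least 2 identities")
    subsample = subsample if subsample is not None else ExperimentConfig().fie_subsample
    c2 = _fie_c2(banks, face_specs, stim, model)
    pairs = list(itertools.combinations(range(len(face_specs)), 2))

    d2 = {
        sc: (_pair_d2(up, pairs), _pair_d2(inv, pairs)) for sc, (up, inv) in c2.items()
    }
    sizes = {
        sc: {
            "upright_mean_dissimilarity": float(np.sqrt(d2u.sum(1)).mean()),
            "inverted_mean_dissimilarity": float(np.sqrt(d2i.sum(1)).mean()),
        }
        for sc, (d2u, d2i) in d2.items()
    }
    rng = np.random.default_rng([seed, 2])
    effects = {sc: np.empty(n_resamples) for sc in d2}
    for r in range(n_resamples):
        for sc, (d2u, d2i) in d2.items():
            n_neurons = d2u.shape[1]
            idx = _resample_indices(rng, n_neurons, subsample.get(sc))
            cnt = _counts(idx, n_neurons)
            effects[sc][r] = np.sqrt(d2u @ cnt).mean() - np.sqrt(d2i @ cnt).mean()
    for sc in d2:
        point = (
            sizes[sc]["upright_mean_dissimilarity"]
            - sizes[sc]["inverted_mean_dissimilarity"]
        )
        sizes[sc]["effect"] = point
        sizes[sc]["bootstrap"] = _bootstrap_summary(effects[sc], point)
        sizes[sc]["subsample"] = subsample.get(sc)
    comparisons = {}
    for hi, lo in itertools.combinations([s for s in ("large", "medium", "small") if s in d2], 2):
        comparisons[f"{hi}_gt_{lo}_p"] = float(np.mean(effects[hi] <= effects[lo]))
    return ExperimentResult(
        "FIE_behavioral",
        sizes,
        comparisons,
        n_trials=len(pairs),
        seed=seed,
        meta={"n_identities": len(face_specs), "n_pairs": len(pairs)},
    )


def run_fie_neural(
    banks,
    face_specs: Sequence[FaceSpec],
    band: Optional[Tuple[float, float]] = (0.75, 0.80),
    seed: int = 0,
    stim_config: Optional[StimulusConfig] = None,
    model_config: Optional[ModelConfig] = None,
) -> ExperimentResult:
    """Neural inversion effect on band-matched C2 neurons.

    Only neurons whose mean response to upright faces lies in ``band``
    enter the analysis; neuron counts are then equalized across tuning
    sizes by seeded random selection (controlling mean upright response and
    ceiling/floor effects). The per-face effect is the drop of the selected
    population's mean response under inversion, tested across faces by
    Wilcoxon signed-rank.

    ``band=None`` skips the response-matching and uses the full neuron
    population of every size class. This is the right variant when the
    size classes' response distributions do not overlap — with schematic
    synthetic faces no band may intersect all three distributions, in
    which case the banded call raises and reports them.
    """
    stim = stim_config or StimulusConfig()
    model = model_config or ModelConfig()
    if hasattr(banks, "templates"):
        banks = {banks.size_class: banks}
    c2 = _fie_c2(banks, face_specs, stim, model)
    eligible = {}
    for sc, (up, _) in c2.items():
        mean_up = up.mean(axis=0)
        if band is None:
            eligible[sc] = np.arange(mean_up.size)
            continue
        lo, hi = band
        sel = np.flatnonzero((mean_up >= lo) & (mean_up <= hi))
        if sel.size == 0:
            qs = np.percentile(mean_up, [5, 25, 50, 75, 95])
            raise ValueError(
                f"no {sc} C2 neurons with mean upright response in "
                f"[{lo}, {hi}]; response percentiles (5/25/50/75/95): "
                f"{np.round(qs, 3).tolist()} — adjust synthetic-face "
                f"contrast or the band"
            )
        eligible[sc] = sel
    k = min(sel.size for sel in eligible.values())
    rng = np.random.default_rng([seed, 3])
    from .stats import wilcoxon_signed_rank

    sizes, per_face = {}, {}
    for sc, (up, inv) in c2.items():
        sel = eligible[sc]
        chosen = np.sort(rng.choice(sel, size=k, replace=False))
        diffs = up[:, chosen].mean(axis=1) - inv[:, chosen].mean(axis=1)
        per_face[sc] = diffs
        _, p_two = wilcoxon_signed_rank(diffs)
        sizes[sc] = {
            "n_neurons_in_band": int(sel.size),
            "n_neurons_used": int(k),
            "upright_mean_response": float(up[:, chosen].mean()),
            "inverted_mean_response": float(inv[:, chosen].mean()),
            "effect": float(diffs.mean()),
            "sem_over_faces": float(diffs.std(ddof=1) / np.sqrt(diffs.size)),
            "wilcoxon_p_two_sided": float(p_two),
        }
    comparisons = {}
    for a, b in itertools.combinations([s for s in ("large", "medium", "small") if s in c2], 2):
        d = per_face[a] - per_face[b]
        try:
            _, p_two = wilcoxon_signed_rank(d)
            p_one = p_two / 2 if np.median(d) > 0 else 1 - p_two / 2
        except ValueError:
            p_one = np.nan
        comparisons[f"{a}_gt_{b}_p"] = float(p_one)
    return ExperimentResult(
        "FIE_neural",
        sizes,
        comparisons,
        n_trials=len(face_specs),
        seed=seed,
        meta={"band": list(band) if band is not None else None, "n_neurons_used": int(k)},
    )


# ---------------------------------------------------------------------------
# Whole-Part Effect


def run_wpe(
    banks,
    face_specs: Sequence[FaceSpec],
    seed: int = 0,
    n_resamples: int = 1000,
    max_trials: Optional[int] = None,
    weight_study_face: bool = True,
    stim_config: Optional[StimulusConfig] = None,
    model_config: Optional[ModelConfig] = None,
) -> ExperimentResult:
    """Whole-part 2AFC memory experiment.

    Trials are ordered triples (A, B, C) of distinct identities: the study
    face blends A's eye region into C's face. In the Whole condition the
    choices are whole(A, C) (correct) and whole(B, C), attention-weighted
    (non-eye pixels x 0.5, recentered on the eyes); in the Part condition
    the choices are the cropped eye regions of those same weighted test
    faces. The simulated subject picks the choice with smaller C2 distance
    to the study face (ties resolved by a seeded coin flip and logged). The
    effect is Whole - Part accuracy, tested by one-sided neuron bootstrap.
    """
    stim = stim_config or StimulusConfig()
    model = model_config or ModelConfig()
    if hasattr(banks, "templates"):
        banks = {banks.size_class: banks}
    if len(face_specs) < 3:
        raise ValueError("WPE needs at least 3 identities")
    rng = np.random.default_rng(seed)
    faces = {s.identity_id: render(s, stim) for s in face_specs}
    ids = sorted(faces)
    eye_region = stim.derived_eye_region()

    images, study_ix, whole_ix, part_ix = [], {}, {}, {}
    for e in ids:
        for r in ids:
            if e == r:
                continue
            whole_raw, _ = make_whole_part_pair(faces[e], faces[r], stim)
            weighted = apply_attention(
                whole_raw, eye_region, stim.wpe_attention_factor, recenter=True,
                soften_px=stim.attention_soften_px,
            )
            part = crop_to_region(weighted, tuple(weighted.meta["attended_region"]))
            study = (
                apply_attention(
                    whole_raw, eye_region, stim.wpe_attention_factor, True,
                    soften_px=stim.attention_soften_px,
                )
                if weight_study_face
                else whole_raw
            )
            study_ix[(e, r)] = len(images); images.append(study)
            whole_ix[(e, r)] = len(images); images.append(weighted)
            part_ix[(e, r)] = len(images); images.append(part)
    c2 = extract_c2_batch(images, banks, model)

    triples = [
        (a, b, c)
        for a, b, c in itertools.permutations(ids, 3)
    ]
    if max_trials is not None and max_trials < len(triples):
        keep = rng.choice(len(triples), size=max_trials, replace=False)
        triples = [triples[t] for t in sorted(keep)]

    sizes, comparisons = {}, {}
    effects = {}
    for sc, mat in c2.items():
        mat = mat.astype(np.float32)
        n_neurons = mat.shape[1]
        s_idx = np.array([study_ix[(a, c)] for a, _, c in triples])
        d2 = {}
        for cond, ix in (("whole", whole_ix), ("part", part_ix)):
            corr = np.array([ix[(a, c)] for a, _, c in triples])
            foil = np.array([ix[(b, c)] for _, b, c in triples])
            d2[(cond, "correct")] = (mat[corr] - mat[s_idx]) ** 2
            d2[(cond, "foil")] = (mat[foil] - mat[s_idx]) ** 2

        tie_flips = {
            cond: rng.random(len(triples)) < 0.5 for cond in ("whole", "part")
        }

        def accuracy(cond, cnt):
            dc = d2[(cond, "correct")] @ cnt
            df = d2[(cond, "foil")] @ cnt
            correct = dc < df
            ties = dc == df
            if ties.any():
                correct = correct | (ties & tie_flips[cond])
            return float(correct.mean()), int(ties.sum())

        full = np.ones(n_neurons, dtype=np.float32)
        acc_w, ties_w = accuracy("whole", full)
        acc_p, ties_p = accuracy("part", full)
        boot = np.empty(n_resamples)
        brng = np.random.default_rng([seed, 4])
        for r in range(n_resamples):
            cnt = _counts(_resample_indices(brng, n_neurons, None), n_neurons)
            boot[r] = accuracy("whole", cnt)[0] - accuracy("part", cnt)[0]
        effects[sc] = boot
        sizes[sc] = {
            "whole_accuracy": acc_w,
            "part_accuracy": acc_p,
            "effect": acc_w - acc_p,
            "n_ties": {"whole": ties_w, "part": ties_p},
            "bootstrap": _bootstrap_summary(boot, acc_w - acc_p),
        }
    for a, b in itertools.combinations([s for s in ("large", "medium", "small") if s in sizes], 2):
        comparisons[f"{a}_gt_{b}_p"] = float(np.mean(effects[a] <= effects[b]))
    return ExperimentResult(
        "WPE",
        sizes,
        comparisons,
        n_trials=len(triples),
        seed=seed,
        meta={"n_identities": len(ids), "eye_region": list(eye_region),
              "weight_study_face": weight_study_face},
    )
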