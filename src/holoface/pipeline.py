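"""End-to-end orchestration: generate -> learn -> run all three experiments.

Train/test split follows the odd/even convention: odd-numbered identities
are used for template learning, even-numbered identities for normal
operation. All outputs (result JSONs, trial tables, manifest) embed the
config hash; a stored config plus the three seed streams reproduces every
output byte-for-byte on one platform.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Dict, Optional

from .config import RunConfig, config_hash
from .experiments import run_cfe, run_fie_behavioral, run_fie_neural, run_wpe
from .stimuli import generate_identity
from .templates import learn_bank, save_banks
from . import stimuli

logger = logging.getLogger("holoface")


def train_test_specs(config: RunConfig):
    """Odd identities train, even identities test."""
    exp = config.experiments
    n_test = max(exp.n_cfe_identities, exp.n_fie_identities, exp.n_wpe_identities)
    train = [
        generate_identity(2 * i + 1, config.stimulus_seed, config.stimuli)
        for i in range(exp.n_train_identities)
    ]
    test = [
        generate_identity(2 * i, config.stimulus_seed, config.stimuli)
        for i in range(n_test)
    ]
    return train, test


def run_all(config: RunConfig, out_dir: str, experiments=("cfe", "fie", "wpe")) -> dict:
    """Execute the full pipeline, writing a manifest of every output file."""
    os.makedirs(out_dir, exist_ok=True)
    chash = config_hash(config)
    manifest = {"config_hash": chash, "files": [], "stages": {}}
    config.to_yaml(os.path.join(out_dir, "config.yml"))
    manifest["files"].append("config.yml")

    def _stage(name):
        logger.info("stage %s starting", name)

    try:
        _stage("generate")
        train, test = train_test_specs(config)
        manifest["stages"]["generate"] = {
            "n_train": len(train), "n_test": len(test), "seed": config.stimulus_seed,
        }

        _stage("learn")
        train_imgs = [stimuli.render(s, config.stimuli) for s in train]
        banks = learn_bank(
            train_imgs,
            per_image=config.experiments.templates_per_image,
            seed=config.template_seed,
            config=config.model,
        )
        bank_path = os.path.join(out_dir, "banks.npz")
        save_banks(banks, bank_path)
        manifest["files"].append("banks.npz")
        manifest["stages"]["learn"] = {
            "n_templates": {sc: len(b) for sc, b in banks.items()},
            "seed": config.template_seed,
        }

        exp = config.experiments
        results: Dict[str, object] = {}
        if "cfe" in experiments:
            _stage("cfe")
            results["cfe"] = run_cfe(
                {sc: banks[sc] for sc in ("large", "small")},
                test[: exp.n_cfe_identities],
                seed=config.experiment_seed,
                n_resamples=exp.n_resamples,
                target_hit_rate=exp.target_hit_rate,
                max_trials=exp.cfe_max_trials,
                stim_config=config.stimuli,
                model_config=config.model,
            )
        if "fie" in experiments:
            _stage("fie")
            fie_faces = test[: exp.n_fie_identities]
            results["fie_behavioral"] = run_fie_behavioral(
                banks, fie_faces,
                seed=config.experiment_seed,
                n_resamples=exp.n_resamples,
                subsample=exp.fie_subsample,
                stim_config=config.stimuli,
                model_config=config.model,
            )
            results["fie_neural"] = run_fie_neural(
                banks, fie_faces,
                band=exp.neural_band,
                seed=config.experiment_seed,
                stim_config=config.stimuli,
                model_config=config.model,
            )
        if "wpe" in experiments:
            _stage("wpe")
            results["wpe"] = run_wpe(
                {sc: banks[sc] for sc in ("large", "small")},
                test[: exp.n_wpe_identities],
                seed=config.experiment_seed,
                n_resamples=exp.n_resamples,
                max_trials=exp.wpe_max_trials,
                weight_study_face=exp.weight_wpe_study_face,
                stim_config=config.stimuli,
                model_config=config.model,
            )
        for name, res in results.items():
            payload = res.to_dict()
            payload["config_hash"] = chash
            fname = f"{name}.json"
            with open(os.path.join(out_dir, fname), "w") as fh:
                json.dump(payload, fh, indent=2, default=float)
            manifest["files"].append(fname)
            if res.trials is not None:
                tname = f"{name}_trials.csv"
                res.trials.to_csv(os.path.join(out_dir, tname), index=False)
                manifest["files"].append(tname)
    except Exception as err:
        raise RuntimeError(f"pipeline aborted: {err}") from err

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
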