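"""Experiment orchestration: configuration, pipelines, reports, provenance.

Ties the modules into reproducible end-to-end experiments: simulate a
cohort, extract features, cross-validate the state decoder, run the
closed-loop stimulation arms, and run the emerging-state novelty suite.
All outputs are tidy CSV/JSON files plus a provenance manifest (config
hash, seeds, package versions); re-running a config reproduces every
number.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth, features, decode, control, novelty

__all__ = [
    "ExperimentConfig", "run_experiment", "permutation_chance",
    "cohort_frames", "cohort_dataset", "state_correlations",
]

log = logging.getLogger("cardioloop")


@dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment."""

    seed: int = 1
    n_subjects: int = 5
    protocols: list = field(default_factory=lambda: ["D", "D", "NE", "NE", "D+NE", "D+NE"])
    n_high_dose_subjects: int = 4
    decoder: dict = field(default_factory=dict)     # DecoderConfig overrides
    decoder_enabled: bool = True
    cv_folds: int = 10
    novelty_cfg: dict = field(default_factory=dict)  # NoveltyConfig overrides
    novelty_folds: int = 10
    novelty_enabled: bool = True
    arms_enabled: bool = True
    arm_runs: int = 3
    reversal_gain: float = 0.85
    n_permutations: int = 10
    out_dir: str = "results"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        return cls(**yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def permutation_chance(metric, labels, n: int = 10, seed: int = 0) -> dict:
    """Chance level of a label-dependent metric under label permutation.

    ``metric(permuted_labels)`` is evaluated for ``n`` random permutations
    of ``labels``; returns mean, SD and the individual values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    values = []
    for _ in range(n):
        values.append(float(metric(rng.permutation(labels))))
    return {"mean": float(np.mean(values)), "sd": float(np.std(values)),
            "values": values}


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def cohort_frames(n_subjects, protocols, seed, subject_overrides=None):
    """Simulate a cohort and extract the feature frame of every recording."""
    records = synth.generate_cohort(n_subjects, protocols, seed=seed,
                                    subject_overrides=subject_overrides)
    frames = []
    for rec in records:
        fr = features.extract_features(rec)
        fr.meta.update(state=rec.meta["state"],
                       subject_id=rec.meta["subject_id"],
                       timeline=dict(rec.protocol.timeline))
        frames.append(fr)
    return records, frames


def cohort_dataset(n_subjects, protocols, seed, subject_overrides=None):
    _, frames = cohort_frames(n_subjects, protocols, seed, subject_overrides)
    return decode.build_dataset(frames)


def state_correlations(dataset: decode.LabeledSequenceSet) -> dict:
    """Within-subject Pearson correlations between infusion-pair feature
    time series (the state-overlap calibration check).

    For each subject and each pair of infusion types, the standardized
    13 x T step matrices of the two recordings are correlated (flattened);
    replicate pairs are averaged.  Returns mean R per pair label.
    """
    from itertools import combinations

    by_subj: dict = {}
    for i, (st, su) in enumerate(zip(dataset.record_states, dataset.subject_ids)):
        if st != "rest":
            by_subj.setdefault(su, []).append(i)
    pair_vals: dict = {}
    for su, idx in by_subj.items():
        for a, b in combinations(idx, 2):
            sa, sb = dataset.record_states[a], dataset.record_states[b]
            if sa == sb:
                continue
            key = "|".join(sorted((sa, sb)))
            xa, xb = dataset.sequences[a], dataset.sequences[b]
            T = min(xa.shape[0], xb.shape[0])
            r = float(np.corrcoef(xa[:T].ravel(), xb[:T].ravel())[0, 1])
            pair_vals.setdefault(key, []).append(r)
    return {k: float(np.mean(v)) for k, v in sorted(pair_vals.items())}


def _stage(name, manifest):
    class _Timer:
        def __enter__(self):
            self.t0 = time.time()
            log.info("stage %s ...", name)
            return self

        def __exit__(self, *exc):
            manifest["stages"][name] = round(time.time() - self.t0, 2)
            log.info("stage %s done in %.1f s", name, time.time() - self.t0)
    return _Timer()


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute simulate -> extract -> decode -> control -> novelty.

    Writes the five canonical result tables (confusion matrix, per-class
    sensitivity + chance, ablation-style feature table, arm outcome table,
    novelty scenario table) under ``config.out_dir`` with a provenance
    manifest.  Any stage failure aborts with stage-tagged context.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": {}, "versions": _versions()}
    (out / "config.yaml").write_text(config.to_yaml())
    results: dict = {"manifest": manifest}

    try:
        with _stage("simulate+extract", manifest):
            dataset = cohort_dataset(config.n_subjects, config.protocols, config.seed)
            results["state_correlations"] = state_correlations(dataset)
            pd.Series(results["state_correlations"]).rename("pearson_r") \
                .to_csv(out / "state_correlations.csv")
    except Exception as exc:
        raise RuntimeError("stage simulate+extract failed") from exc

    model = None
    dec_cfg = decode.DecoderConfig(**{"seed": config.seed, **config.decoder})
    if config.decoder_enabled:
        try:
            with _stage("decode", manifest):
                report = decode.crossvalidate(dataset, dec_cfg, k=config.cv_folds,
                                              seed=config.seed)
                chance = permutation_chance(
                    lambda lab: float(np.mean(lab == _all_step_labels(dataset))),
                    _all_step_labels(dataset), n=config.n_permutations,
                    seed=config.seed)
                report.chance = chance
                results["decoder"] = report
                pd.DataFrame(report.confusion, index=decode.CLASSES,
                             columns=decode.CLASSES).to_csv(out / "confusion_matrix.csv")
                pd.DataFrame({
                    "class": decode.CLASSES,
                    "sensitivity": report.per_class_sensitivity,
                }).to_csv(out / "per_class_sensitivity.csv", index=False)
                model = decode.train(dataset, dec_cfg)
        except Exception as exc:
            raise RuntimeError("stage decode failed") from exc

    if config.arms_enabled:
        if not config.decoder_enabled:
            raise RuntimeError(
                "stage control failed: closed-loop arms need the decoder enabled")
        try:
            with _stage("control", manifest):
                arm_rows = []
                for arm in control.ARMS:
                    res = control.run_arm(
                        arm, model=model, n_runs=config.arm_runs,
                        seed=config.seed, reversal_gain=config.reversal_gain)
                    for i, oc in enumerate(res["outcomes"]):
                        arm_rows.append({"arm": arm, "run": i,
                                         "on_time": res["on_times"][i],
                                         "charge_uc": res["charges_uc"][i], **oc})
                results["arms"] = arm_rows
                pd.DataFrame(arm_rows).to_csv(out / "arm_outcomes.csv", index=False)
        except Exception as exc:
            raise RuntimeError("stage control failed") from exc

    if config.novelty_enabled:
        try:
            with _stage("novelty", manifest):
                high = cohort_dataset(
                    config.n_high_dose_subjects,
                    ["H-D", "H-NE", "H-D+NE"], config.seed + 1)
                nov_cfg = novelty.NoveltyConfig(**{"seed": config.seed,
                                                   **config.novelty_cfg})
                suite = novelty.run_novelty_suite(
                    dataset, high, nov_cfg, k=config.novelty_folds,
                    seed=config.seed)
                results["novelty"] = suite
                rows = [r for f in suite["folds"] for r in f.get("scenario_rows", [])]
                pd.DataFrame(rows).to_csv(out / "novelty_scenarios.csv", index=False)
                pd.DataFrame([{k: v for k, v in f.items() if not isinstance(v, list)}
                              for f in suite["folds"]]).to_csv(
                    out / "novelty_folds.csv", index=False)
        except Exception as exc:
            raise RuntimeError("stage novelty failed") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


def _all_step_labels(dataset):
    y = np.concatenate(dataset.labels)
    return y[y >= 0]


def _versions() -> dict:
    import importlib.metadata as im
    out = {}
    for pkg in ("numpy", "scipy", "pandas", "scikit-learn", "umap-learn"):
        try:
            out[pkg] = im.version(pkg)
        except im.PackageNotFoundError:
            out[pkg] = "unknown"
    return out
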