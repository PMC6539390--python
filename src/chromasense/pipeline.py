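"""End-to-end study orchestration: simulate -> split -> select -> report.

One :func:`run_pipeline` call reproduces the whole study from a config
and a seed: a synthetic multi-batch dataset, the batch-wise
calibration/validation split, repeated ACO wrapper-selection runs, the
component-frequency table, and the case comparison in which a fresh BPNN
is refit many times on each frequency-thresholded component set and its
metrics summarized.  Every output records the config hash and seed; no
timestamps are written, so identical inputs give byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import aco, evaluation, synthetic
from .bpnn import BPNNRegressor, TrainConfig

__all__ = ["PipelineConfig", "run_pipeline", "evaluate_case"]


@dataclass
class PipelineConfig:
    """Study-level configuration; defaults are the full protocol scale."""

    seed: int = 0
    n_batches: int = 8
    n_cal_batches: int = 6
    response_model: str = "default"      # or "two_component"
    response_noise_sd: float = 2.0
    write_images: bool = False
    target: str = "od_measured"
    # ACO block
    n_ants: int = 20
    max_iterations: int = 100
    n_runs: int = 50
    evaporation: float = 0.05
    evaporation_mode: str = "conventional"
    visibility_mode: str = "abs_correlation"
    # BPNN block (selection-time trainings use selection_max_epochs)
    n_hidden: int = 10
    learning_rate: float = 0.1
    momentum: float = 0.1
    init_weight_scale: float = 0.3
    error_goal: float = 0.01
    max_epochs: int = 1000
    selection_max_epochs: int = 200
    # reporting block
    frequency_thresholds: tuple[int, ...] = (25, 20, 15)
    case_repeats: int = 50

    def __post_init__(self) -> None:
        if any(t > self.n_runs for t in self.frequency_thresholds):
            raise ValueError("frequency thresholds cannot exceed n_runs")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "frequency_thresholds" in doc:
            doc["frequency_thresholds"] = tuple(doc["frequency_thresholds"])
        return cls(**doc)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _response(config: PipelineConfig) -> synthetic.ResponseModel:
    factory = {"default": synthetic.ResponseModel.default,
               "two_component": synthetic.ResponseModel.two_component}
    try:
        return factory[config.response_model](noise_sd=config.response_noise_sd)
    except KeyError:
        raise ValueError(f"unknown response_model {config.response_model!r}")


def _train_config(config: PipelineConfig, max_epochs: int,
                  seed: int | None = None) -> TrainConfig:
    return TrainConfig(
        n_hidden=config.n_hidden, learning_rate=config.learning_rate,
        momentum=config.momentum, init_weight_scale=config.init_weight_scale,
        error_goal=config.error_goal, max_epochs=max_epochs, seed=seed)


def evaluate_case(split: evaluation.SplitDataset, components: list[int],
                  config: PipelineConfig, base_seed: int) -> dict:
    """Refit the BPNN ``case_repeats`` times on one component set.

    Mirrors the study's case comparison: every repeat re-initializes the
    network from a fresh seed and the four metrics are summarized over
    repeats (mean, sample variance, sd).
    """
    X_cal, y_cal = split.xy("calibration", config.target)
    X_val, y_val = split.xy("validation", config.target)
    metrics: dict[str, list[float]] = {m: [] for m in
                                       ("Rc2", "RMSECV", "Rp2", "RMSEP")}
    for rep in range(config.case_repeats):
        est = BPNNRegressor(
            n_hidden=config.n_hidden, learning_rate=config.learning_rate,
            momentum=config.momentum,
            init_weight_scale=config.init_weight_scale,
            error_goal=config.error_goal, max_epochs=config.max_epochs,
            random_state=base_seed + rep)
        est.fit(X_cal[:, components], y_cal)
        pc, pv = est.predict(X_cal[:, components]), est.predict(X_val[:, components])
        metrics["Rc2"].append(evaluation.r2(y_cal, pc))
        metrics["RMSECV"].append(evaluation.rmse(y_cal, pc))
        metrics["Rp2"].append(evaluation.r2(y_val, pv))
        metrics["RMSEP"].append(evaluation.rmse(y_val, pv))
    out = {}
    for name, vals in metrics.items():
        s = evaluation.summarize_runs(vals)
        out[name] = {"mean": s.mean, "variance": s.variance, "sd": s.sd}
    return out


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full study and write the report bundle under ``outdir``.

    Writes dataset.csv, runs.json, frequency.csv, cases.csv and
    report.json (plus per-sample image pairs when requested) and returns
    the report dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        design = synthetic.DatasetDesign(response=_response(config))
        records = synthetic.generate_dataset(config.n_batches, design,
                                             seed=config.seed)
        frame = synthetic.dataset_to_frame(records)
        frame.to_csv(outdir / "dataset.csv", index=False)
        if config.write_images:
            _write_images(records, outdir / "images", config.seed)

        stage = "split"
        split = evaluation.split_by_batch(frame, config.n_cal_batches)

        stage = "select"
        aco_cfg = aco.ACOConfig(
            n_ants=config.n_ants, max_iterations=config.max_iterations,
            evaporation=config.evaporation,
            evaporation_mode=config.evaporation_mode,
            visibility_mode=config.visibility_mode)
        sel_tc = _train_config(config, config.selection_max_epochs)
        results, freq = aco.repeat_runs(split, aco_cfg, sel_tc,
                                        n_runs=config.n_runs,
                                        base_seed=config.seed,
                                        target=config.target)
        _write_runs(results, outdir / "runs.json", config)
        _write_frequency(freq, outdir / "frequency.csv")

        stage = "evaluate"
        cases = []
        for case_no, threshold in enumerate(config.frequency_thresholds, 1):
            comps = aco.select_by_frequency(freq, threshold)
            row = {"case": case_no, "threshold": threshold,
                   "n_components": len(comps),
                   "components": [synthetic.FEATURE_NAMES[i] for i in comps]}
            if comps:
                row["metrics"] = evaluate_case(
                    split, comps, config,
                    base_seed=config.seed + 1000 * case_no)
            else:
                row["metrics"] = None
            cases.append(row)

        stage = "report"
        report = {
            "config_hash": config.hash(),
            "seed": config.seed,
            "sign_convention": "after_minus_before",
            "n_samples": int(len(frame)),
            "n_calibration": int(len(split.calibration)),
            "n_validation": int(len(split.validation)),
            "best_cost": float(min(r.best_solution.cost for r in results)),
            "frequency": {synthetic.FEATURE_NAMES[i]: int(c)
                          for i, c in enumerate(freq.counts)},
            "cases": cases,
        }
        _write_cases_csv(cases, outdir / "cases.csv")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_images(records, imgdir: Path, seed: int) -> None:
    from PIL import Image

    imgdir.mkdir(parents=True, exist_ok=True)
    layout = synthetic.SensorLayout()
    rng = np.random.default_rng(seed + 777)
    for rec in records:
        pair = synthetic.render_image_pair(rec.features, layout, rng)
        Image.fromarray(pair.before).save(imgdir / f"{rec.sample_id}_pre.png")
        Image.fromarray(pair.after).save(imgdir / f"{rec.sample_id}_post.png")
    with open(imgdir / "layout.yaml", "w") as fh:
        yaml.safe_dump(layout.to_dict(), fh, sort_keys=True)


def _write_runs(results, path: Path, config: PipelineConfig) -> None:
    doc = {
        "config_hash": config.hash(),
        "runs": [
            {
                "seed": r.seed,
                "best_mask": [int(i) for i in
                              np.flatnonzero(r.best_solution.mask)],
                "best_cost": float(r.best_solution.cost),
                "metrics": {k: float(v)
                            for k, v in r.best_solution.metrics.items()},
                "convergence_curve": [float(c) for c in r.convergence_curve],
                "convergence_iteration": int(r.convergence_iteration),
            }
            for r in results
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)


def _write_frequency(freq, path: Path) -> None:
    import pandas as pd

    dyes = [n.split(":")[0] for n in synthetic.FEATURE_NAMES]
    chans = [n.split(":")[1] for n in synthetic.FEATURE_NAMES]
    pd.DataFrame({"component": synthetic.FEATURE_NAMES, "dye": dyes,
                  "channel": chans, "count": freq.counts}
                 ).to_csv(path, index=False)


def _write_cases_csv(cases, path: Path) -> None:
    import pandas as pd

    rows = []
    for c in cases:
        row = {"case": c["case"], "threshold": c["threshold"],
               "n_components": c["n_components"],
               "components": "|".join(c["components"])}
        if c["metrics"]:
            for m, s in c["metrics"].items():
                row[f"{m}_mean"] = s["mean"]
                row[f"{m}_variance"] = s["variance"]
                row[f"{m}_sd"] = s["sd"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
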