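"""End-to-end benchmark orchestration.

One config drives generate -> train -> attribute -> correct -> evaluate ->
angle diagnostics; every stage writes files the next stage can consume, so
stages are also independently runnable from the CLI.  Per-trial seeds derive
deterministically from the master seed and trial index.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import roc_auc_score

from . import io as sgio
from .attribution import AttributionConfig, attribute
from .correction import GradientCorrector, gradient_angles
from .evaluation import evaluate_maps
from .models import ModelSpec, TrainConfig, build_model, train
from .synthetic import DatasetSplits, generate_dataset

DEFAULT_MODELS = [
    ("shallow", "relu"),
    ("shallow", "exponential"),
    ("deep", "relu"),
    ("deep", "exponential"),
]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one benchmark run."""

    n_sequences: int = 20_000
    length: int = 200
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    models: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_MODELS))
    methods: list[str] = field(default_factory=lambda: ["saliency"])
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    attribution: dict = field(default_factory=dict)  # AttributionConfig overrides
    angle_thresholds: tuple[float, ...] = (30.0, 45.0, 60.0)
    n_trials: int = 1
    n_test_eval: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        self.fractions = tuple(self.fractions)
        self.models = [tuple(m) for m in self.models]
        self.angle_thresholds = tuple(self.angle_thresholds)

    @classmethod
    def smoke(cls, seed: int = 0) -> "ExperimentConfig":
        """Desk-scale preset: 2,000 sequences, 2 trials, CNN-deep-relu, saliency only."""
        return cls(
            n_sequences=2_000,
            models=[("deep", "relu")],
            methods=["saliency"],
            n_trials=2,
            n_test_eval=200,
            train={"epochs": 20},
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(json.loads(json.dumps(asdict(self)))))

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


def trial_seed(master_seed: int, trial: int) -> int:
    """Deterministic per-trial seed below 2**31."""
    return int(np.random.SeedSequence([int(master_seed), int(trial)]).generate_state(1)[0] % (2**31))


def run_benchmark(config: ExperimentConfig, out_dir, dataset: DatasetSplits | None = None) -> dict:
    """Run the full benchmark; returns report tables and writes artifacts.

    For each trial x model x method: train from a trial-specific
    initialization, attribute held-out test sequences, correct the maps,
    score both versions against ground truth, and record angle-exceedance
    fractions.  A failing combination is logged and skipped; the rest
    continue.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "benchmark.log.jsonl"

    def log(**entry):
        entry["time"] = time.time()
        with log_path.open("a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")

    config.to_yaml(out / "config.yaml")
    log(stage="start", config_digest=config.digest, seed=config.seed)

    if dataset is None:
        t0 = time.time()
        dataset = generate_dataset(
            n=config.n_sequences,
            fractions=config.fractions,
            seed=config.seed,
            length=config.length,
        )
        log(stage="generate", n=config.n_sequences, seconds=time.time() - t0)

    X_te, y_te, M_te = dataset.arrays("test")
    n_eval = min(config.n_test_eval, len(X_te))
    X_ev, M_ev = X_te[:n_eval], M_te[:n_eval]

    corrector = GradientCorrector()
    report_rows: list[pd.DataFrame] = []
    angle_rows = []
    failures = []

    for trial in range(config.n_trials):
        seed = trial_seed(config.seed, trial)
        for arch, act in config.models:
            model_name = f"cnn-{arch}-{'exp' if act.startswith('exp') else act}"
            try:
                t0 = time.time()
                spec = ModelSpec(architecture=arch, first_layer_activation=act, input_length=config.length)
                cfg = TrainConfig(**{**config.train, "seed": seed})
                model = train(build_model(spec, seed=seed), dataset, cfg)
                test_auc = float(roc_auc_score(y_te, model.predict_proba(X_te)[:, 1]))
                log(stage="train", trial=trial, model=model_name, seed=seed,
                    best_val_auc=model.best_val_auc_, test_auc=test_auc,
                    epochs_run=len(model.history_["loss"]), seconds=time.time() - t0)
            except Exception as exc:  # noqa: BLE001 - stage isolation
                failures.append({"trial": trial, "model": model_name, "stage": "train", "error": str(exc)})
                log(stage="train-failed", trial=trial, model=model_name, error=str(exc))
                continue

            for method in config.methods:
                try:
                    t0 = time.time()
                    attr_cfg = AttributionConfig(
                        **{**config.attribution, "method": method, "seed": seed}
                    )
                    maps = attribute(model, X_ev, attr_cfg)
                    corrected = corrector.fit_transform(maps)

                    before = evaluate_maps(maps, X_ev, M_ev)
                    after = evaluate_maps(corrected, X_ev, M_ev)
                    for df, when in ((before, "before"), (after, "after")):
                        df.insert(0, "method", method)
                        df.insert(0, "model", model_name)
                        df.insert(0, "trial", trial)
                        df.insert(3, "corrected", when)
                    report_rows.extend([before, after])

                    exceed = corrector.exceedance_summary(maps, config.angle_thresholds)
                    angle_rows.append(
                        {
                            "trial": trial,
                            "model": model_name,
                            "method": method,
                            "test_auc": test_auc,
                            **{f"frac_gt_{int(t)}deg": v for t, v in exceed.items()},
                        }
                    )
                    log(stage="attribute", trial=trial, model=model_name, method=method,
                        n_maps=n_eval, seconds=time.time() - t0)
                except Exception as exc:  # noqa: BLE001
                    failures.append(
                        {"trial": trial, "model": model_name, "method": method,
                         "stage": "attribute", "error": str(exc)}
                    )
                    log(stage="attribute-failed", trial=trial, model=model_name,
                        method=method, error=str(exc))

    report = pd.concat(report_rows, ignore_index=True) if report_rows else pd.DataFrame()
    angles = pd.DataFrame(angle_rows)
    report.to_csv(out / "report.tsv", sep="\t", index=False)
    angles.to_csv(out / "angles.tsv", sep="\t", index=False)

    summary = summarize_report(report) if len(report) else pd.DataFrame()
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(
        json.dumps(
            {
                "config_digest": config.digest,
                "seed": config.seed,
                "n_failures": len(failures),
                "failures": failures,
                "improvement": summary.to_dict(orient="records"),
                "angles": angles.to_dict(orient="records"),
            },
            indent=2,
            default=float,
        )
    )
    log(stage="done", failures=len(failures))
    return {"report": report, "angles": angles, "summary": summary, "failures": failures, "out_dir": out}


def summarize_report(report: pd.DataFrame) -> pd.DataFrame:
    """Median per trial/model/method improvement (after - before) for each metric."""
    keys = ["trial", "model", "method"]
    metrics = ["cosine", "auroc", "aupr"]
    before = report[report["corrected"] == "before"].set_index(keys + ["sequence"])[metrics]
    after = report[report["corrected"] == "after"].set_index(keys + ["sequence"])[metrics]
    delta = (after - before).reset_index()
    return (
        delta.groupby(keys)[metrics]
        .median()
        .rename(columns={m: f"median_delta_{m}" for m in metrics})
        .reset_index()
    )


def correct_file(attr_file, out_file, angles_file=None) -> int:
    """Apply the simplex correction to every map in a file; same format out.

    Also writes a per-sequence angle profile TSV when ``angles_file`` is
    given.  Returns the number of records processed.
    """
    maps = sgio.read_attributions(attr_file)
    corrected = GradientCorrector().fit_transform(maps)
    sgio.write_attributions(corrected, out_file)
    if angles_file is not None:
        rows = []
        for m in maps:
            prof = gradient_angles(m)
            for pos, (ang, ok) in enumerate(zip(prof.angles, prof.valid_mask)):
                rows.append(
                    {"sequence_id": m.sequence_id, "position": pos,
                     "angle_deg": ang if ok else np.nan, "valid": bool(ok)}
                )
        pd.DataFrame(rows).to_csv(angles_file, sep="\t", index=False)
    return len(maps)
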