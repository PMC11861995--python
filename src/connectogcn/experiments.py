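"""Study orchestration: run the evaluation regimes, the architecture
exploration grid (depth, pooling/aggregation, skip ablation) and the FGSM
sweep from one declarative config, writing tidy CSVs, figures, a JSON summary
and a log.

Reproducibility scheme: a single global seed fans out to per-experiment seeds
as ``seed_k = (global_seed * 100003 + k) mod 2^31`` where ``k`` is the
experiment's position in a fixed registration order; every output artifact
records the config and seed that produced it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import yaml

from .adversarial import AttackConfig, AttackResult, robustness_sweep
from .io import load_manifest
from .models import DEEP_MODELS, SHALLOW_MODELS, ModelSpec
from .synthetic import SyntheticConfig, generate_dataset
from .training import EvalReport, REGIMES, TrainConfig, run_regime

__all__ = ["StudyConfig", "run_study", "load_manifest", "derive_seed", "build_specs"]

log = logging.getLogger("connectogcn")

DEPTH_GRID = {"gcn_simple": (2, 3, 4, 5), "gcn_residual": (2, 3, 4)}
LAYER_WIDTH = {"gcn_simple": 64, "gcn_residual": 32}


def derive_seed(global_seed: int, k: int) -> int:
    """Documented fan-out: independent experiments get disjoint RNG streams
    while remaining reproducible from one global seed."""
    return (global_seed * 100003 + k) % 2**31


@dataclass
class StudyConfig:
    """Declarative description of a full study run."""

    synthetic: dict | None = None  # SyntheticConfig fields
    manifest: str | None = None  # alternative: load a written dataset
    regimes: tuple[str, ...] = ("enriched",)
    models: tuple[str, ...] = DEEP_MODELS + SHALLOW_MODELS
    explore_depth: bool = False
    explore_pooling: bool = False
    ablate_skips: bool = False
    attack: dict | None = None  # AttackConfig fields; models from `models`
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    seed: int = 0
    outdir: str = "study_out"

    def __post_init__(self):
        if self.synthetic is None and self.manifest is None:
            raise ValueError("config needs either a synthetic section or a manifest path")
        unknown = set(self.regimes) - set(REGIMES)
        if unknown:
            raise ValueError(f"unknown regimes {sorted(unknown)}")
        unknown = set(self.models) - set(DEEP_MODELS + SHALLOW_MODELS)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("regimes", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def build_specs(names, n_regions: int, **overrides) -> list[ModelSpec]:
    return [ModelSpec(name=n, n_regions=n_regions, **overrides) for n in names]


def _load_data(config: StudyConfig):
    if config.manifest is not None:
        return load_manifest(config.manifest)
    return generate_dataset(SyntheticConfig(**config.synthetic))


def _save_report(report: EvalReport, outdir: Path, tag: str, seed: int) -> dict:
    report.to_csv(outdir / f"{tag}_folds.csv")
    summary = report.summary()
    summary.to_csv(outdir / f"{tag}_summary.csv", index=False)
    curves_rows = []
    for (model, fold), curves in report.loss_curves.items():
        for epoch, (tr, va) in enumerate(zip(curves["train_loss"], curves["val_loss"])):
            curves_rows.append(dict(model=model, fold=fold, epoch=epoch,
                                    train_loss=tr, val_loss=va))
    if curves_rows:
        pd.DataFrame(curves_rows).to_csv(outdir / f"{tag}_loss_curves.csv", index=False)
        _plot_losses(report, outdir / f"{tag}_loss_curves.png")
    if report.roc_curves:
        _plot_rocs(report, outdir / f"{tag}_roc.png")
    _plot_accuracy_bars(summary, outdir / f"{tag}_accuracy.png")
    return {"tag": tag, "seed": seed, "summary": summary.to_dict(orient="records")}


def _plot_losses(report: EvalReport, path: Path) -> None:
    models = sorted({m for (m, _) in report.loss_curves})
    fig, axes = plt.subplots(1, max(len(models), 1), figsize=(4 * max(len(models), 1), 3),
                             squeeze=False)
    for ax, model in zip(axes[0], models):
        curves = report.loss_curves[(model, 0)]
        ax.plot(curves["train_loss"], label="train")
        ax.plot(curves["val_loss"], label="validation")
        ax.set_title(model)
        ax.set_xlabel("epoch")
        ax.set_ylabel("weighted BCE")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_rocs(report: EvalReport, path: Path) -> None:
    models = sorted({m for (m, _, _) in report.roc_curves})
    fig, axes = plt.subplots(1, max(len(models), 1), figsize=(4 * max(len(models), 1), 3.5),
                             squeeze=False)
    for ax, model in zip(axes[0], models):
        for (m, fold, stratum), (fpr, tpr) in report.roc_curves.items():
            if m == model and fold == 0:
                ax.plot(fpr, tpr, label=stratum)
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_title(model)
        ax.set_xlabel("FPR")
        ax.set_ylabel("TPR")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_accuracy_bars(summary: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 3.5))
    piv = summary.pivot_table(index="model", columns="stratum", values="accuracy_mean")
    err = summary.pivot_table(index="model", columns="stratum", values="accuracy_sd")
    piv.plot.bar(ax=ax, yerr=err, rot=0)
    ax.set_ylabel("accuracy (%)")
    ax.axhline(50, color="k", lw=0.6, ls=":")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_attack(result: AttackResult, path: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    s = result.summary()
    for model, sub in s.groupby("model"):
        axes[0].errorbar(sub["epsilon"], sub["accuracy_mean"], yerr=sub["accuracy_sd"],
                         marker="o", label=model)
        axes[1].errorbar(sub["epsilon"], sub["auc_mean"], yerr=sub["auc_sd"],
                         marker="o", label=model)
    for ax, ylab in zip(axes, ("accuracy (%)", "AUC")):
        ax.set_xscale("symlog", linthresh=1e-5)
        ax.set_xlabel("epsilon")
        ax.set_ylabel(ylab)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_study(config: StudyConfig) -> Path:
    """Execute the configured study; returns the output directory.

    Idempotent given identical config + seed.  Partial failures are isolated
    per experiment and marked in the JSON summary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "study.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    summary: dict = {"config": asdict(config), "experiments": []}
    try:
        dataset = _load_data(config)
        n_regions = dataset[0].n_regions
        log.info("dataset: %d subjects, %d regions", len(dataset), n_regions)

        counter = 0
        enriched_reports: dict[str, EvalReport] = {}

        for regime in config.regimes:
            seed = derive_seed(config.seed, counter)
            counter += 1
            tag = f"regime_{regime}"
            try:
                specs = build_specs(config.models, n_regions)
                tc = TrainConfig(seed=seed, **config.train)
                report = run_regime(regime, specs, dataset, tc)
                if regime == "enriched":
                    enriched_reports["default"] = report
                summary["experiments"].append(_save_report(report, outdir, tag, seed))
                log.info("finished %s", tag)
            except Exception as exc:  # isolate per-experiment failures
                log.exception("experiment %s failed", tag)
                summary["experiments"].append({"tag": tag, "seed": seed, "error": str(exc)})

        explore_jobs = []
        if config.explore_depth:
            for name, depths in DEPTH_GRID.items():
                if name in config.models:
                    for depth in depths:
                        widths = (LAYER_WIDTH[name],) * depth
                        explore_jobs.append(
                            (f"depth_{name}_{depth}", [ModelSpec(name=name, n_regions=n_regions,
                                                                 gcn_widths=widths)])
                        )
        if config.explore_pooling:
            if "gcn_simple" in config.models:
                explore_jobs.append(
                    ("pooling_gcn_simple_max",
                     [ModelSpec(name="gcn_simple", n_regions=n_regions, pooling="max")])
                )
            if "gcn_residual" in config.models:
                explore_jobs.append(
                    ("aggregation_gcn_residual_max",
                     [ModelSpec(name="gcn_residual", n_regions=n_regions, aggregation="max")])
                )
        if config.ablate_skips and "gcn_residual" in config.models:
            explore_jobs.append(
                ("skip_ablation_gcn_residual",
                 [ModelSpec(name="gcn_residual", n_regions=n_regions, use_skips=False)])
            )

        for tag, specs in explore_jobs:
            seed = derive_seed(config.seed, counter)
            counter += 1
            try:
                tc = TrainConfig(seed=seed, **config.train)
                report = run_regime("enriched", specs, dataset, tc)
                summary["experiments"].append(_save_report(report, outdir, tag, seed))
                log.info("finished %s", tag)
            except Exception as exc:
                log.exception("experiment %s failed", tag)
                summary["experiments"].append({"tag": tag, "seed": seed, "error": str(exc)})

        if config.attack is not None:
            seed = derive_seed(config.seed, counter)
            counter += 1
            tag = "fgsm_sweep"
            try:
                ac = AttackConfig(seed=seed, **config.attack)
                report = enriched_reports.get("default")
                if report is None:
                    specs = build_specs([m for m in config.models if m in DEEP_MODELS], n_regions)
                    report = run_regime("enriched", specs, dataset, TrainConfig(seed=seed, **config.train))
                tables = []
                for name in config.models:
                    if name not in DEEP_MODELS:
                        continue
                    models_by_fold = {f: m for (n, f), m in report.models.items() if n == name}
                    res = robustness_sweep(models_by_fold, dataset, report.plans["deep"], ac)
                    tables.append(res.table)
                result = AttackResult(table=pd.concat(tables, ignore_index=True))
                result.table.to_csv(outdir / f"{tag}.csv", index=False)
                _plot_attack(result, outdir / f"{tag}.png")
                summary["experiments"].append(
                    {"tag": tag, "seed": seed,
                     "summary": result.summary().to_dict(orient="records")}
                )
                log.info("finished %s", tag)
            except Exception as exc:
                log.exception("experiment %s failed", tag)
                summary["experiments"].append({"tag": tag, "seed": seed, "error": str(exc)})
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return outdir
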