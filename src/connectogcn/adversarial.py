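"""FGSM white-box adversarial attack and epsilon-sweep robustness protocol.

The fast gradient sign method perturbs the node feature matrix of each test
subject by ``X_adv = X + eps * sign(dL/dX)`` where ``L`` is the same weighted
binary cross entropy the model was trained with, evaluated at the true label.
The adjacency used for message passing stays clean even when features were
derived from it: only ``X`` is attacked.  The sweep re-evaluates each
cross-validation fold's test subjects (in a target cohort stratum) with that
fold's own model across a grid of perturbation sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import DEEP_MODELS
from .training import SplitPlan, _metrics
from .synthetic import ConnectomeGraph

__all__ = ["AttackConfig", "AttackResult", "fgsm_perturb", "robustness_sweep", "default_epsilons"]


def default_epsilons() -> np.ndarray:
    """0 plus a geometric grid spanning 1e-5 … 1e-3."""
    return np.concatenate([[0.0], np.geomspace(1e-5, 1e-3, 9)])


@dataclass(frozen=True)
class AttackConfig:
    epsilons: tuple[float, ...] = tuple(default_epsilons())
    target_stratum: str = "pediatric"
    clip_nonnegative: bool = False  # whether to project perturbed features back to >= 0
    resymmetrize: bool = False
    seed: int = 0

    def __post_init__(self):
        eps = np.asarray(self.epsilons, dtype=float)
        if (eps < 0).any():
            raise ValueError("epsilons must be non-negative")
        if not np.all(np.diff(eps) >= 0):
            raise ValueError("epsilons must be sorted ascending")
        if self.target_stratum not in ("adult", "pediatric", "overall"):
            raise ValueError(f"unknown target stratum {self.target_stratum!r}")


@dataclass
class AttackResult:
    """Per-epsilon, per-fold accuracy/AUC; the epsilon=0 row is the clean
    evaluation exactly."""

    table: pd.DataFrame
    perturbed: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby(["model", "epsilon"], sort=True)
        return g.agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_sd=("accuracy", lambda s: s.std(ddof=1)),
            auc_mean=("auc", "mean"),
            auc_sd=("auc", lambda s: s.std(ddof=1)),
        ).reset_index()


def _perturb_batch(model, graphs: list[ConnectomeGraph], epsilon: float,
                   clip_nonnegative: bool = False, resymmetrize: bool = False) -> np.ndarray:
    if not getattr(model, "is_deep", False):
        raise TypeError("FGSM requires a differentiable model; RF/SVM have no gradient")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    _, X = model.prepare(graphs)
    if epsilon == 0:
        return X
    dX = model.input_gradient(graphs)
    X_adv = X + epsilon * np.sign(dX)  # sign(0) = 0
    if clip_nonnegative:
        X_adv = np.clip(X_adv, 0.0, None)
    if resymmetrize:
        X_adv = (X_adv + np.swapaxes(X_adv, 1, 2)) / 2.0
    return X_adv


def fgsm_perturb(model, graph: ConnectomeGraph, epsilon: float,
                 clip_nonnegative: bool = False, resymmetrize: bool = False) -> np.ndarray:
    """Perturbed node feature matrix for one subject.

    The loss gradient is taken at the true label (untargeted FGSM, ascending
    the training loss).  At ``epsilon=0`` the features are returned unchanged.
    """
    return _perturb_batch(model, [graph], epsilon, clip_nonnegative, resymmetrize)[0]


def robustness_sweep(
    models_by_fold: dict[int, object],
    dataset: list[ConnectomeGraph],
    plan: SplitPlan,
    config: AttackConfig = AttackConfig(),
    model_name: str | None = None,
    keep_perturbed: bool = False,
) -> AttackResult:
    """White-box epsilon sweep over the CV test sets of a target stratum.

    For each fold and epsilon, every test subject in ``target_stratum`` is
    perturbed with that fold's own model and re-scored by the same model;
    accuracy/AUC aggregate to mean ± SD across folds.
    """
    rows = []
    perturbed = {}
    for fold, model in sorted(models_by_fold.items()):
        if not getattr(model, "is_deep", False):
            raise TypeError("robustness_sweep applies to deep models only")
        test_graphs = [dataset[i] for i in plan.folds[fold].test]
        if config.target_stratum != "overall":
            test_graphs = [g for g in test_graphs if g.cohort == config.target_stratum]
        if not test_graphs:
            raise ValueError(f"fold {fold}: empty target stratum {config.target_stratum!r}")
        y = np.array([g.label for g in test_graphs])
        A, _ = model.prepare(test_graphs)
        name = model_name or model.spec.name
        if name not in DEEP_MODELS:
            raise ValueError(f"unexpected model name {name!r}")
        for eps in config.epsilons:
            X_adv = _perturb_batch(model, test_graphs, float(eps),
                                   config.clip_nonnegative, config.resymmetrize)
            scores = model.predict_scores_on(A, X_adv)
            acc, auc = _metrics(scores, y)
            rows.append(dict(model=name, epsilon=float(eps), fold=fold,
                             stratum=config.target_stratum, accuracy=acc, auc=auc))
            if keep_perturbed:
                perturbed[(name, fold, float(eps))] = X_adv
    return AttackResult(table=pd.DataFrame(rows), perturbed=perturbed)
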