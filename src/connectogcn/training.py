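"""Training loop, cross-validation splits, the four evaluation regimes, and
metric reporting.

Deep models train with Adam (lr 1e-3, weight decay 5e-4) for up to 100 epochs
under weighted binary cross entropy, with 50% dropout and early stopping on
validation loss at patience 35, restoring the best-validation weights.  Splits
are 5-fold, stratified jointly by (sex label, cohort): each fold's 20% is the
test set; for deep models the remaining 80% is re-split 7:1 into
train:validation, for RF/SVM it is used whole (80/20).

Regimes: ``adult_adult`` and ``pediatric_pediatric`` are within-cohort CV;
``adult_to_pediatric`` evaluates each adult-fold model on the entire pediatric
cohort (external validation); ``enriched`` pools both cohorts with
cohort-stratified splits and cohort-stratified reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit, KFold

from .models import DEEP_MODELS, ModelSpec, build_model
from .nets import Adam
from .synthetic import ConnectomeGraph

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "SplitPlan",
    "EvalReport",
    "EarlyStopper",
    "weighted_bce",
    "make_splits",
    "class_weights_from_labels",
    "train_model",
    "evaluate",
    "run_regime",
    "assert_no_leakage",
    "REGIMES",
]

REGIMES = ("adult_adult", "adult_to_pediatric", "pediatric_pediatric", "enriched")
N_FOLDS = 5


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 100
    weight_decay: float = 5e-4
    early_stopping_patience: int = 35
    dropout: float = 0.5
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.epochs, self.weight_decay,
               self.early_stopping_patience, self.batch_size) <= 0:
            raise ValueError("training hyperparameters must be positive")
        if self.early_stopping_patience > self.epochs:
            raise ValueError("patience must not exceed the epoch budget")


@dataclass(frozen=True)
class FoldSplit:
    train: np.ndarray
    val: np.ndarray  # empty for shallow models
    test: np.ndarray


@dataclass(frozen=True)
class SplitPlan:
    folds: tuple[FoldSplit, ...]
    mode: str
    model_family: str
    seed: int
    n: int


class EarlyStopper:
    """Stop when the monitored loss has not strictly improved for ``patience``
    consecutive epochs; remembers which epoch held the best value."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record this epoch's loss; returns True when training should stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def weighted_bce(scores, labels, class_weights=(1.0, 1.0)) -> float:
    """Mean of ``-w_y [y log s + (1-y) log(1-s)]`` with scores clamped away
    from 0 and 1 at 1e-12."""
    s = np.clip(np.asarray(scores, dtype=float), 1e-12, 1 - 1e-12)
    y = np.asarray(labels, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    w0, w1 = class_weights
    if w0 <= 0 or w1 <= 0:
        raise ValueError("class weights must be positive")
    w = np.where(y == 1, w1, w0)
    return float(-(w * (y * np.log(s) + (1 - y) * np.log(1 - s))).mean())


def class_weights_from_labels(labels) -> tuple[float, float]:
    """Inverse class frequency of the training split, normalized to mean 1."""
    y = np.asarray(labels)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        return (1.0, 1.0)
    w0, w1 = 1.0 / n0, 1.0 / n1
    mean = (w0 + w1) / 2.0
    return (w0 / mean, w1 / mean)


def _strat_key(graphs, idx=None):
    idx = np.arange(len(graphs)) if idx is None else idx
    return np.array([2 * graphs[i].label + (graphs[i].cohort == "pediatric") for i in idx])


def make_splits(
    dataset: list[ConnectomeGraph],
    mode: str = "single_cohort",
    model_family: str = "deep",
    seed: int = 0,
) -> SplitPlan:
    """Five stratified folds; each fold's 20% is the test set.

    Stratification is joint on (label, cohort), so in enriched mode the
    adult:pediatric ratio is held constant across train/val/test up to
    rounding.  Deep folds re-split the remaining 80% into 70/10 of the total.
    Deterministic given ``seed``.
    """
    if mode not in ("single_cohort", "enriched"):
        raise ValueError(f"unknown split mode {mode!r}")
    if model_family not in ("deep", "shallow"):
        raise ValueError(f"unknown model family {model_family!r}")
    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    if mode == "enriched":
        cohorts = {g.cohort for g in dataset}
        if cohorts != {"adult", "pediatric"}:
            raise ValueError("enriched mode requires both cohorts present")

    key = _strat_key(dataset)
    counts = np.bincount(key)
    if counts[counts > 0].min() < N_FOLDS:
        warnings.warn(
            "a (label, cohort) stratum has fewer than 5 subjects; "
            "falling back to label-only stratification",
            stacklevel=2,
        )
        key = np.array([g.label for g in dataset])
        if np.bincount(key)[np.bincount(key) > 0].min() < N_FOLDS:
            warnings.warn("a label stratum has fewer than 5 subjects; unstratified folds",
                          stacklevel=2)
            key = None

    idx = np.arange(n)
    if key is None:
        splitter = KFold(N_FOLDS, shuffle=True, random_state=seed % 2**31)
        fold_iter = splitter.split(idx)
    else:
        splitter = StratifiedKFold(N_FOLDS, shuffle=True, random_state=seed % 2**31)
        fold_iter = splitter.split(idx, key)

    folds = []
    for k, (rest, test) in enumerate(fold_iter):
        if model_family == "shallow":
            folds.append(FoldSplit(train=rest, val=np.array([], dtype=int), test=test))
            continue
        inner_key = key[rest] if key is not None else None
        inner_seed = (seed * 7919 + k + 1) % 2**31
        if inner_key is not None and np.bincount(inner_key)[np.bincount(inner_key) > 0].min() >= 2:
            sss = StratifiedShuffleSplit(n_splits=1, test_size=1 / 8, random_state=inner_seed)
            tr_pos, val_pos = next(sss.split(rest, inner_key))
        else:
            rng = np.random.default_rng(inner_seed)
            perm = rng.permutation(len(rest))
            n_val = max(1, int(round(len(rest) / 8)))
            val_pos, tr_pos = perm[:n_val], perm[n_val:]
        folds.append(FoldSplit(train=rest[tr_pos], val=rest[val_pos], test=test))
    plan = SplitPlan(folds=tuple(folds), mode=mode, model_family=model_family, seed=seed, n=n)
    assert_no_leakage(plan)
    return plan


def assert_no_leakage(plan: SplitPlan) -> None:
    """Every subject in exactly one test fold; train/val/test disjoint per fold."""
    all_test = np.concatenate([f.test for f in plan.folds])
    if len(np.unique(all_test)) != plan.n or len(all_test) != plan.n:
        raise AssertionError("test folds do not partition the dataset")
    for f in plan.folds:
        tr, va, te = set(f.train.tolist()), set(f.val.tolist()), set(f.test.tolist())
        if tr & te or va & te or tr & va:
            raise AssertionError("overlapping train/val/test membership")


def train_model(
    spec: ModelSpec,
    dataset: list[ConnectomeGraph],
    plan: SplitPlan,
    fold: int,
    config: TrainConfig = TrainConfig(),
):
    """Train one fold's model; returns ``(model, curves)``.

    Deep models run the Adam loop with per-epoch validation loss and early
    stopping, then restore the best-validation weights.  RF/SVM ignore the
    epoch machinery and fit once on the training split (PCA fit inside the
    fold).  ``curves`` maps 'train_loss'/'val_loss' to per-epoch lists.
    """
    split = plan.folds[fold]
    train_graphs = [dataset[i] for i in split.train]
    y_train = np.array([g.label for g in train_graphs], dtype=float)

    if spec.name not in DEEP_MODELS:
        model = build_model(spec, seed=(config.seed * 1000003 + fold) % 2**31)
        model.fit(train_graphs)
        return model, {"train_loss": [], "val_loss": []}

    model = build_model(spec, seed=(config.seed * 1000003 + fold) % 2**31)
    model.class_weights = class_weights_from_labels(y_train)
    if spec.dropout != config.dropout:
        model.net.dropout = config.dropout

    A_tr, X_tr = model.prepare(train_graphs)
    val_graphs = [dataset[i] for i in split.val]
    y_val = np.array([g.label for g in val_graphs], dtype=float)
    A_va, X_va = model.prepare(val_graphs) if val_graphs else (None, None)

    rng = np.random.default_rng((config.seed * 524287 + fold) % 2**31)
    optimizer = Adam(model.net.params(), lr=config.learning_rate,
                     weight_decay=config.weight_decay)
    stopper = EarlyStopper(config.early_stopping_patience)
    best_state = model.net.get_state()
    curves = {"train_loss": [], "val_loss": []}

    n_train = len(train_graphs)
    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        epoch_losses = []
        for start in range(0, n_train, config.batch_size):
            b = order[start : start + config.batch_size]
            loss, grads, _ = model.net.loss_and_grads(
                A_tr[b], X_tr[b], y_train[b], model.class_weights, rng=rng, train=True
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} ({spec.name}, fold {fold})"
                )
            optimizer.step(grads)
            epoch_losses.append(loss)
        curves["train_loss"].append(float(np.mean(epoch_losses)))

        if val_graphs:
            val_scores = model.net.scores(A_va, X_va)
            val_loss = weighted_bce(val_scores, y_val, model.class_weights)
        else:
            val_loss = curves["train_loss"][-1]
        curves["val_loss"].append(val_loss)
        if val_loss < stopper.best:
            best_state = model.net.get_state()
        if stopper.update(val_loss, epoch):
            break

    model.net.set_state(best_state)
    return model, curves


def _metrics(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float | None]:
    acc = 100.0 * float(((scores >= 0.5).astype(int) == labels).mean())
    if len(np.unique(labels)) < 2:
        return acc, None  # AUC undefined for a single-class stratum
    return acc, float(roc_auc_score(labels, scores))


def evaluate(
    model,
    dataset: list[ConnectomeGraph],
    plan: SplitPlan,
    fold: int,
    strata=("overall", "adult", "pediatric"),
) -> dict:
    """Test-fold accuracy (%, threshold 0.5), rank-based AUC (ties half), and
    ROC curves, overall and per cohort stratum."""
    test_graphs = [dataset[i] for i in plan.folds[fold].test]
    return evaluate_on(model, test_graphs, strata)


def evaluate_on(model, test_graphs: list[ConnectomeGraph], strata=("overall", "adult", "pediatric")) -> dict:
    scores = np.asarray(model.predict_scores(test_graphs), dtype=float)
    labels = np.array([g.label for g in test_graphs])
    cohorts = np.array([g.cohort for g in test_graphs])
    out = {}
    for stratum in strata:
        sel = np.ones(len(test_graphs), bool) if stratum == "overall" else cohorts == stratum
        if not sel.any():
            continue
        acc, auc = _metrics(scores[sel], labels[sel])
        roc = None
        if auc is not None:
            fpr, tpr, _ = roc_curve(labels[sel], scores[sel])
            roc = (fpr, tpr)
        out[stratum] = {"n": int(sel.sum()), "accuracy": acc, "auc": auc, "roc": roc}
    return out


@dataclass
class EvalReport:
    """Tidy per-fold metrics plus loss and ROC curves.

    ``rows`` columns: model, regime, stratum, fold, n, accuracy (percent),
    auc.  ``summary()`` aggregates to mean ± sample SD (n−1) across folds.
    """

    rows: pd.DataFrame
    loss_curves: dict = field(default_factory=dict)
    roc_curves: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    plans: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        g = self.rows.groupby(["model", "regime", "stratum"], sort=False)
        out = g.agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_sd=("accuracy", lambda s: s.std(ddof=1)),
            auc_mean=("auc", "mean"),
            auc_sd=("auc", lambda s: s.std(ddof=1)),
            folds=("fold", "count"),
        ).reset_index()
        return out

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def run_regime(
    regime: str,
    specs: list[ModelSpec],
    dataset: list[ConnectomeGraph],
    config: TrainConfig = TrainConfig(),
) -> EvalReport:
    """Run one evaluation regime for each model spec over 5-fold CV."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")

    adults = [g for g in dataset if g.cohort == "adult"]
    peds = [g for g in dataset if g.cohort == "pediatric"]
    if regime in ("adult_adult", "adult_to_pediatric") and not adults:
        raise ValueError(f"regime {regime} requires adult subjects")
    if regime in ("pediatric_pediatric", "adult_to_pediatric", "enriched") and not peds:
        raise ValueError(f"regime {regime} requires pediatric subjects")

    if regime == "enriched":
        base, mode = dataset, "enriched"
    elif regime == "pediatric_pediatric":
        base, mode = peds, "single_cohort"
    else:
        base, mode = adults, "single_cohort"

    rows, loss_curves, roc_curves, models, plans = [], {}, {}, {}, {}
    for spec in specs:
        family = "deep" if spec.name in DEEP_MODELS else "shallow"
        if family not in plans:
            plans[family] = make_splits(base, mode=mode, model_family=family, seed=config.seed)
        plan = plans[family]
        for fold in range(N_FOLDS):
            model, curves = train_model(spec, base, plan, fold, config)
            models[(spec.name, fold)] = model
            loss_curves[(spec.name, fold)] = curves
            if regime == "adult_to_pediatric":
                frag = evaluate_on(model, peds, strata=("overall", "pediatric"))
            else:
                frag = evaluate(model, base, plan, fold)
            for stratum, m in frag.items():
                rows.append(
                    dict(model=spec.name, regime=regime, stratum=stratum, fold=fold,
                         n=m["n"], accuracy=m["accuracy"], auc=m["auc"])
                )
                if m["roc"] is not None:
                    roc_curves[(spec.name, fold, stratum)] = m["roc"]
    report = EvalReport(
        rows=pd.DataFrame(rows),
        loss_curves=loss_curves,
        roc_curves=roc_curves,
        models=models,
        plans=plans,
    )
    return report
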