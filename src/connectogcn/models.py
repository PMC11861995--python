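"""The five classifiers: two GCNs, an MLP, and PCA-based RF / SVM baselines.

``ModelSpec`` is a declarative architecture description; :func:`build_model`
assembles a classifier from it.  Deep models wrap the hand-written nets from
:mod:`connectogcn.nets` and normalize adjacencies once per dataset; shallow
baselines wrap scikit-learn pipelines (PCA fit on training folds only).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .graphops import normalize_adjacency
from .nets import MLPNet, ResidualGCNNet, SimpleGCNNet
from .synthetic import ConnectomeGraph

__all__ = [
    "ModelSpec",
    "Prediction",
    "build_model",
    "count_parameters",
    "predict",
    "save_model",
    "load_model",
    "DEEP_MODELS",
    "SHALLOW_MODELS",
]

DEEP_MODELS = ("gcn_simple", "gcn_residual", "mlp")
SHALLOW_MODELS = ("rf", "svm")


@dataclass(frozen=True)
class Prediction:
    """Probability of the positive (female) class and the 0.5-threshold label."""

    score: float
    label_hat: int


@dataclass(frozen=True)
class ModelSpec:
    name: str
    n_regions: int
    feature_dim: int | None = None  # defaults to n_regions (connectivity profile)
    gcn_widths: tuple[int, ...] | None = None  # [64,64] simple, [32,32,32] residual
    activation: str | None = None  # relu for simple/mlp, tanh for residual
    pooling: str = "mean"
    aggregation: str = "mean"
    use_skips: bool = True
    mlp_widths: tuple[int, ...] = (512, 256, 128)
    dropout: float = 0.5
    pca_components: int = 100
    rf_estimators: int = 100
    svm_kernel: str = "rbf"

    def __post_init__(self):
        if self.name not in DEEP_MODELS + SHALLOW_MODELS:
            raise ValueError(f"unknown model name {self.name!r}")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.feature_dim is None:
            object.__setattr__(self, "feature_dim", self.n_regions)
        if self.gcn_widths is None:
            default = (64, 64) if self.name == "gcn_simple" else (32, 32, 32)
            object.__setattr__(self, "gcn_widths", default)
        else:
            object.__setattr__(self, "gcn_widths", tuple(self.gcn_widths))
        object.__setattr__(self, "mlp_widths", tuple(self.mlp_widths))
        if self.activation is None:
            object.__setattr__(
                self, "activation", "tanh" if self.name == "gcn_residual" else "relu"
            )
        if any(w <= 0 for w in self.gcn_widths) or any(w <= 0 for w in self.mlp_widths):
            raise ValueError("layer widths must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.pooling not in ("mean", "max") or self.aggregation not in ("mean", "max"):
            raise ValueError("pooling/aggregation must be 'mean' or 'max'")
        if self.name == "gcn_simple" and self.activation != "relu":
            raise ValueError("gcn_simple uses relu activation")
        if self.name == "gcn_residual" and self.activation != "tanh":
            raise ValueError("gcn_residual uses tanh activation")
        if self.svm_kernel != "rbf":
            raise ValueError("svm kernel is fixed to rbf")


class DeepClassifier:
    """A differentiable graph classifier (GCN or MLP) over connectome graphs.

    Holds the training class weights so that adversarial gradients use the
    same loss the model was trained with.  Dropout is active only inside
    ``loss_and_grads`` during training; inference is deterministic.
    """

    is_deep = True

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        if spec.name == "gcn_simple":
            self.net = SimpleGCNNet(
                spec.feature_dim, list(spec.gcn_widths), spec.pooling, spec.dropout, rng
            )
        elif spec.name == "gcn_residual":
            self.net = ResidualGCNNet(
                spec.feature_dim,
                list(spec.gcn_widths),
                spec.aggregation,
                spec.use_skips,
                spec.dropout,
                rng,
            )
        elif spec.name == "mlp":
            self.net = MLPNet(
                spec.n_regions * spec.feature_dim, list(spec.mlp_widths), spec.dropout, rng
            )
        else:
            raise ValueError(f"{spec.name} is not a deep model")
        self.class_weights: tuple[float, float] = (1.0, 1.0)

    def prepare(self, graphs: list[ConnectomeGraph]) -> tuple[np.ndarray, np.ndarray]:
        """Stack normalized adjacencies and node features along a batch axis.

        Propagation always uses the clean adjacency derived from the graph,
        independently of the (possibly perturbed) node features.
        """
        A = np.stack([normalize_adjacency(g.adjacency) for g in graphs])
        X = np.stack(
            [
                g.node_features if g.node_features is not None else g.adjacency
                for g in graphs
            ]
        )
        if X.shape[1] != self.spec.n_regions or X.shape[2] != self.spec.feature_dim:
            raise ValueError(
                f"graphs have features {X.shape[1:]}, model expects "
                f"({self.spec.n_regions}, {self.spec.feature_dim})"
            )
        return A, X

    def predict_scores(self, graphs: list[ConnectomeGraph]) -> np.ndarray:
        A, X = self.prepare(graphs)
        return self.net.scores(A, X)

    def predict_scores_on(self, A: np.ndarray, X: np.ndarray) -> np.ndarray:
        return self.net.scores(A, X)

    def input_gradient(self, graphs: list[ConnectomeGraph]) -> np.ndarray:
        """d(weighted BCE at the true labels)/d(node features), eval mode."""
        A, X = self.prepare(graphs)
        y = np.array([g.label for g in graphs], dtype=float)
        _, _, dX = self.net.loss_and_grads(A, X, y, self.class_weights, rng=None, train=False)
        return dX


class ShallowClassifier:
    """PCA-reduced flattened connectivity features into RF or an rbf SVM.

    The PCA is part of the pipeline and is therefore fit on training folds
    only; SVM scores come from Platt calibration on the training data.
    """

    is_deep = False

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        if spec.name == "rf":
            learner = RandomForestClassifier(
                n_estimators=spec.rf_estimators, random_state=seed
            )
        elif spec.name == "svm":
            # Platt-style sigmoid calibration of decision values, fit on the
            # training folds, so AUC/ROC get probability scores
            learner = CalibratedClassifierCV(
                SVC(kernel=spec.svm_kernel, random_state=seed),
                method="sigmoid",
                ensemble=False,
            )
        else:
            raise ValueError(f"{spec.name} is not a shallow model")
        self._pca_requested = spec.pca_components
        self.pipeline = Pipeline(
            [("pca", PCA(n_components=None, random_state=seed)), ("clf", learner)]
        )
        self.fitted = False

    @staticmethod
    def _features(graphs: list[ConnectomeGraph]) -> np.ndarray:
        X = np.stack(
            [
                g.node_features if g.node_features is not None else g.adjacency
                for g in graphs
            ]
        )
        return X.reshape(len(graphs), -1)

    def fit(self, graphs: list[ConnectomeGraph]) -> "ShallowClassifier":
        F = self._features(graphs)
        n_comp = min(self._pca_requested, F.shape[0], F.shape[1])
        self.pipeline.set_params(pca__n_components=n_comp)
        y = np.array([g.label for g in graphs])
        self.pipeline.fit(F, y)
        self.fitted = True
        return self

    def predict_scores(self, graphs: list[ConnectomeGraph]) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("shallow model not fitted")
        F = self._features(graphs)
        proba = self.pipeline.predict_proba(F)
        pos = list(self.pipeline.classes_).index(1)
        return proba[:, pos]


def build_model(spec: ModelSpec, seed: int = 0):
    """Build an (untrained) classifier from its declarative spec.

    Weight initialization for deep models is Glorot-uniform seeded by ``seed``
    and recorded on the model for audit.
    """
    if spec.name in DEEP_MODELS:
        return DeepClassifier(spec, seed)
    return ShallowClassifier(spec, seed)


def count_parameters(model) -> int:
    """Exact number of trainable scalars (weights and biases)."""
    if not getattr(model, "is_deep", False):
        raise TypeError("parameter counting applies to deep models only")
    return model.net.n_parameters()


def predict(model, graph: ConnectomeGraph) -> Prediction:
    """Score a single graph; deterministic given trained weights."""
    score = float(model.predict_scores([graph])[0])
    return Prediction(score=score, label_hat=int(score >= 0.5))


def save_model(model, path) -> None:
    """Serialize spec, seed, class weights and weight arrays to one ``.npz``."""
    if not getattr(model, "is_deep", False):
        raise TypeError("checkpointing is implemented for deep models")
    meta = json.dumps(
        {
            "spec": asdict(model.spec),
            "seed": model.seed,
            "class_weights": list(model.class_weights),
        }
    )
    arrays = {f"param::{k}": v for k, v in model.net.params().items()}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path):
    """Restore a checkpoint; predictions are bit-identical to the saved model."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec_dict = meta["spec"]
        for key in ("gcn_widths", "mlp_widths"):
            if spec_dict.get(key) is not None:
                spec_dict[key] = tuple(spec_dict[key])
        spec = ModelSpec(**spec_dict)
        model = DeepClassifier(spec, seed=meta["seed"])
        model.class_weights = tuple(meta["class_weights"])
        state = {
            k.removeprefix("param::"): data[k] for k in data.files if k.startswith("param::")
        }
        model.net.set_state(state)
    return model
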