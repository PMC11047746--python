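"""Five binary classifiers behind one fit/predict contract.

* ``nr`` — a bespoke nonlinear-regression scorer: the squared Euclidean
  distance d of a sample from a class target profile is projected through
  the cuboid a(n1) = n1*d + (n1/10)^2*d^2 + (n1/100)^3*d^3, minimised over
  a grid of n1 values subject to n1 > n2 > n3 > 0 (n2 = n1/10,
  n3 = n2/10); the class with the smaller thresholded score s = f + b0
  wins.
* ``nb`` — Gaussian naive Bayes with additive variance smoothing alpha and
  a fixed minority-class prior.
* ``dt`` / ``rf`` — decision tree / 100-tree random forest, depth 10,
  Gini or information-gain splits (scikit-learn backends).
* ``svm-rbf`` — RBF-kernel SVM, gamma = 1, regularisation R (scikit-learn
  SMO backend; dual feasibility is exposed for verification).

Default hyper-parameters: NR T1=0.85, T2=0.65, b0=0.01; NB alpha=0.06,
prior=0.15; RF 100 trees depth 10; DT depth 10; SVM gamma=1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClassifierSpec",
    "NRModel",
    "TrainedModel",
    "nr_score",
    "fit",
    "predict",
    "training_mse",
    "CLASSIFIER_KINDS",
    "DEFAULT_HYPER_PARAMS",
    "TUNABLE_PARAM",
]

CLASSIFIER_KINDS = ("nr", "nb", "dt", "rf", "svm-rbf")

DEFAULT_HYPER_PARAMS: dict[str, dict[str, float]] = {
    "nr": {"T1": 0.85, "T2": 0.65, "b0": 0.01},
    "nb": {"alpha": 0.06, "prior": 0.15},
    "dt": {"max_depth": 10, "min_impurity_decrease": 0.0},
    "rf": {"n_trees": 100, "max_depth": 10, "min_impurity_decrease": 0.0},
    "svm-rbf": {"gamma": 1.0, "R": 1.0},
}

# default scalar tuned by the hyper-parameter tuners, per classifier
TUNABLE_PARAM: dict[str, str] = {
    "nr": "b0",
    "nb": "alpha",
    "dt": "min_impurity_decrease",
    "rf": "min_impurity_decrease",
    "svm-rbf": "gamma",
}

# admissible n1 grid of the NR cuboid: 0.01, 0.02, ..., 1.00
_N1_GRID = np.round(np.arange(1, 101) * 0.01, 2)


@dataclass
class ClassifierSpec:
    kind: str
    hyper_params: dict = field(default_factory=dict)
    seed: int = 0
    criterion: str = "gini"  # dt/rf split criterion: "gini" or "entropy"

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        merged = dict(DEFAULT_HYPER_PARAMS[self.kind])
        merged.update(self.hyper_params)
        self.hyper_params = merged


@dataclass
class NRModel:
    """Per-class target profiles plus the cuboid/threshold parameters."""

    targets: dict  # class label -> target profile (training class centroid)
    b0: float
    T1: float
    T2: float
    n1: float = 0.01
    use_acceptance_thresholds: bool = False

    @property
    def n2(self) -> float:
        return self.n1 / 10.0

    @property
    def n3(self) -> float:
        return self.n2 / 10.0


def nr_score(x, model: NRModel, target=None) -> float:
    """f = min over the n1 grid of the cuboid projection of d = sum|T-x|^2."""
    x = np.asarray(x, dtype=float)
    if target is None:
        target = next(iter(model.targets.values()))
    target = np.asarray(target, dtype=float)
    if target.shape != x.shape:
        raise ValueError("feature dimension does not match the target profile")
    d = float(np.sum(np.abs(target - x) ** 2))
    a = _N1_GRID * d + (_N1_GRID / 10.0) ** 2 * d**2 + (_N1_GRID / 100.0) ** 3 * d**3
    return float(np.min(a))


def _nr_best_n1(d: float) -> float:
    a = _N1_GRID * d + (_N1_GRID / 10.0) ** 2 * d**2 + (_N1_GRID / 100.0) ** 3 * d**3
    return float(_N1_GRID[int(np.argmin(a))])


class _GaussianNB:
    """Gaussian naive Bayes with additive variance smoothing.

    The smoothing constant ``alpha`` is added to every per-feature variance
    estimate; ``prior`` is the minority class's prior probability, the
    majority class taking the complement.
    """

    def __init__(self, alpha: float, prior: float):
        self.alpha = alpha
        self.prior = prior

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        counts = np.array([(y == c).sum() for c in self.classes_])
        minority = self.classes_[int(np.argmin(counts))]
        self.priors_ = np.array(
            [self.prior if c == minority else 1.0 - self.prior for c in self.classes_]
        )
        self.theta_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        self.var_ = (
            np.stack([X[y == c].var(axis=0) for c in self.classes_]) + self.alpha
        )
        if np.any(self.var_ <= 0):
            raise ValueError("smoothed variances must be positive; raise alpha")
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        jll = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            var = self.var_[k]
            jll[:, k] = (
                np.log(self.priors_[k])
                - 0.5 * np.sum(np.log(2.0 * np.pi * var))
                - 0.5 * np.sum((X - self.theta_[k]) ** 2 / var, axis=1)
            )
        return jll

    def predict_proba(self, X):
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    n_features: int
    classes: np.ndarray
    backend: object = None  # sklearn estimator or _GaussianNB
    nr: NRModel | None = None
    constant_class: object = None  # degenerate single-class model

    def predict(self, X):
        return predict(self, X)


def _check_dim(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training "
            f"dimension {model.n_features}"
        )
    return X


def fit(spec: ClassifierSpec, X, y) -> TrainedModel:
    """Train the classifier named by ``spec`` on samples x features X."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be samples x features")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    classes = np.unique(y)
    model = TrainedModel(spec=spec, n_features=X.shape[1], classes=classes)
    if len(classes) == 1:
        warnings.warn("single-class training data: model predicts that class")
        model.constant_class = classes[0]
        return model

    hp = spec.hyper_params
    if spec.kind == "nr":
        targets = {c: X[y == c].mean(axis=0) for c in classes}
        # b0 from data when not fixed: mean squared deviation of training
        # scores about their class means (least-squares estimate)
        b0 = hp.get("b0")
        if b0 is None:
            devs = []
            scores = {
                c: np.array([_nr_f(x, targets[c]) for x in X]) for c in classes
            }
            for c in classes:
                devs.append(scores[c] - scores[c].mean())
            b0 = float(np.mean(np.concatenate(devs) ** 2))
        model.nr = NRModel(
            targets=targets,
            b0=float(b0),
            T1=hp["T1"],
            T2=hp["T2"],
            use_acceptance_thresholds=bool(hp.get("use_acceptance_thresholds", False)),
        )
    elif spec.kind == "nb":
        model.backend = _GaussianNB(alpha=hp["alpha"], prior=hp["prior"]).fit(X, y)
    elif spec.kind == "dt":
        model.backend = DecisionTreeClassifier(
            max_depth=int(hp["max_depth"]),
            criterion=spec.criterion,
            min_impurity_decrease=float(hp["min_impurity_decrease"]),
            random_state=spec.seed,
        ).fit(X, y)
    elif spec.kind == "rf":
        model.backend = RandomForestClassifier(
            n_estimators=int(hp["n_trees"]),
            max_depth=int(hp["max_depth"]),
            max_features="sqrt",
            criterion=spec.criterion,
            min_impurity_decrease=float(hp["min_impurity_decrease"]),
            random_state=spec.seed,
        ).fit(X, y)
    elif spec.kind == "svm-rbf":
        model.backend = SVC(
            kernel="rbf",
            gamma=float(hp["gamma"]),
            C=float(hp["R"]),
            random_state=spec.seed,
        ).fit(X, y)
    return model


def _nr_f(x: np.ndarray, target: np.ndarray) -> float:
    d = float(np.sum(np.abs(target - x) ** 2))
    a = _N1_GRID * d + (_N1_GRID / 10.0) ** 2 * d**2 + (_N1_GRID / 100.0) ** 3 * d**3
    return float(np.min(a))


def predict(model: TrainedModel, X):
    """One label per sample."""
    X = _check_dim(model, X)
    if model.constant_class is not None:
        return np.full(X.shape[0], model.constant_class, dtype=model.classes.dtype)
    if model.spec.kind == "nr":
        nr = model.nr
        cls = list(nr.targets)
        scores = np.stack(
            [np.array([_nr_f(x, nr.targets[c]) for x in X]) + nr.b0 for c in cls],
            axis=1,
        )
        if nr.use_acceptance_thresholds:
            # accept a class outright when its score clears its threshold
            thr = np.array([nr.T1, nr.T2][: len(cls)])
            accepted = scores <= thr[None, :]
            only_one = accepted.sum(axis=1) == 1
            out = np.array(cls)[np.argmin(scores, axis=1)]
            out[only_one] = np.array(cls)[np.argmax(accepted[only_one], axis=1)]
            return out
        return np.array(cls)[np.argmin(scores, axis=1)]
    return model.backend.predict(X)


def predict_proba(model: TrainedModel, X):
    """Class posteriors (nb only); rows sum to one."""
    X = _check_dim(model, X)
    if model.spec.kind != "nb":
        raise ValueError("posteriors are defined for the nb classifier")
    return model.backend.predict_proba(X)


def decision_values(model: TrainedModel, X):
    """Signed decision values (svm-rbf only)."""
    X = _check_dim(model, X)
    if model.spec.kind != "svm-rbf":
        raise ValueError("decision values are defined for the svm-rbf classifier")
    return model.backend.decision_function(X)


def svm_dual_feasibility(model: TrainedModel) -> dict[str, float]:
    """Check the SVM dual constraints 0 <= v_i <= R and sum v_i x_i = 0."""
    if model.spec.kind != "svm-rbf":
        raise ValueError("dual feasibility applies to svm-rbf")
    svc: SVC = model.backend
    signed = svc.dual_coef_.ravel()  # v_i * x_i with x_i in {-1,+1}
    v = np.abs(signed)
    R = float(svc.C)
    return {
        "max_violation_box": float(max(0.0, np.max(v) - R)),
        "min_v": float(np.min(v)),
        "equality_residual": float(abs(np.sum(signed))),
        "R": R,
    }


def training_mse(model: TrainedModel, X, y) -> float:
    """Eq.-style MSE supervision: labels mapped to {0,1} vs predictions."""
    X = _check_dim(model, X)
    y = np.asarray(y)
    pos = sorted(model.classes.tolist())[-1]
    t = (y == pos).astype(float)
    o = (predict(model, X) == pos).astype(float)
    return float(np.mean((o - t) ** 2))
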