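"""Confusion-matrix metric suite, MSE and the cross-validation loop.

Metrics (positive = adenocarcinoma, negative = mesothelioma):

    accuracy   = (TP + TN) / total                      (percent)
    F1         = 2 TP / (2 TP + FP + FN)                (percent)
    MCC        = (TP*TN - FP*FN) / sqrt((TP+FP)(FP+TN)(TN+FN)(TP+FN))
    error rate = (FP + FN) / total                      (percent)
    Youden     = sensitivity% + specificity% - 100
    kappa      = (p_o - p_e) / (1 - p_e)   (Cohen, chance from marginals)

Zero-denominator cases return 0 and raise the ``degenerate`` flag instead
of failing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import classifiers as clf
from .data import CVPlan, ExpressionMatrix, make_stratified_folds

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "compute_metrics",
    "mean_squared_error",
    "cross_validate",
    "CrossValidationResult",
]


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fn, self.fp, self.tn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsReport:
    accuracy: float  # percent
    f1: float  # percent
    mcc: float
    error_rate: float  # percent
    youden: float  # percent points
    kappa: float
    mse: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "mcc": self.mcc,
            "error_rate": self.error_rate,
            "youden": self.youden,
            "kappa": self.kappa,
            "mse": self.mse,
        }


def confusion_matrix(y_true, y_pred, positive_label) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    seen = set(np.unique(y_true)) | set(np.unique(y_pred))
    labels = set(np.unique(y_true))
    if positive_label not in labels and len(labels) >= 2:
        raise ValueError(f"positive label {positive_label!r} not present in y_true")
    extra = seen - labels
    if extra and len(labels) == 2:
        raise ValueError(f"predictions contain unseen labels: {sorted(map(str, extra))}")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def _guarded(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def compute_metrics(cm: ConfusionMatrix, mse: float = 0.0) -> MetricsReport:
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    total = cm.total
    degenerate = False

    accuracy = 100.0 * (tp + tn) / total
    error_rate = 100.0 * (fp + fn) / total
    f1, d = _guarded(100.0 * 2 * tp, 2 * tp + fp + fn)
    degenerate |= d
    mcc_den = np.sqrt(float(tp + fp) * (fp + tn) * (tn + fn) * (tp + fn))
    mcc, d = _guarded(float(tp) * tn - float(fp) * fn, mcc_den)
    degenerate |= d
    sens, d1 = _guarded(100.0 * tp, tp + fn)
    spec, d2 = _guarded(100.0 * tn, tn + fp)
    degenerate |= d1 or d2
    youden = sens + spec - 100.0 if not (d1 or d2) else 0.0
    p_o = (tp + tn) / total
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / total**2
    kappa, d = _guarded(p_o - p_e, 1.0 - p_e)
    degenerate |= d
    return MetricsReport(
        accuracy=accuracy,
        f1=f1,
        mcc=mcc,
        error_rate=error_rate,
        youden=youden,
        kappa=kappa,
        mse=mse,
        degenerate=degenerate,
    )


def mean_squared_error(targets, outputs) -> float:
    t = np.asarray(targets, dtype=float)
    o = np.asarray(outputs, dtype=float)
    if t.shape != o.shape or t.size == 0:
        raise ValueError("targets and outputs must be non-empty and equal length")
    return float(np.mean((o - t) ** 2))


@dataclass
class CrossValidationResult:
    per_fold: list  # MetricsReport per fold
    pooled_cm: ConfusionMatrix
    mean: dict
    sd: dict
    train_mse: list
    test_mse: list
    plan: CVPlan
    masks: list  # FeatureMask per fold (None without selection)
    tuned: list  # (param, best_w) per fold (None without tuning)


def cross_validate(
    m: ExpressionMatrix,
    classifier_spec,
    dimre: str = "fft",
    n_out: int | None = None,
    selector_cfg=None,
    tuner: str | None = None,
    tuner_cfg=None,
    tunable: str | None = None,
    k: int = 10,
    seed: int = 0,
) -> CrossValidationResult:
    """Stratified k-fold evaluation of the full pipeline.

    Per fold, every fitted stage — mixture-model gene ranking, dragonfly
    mask, hyper-parameter tuning, classifier — sees the training folds
    only; the held-out fold is transformed and scored. FFT reduction is
    per-sample and needs no fitting. Aggregates are the unweighted mean
    and SD of the per-fold metrics.
    """
    from . import dimre as dr
    from . import feature_selection as fs
    from . import tuning as tn

    labels = np.asarray(m.labels)
    plan = make_stratified_folds(m.labels, k=k, seed=seed)
    for fold in range(k):
        if len(set(labels[plan.train_indices(fold)])) < 2:
            raise ValueError(f"fold {fold}: training partition has a single class")

    if dimre == "fft":
        features = dr.fft_reduce(m, n_out=n_out).values  # stateless, per-sample
    elif dimre != "mm":
        raise ValueError("dimre must be 'fft' or 'mm'")

    reports, train_mses, test_mses, fold_masks, fold_tuned = [], [], [], [], []
    agg_cm = np.zeros(4, dtype=int)
    for fold in range(k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        if dimre == "mm":
            red = dr.MMReducer(n_out=n_out, seed=seed).fit(m.values[:, tr])
            X_tr = red.transform(m.values[:, tr])
            X_te = red.transform(m.values[:, te])
        else:
            X_tr, X_te = features[tr], features[te]
        y_tr, y_te = labels[tr], labels[te]

        if selector_cfg is not None:
            fitness = fs.make_wrapper_fitness(
                X_tr, y_tr, seed=selector_cfg.seed, alpha=selector_cfg.fitness_alpha
            )
            mask = fs.dragonfly_select(X_tr, fitness=fitness, cfg=selector_cfg)
            cols = np.flatnonzero(mask.bits)
            X_tr, X_te = X_tr[:, cols], X_te[:, cols]
            fold_masks.append(mask)
        else:
            fold_masks.append(None)

        spec = classifier_spec
        if tuner is not None:
            param = tunable or clf.TUNABLE_PARAM[spec.kind]
            inner = make_param_eval(spec, param, X_tr, y_tr, seed=seed)
            if tuner == "adam":
                cfg = tuner_cfg or tn.adam_config_for(spec.kind)
                best_w, _ = tn.adam_tune(inner, cfg)
            elif tuner == "ranadam":
                cfg = tuner_cfg or tn.RanAdamConfig(
                    adam=tn.adam_config_for(spec.kind), lb=1e-4, ub=1.0, seed=seed
                )
                best_w, _ = tn.ranadam_tune(inner, cfg)
            else:
                raise ValueError("tuner must be 'adam' or 'ranadam'")
            hp = dict(spec.hyper_params)
            hp[param] = best_w
            spec = clf.ClassifierSpec(
                kind=spec.kind, hyper_params=hp, seed=spec.seed, criterion=spec.criterion
            )
            fold_tuned.append((param, best_w))
        else:
            fold_tuned.append(None)

        model = clf.fit(spec, X_tr, y_tr)
        pred_te = clf.predict(model, X_te)
        cm = confusion_matrix(y_te, pred_te, m.positive_label)
        test_mse = mean_squared_error(
            (y_te == m.positive_label).astype(float),
            (pred_te == m.positive_label).astype(float),
        )
        train_mse = clf.training_mse(model, X_tr, y_tr)
        reports.append(compute_metrics(cm, mse=test_mse))
        train_mses.append(train_mse)
        test_mses.append(test_mse)
        agg_cm += np.array([cm.tp, cm.fn, cm.fp, cm.tn])

    keys = reports[0].as_dict().keys()
    stacked = {kk: np.array([r.as_dict()[kk] for r in reports]) for kk in keys}
    return CrossValidationResult(
        per_fold=reports,
        pooled_cm=ConfusionMatrix(*agg_cm),
        mean={kk: float(v.mean()) for kk, v in stacked.items()},
        sd={kk: float(v.std(ddof=1)) for kk, v in stacked.items()},
        train_mse=train_mses,
        test_mse=test_mses,
        plan=plan,
        masks=fold_masks,
        tuned=fold_tuned,
    )


def make_param_eval(spec, param: str, X, y, n_splits: int = 3, seed: int = 0):
    """eval(w) -> inner stratified CV error rate with hyper-parameter w."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    plan = make_stratified_folds(list(y), k=n_splits, seed=seed)

    def eval_fn(w: float) -> float:
        hp = dict(spec.hyper_params)
        hp[param] = float(w)
        trial = clf.ClassifierSpec(
            kind=spec.kind, hyper_params=hp, seed=spec.seed, criterion=spec.criterion
        )
        errors = 0
        for fold in range(n_splits):
            tr, te = plan.train_indices(fold), plan.test_indices(fold)
            model = clf.fit(trial, X[tr], y[tr])
            errors += int(np.sum(clf.predict(model, X[te]) != y[te]))
        return errors / len(y)

    return eval_fn
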