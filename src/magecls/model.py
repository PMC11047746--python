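"""Statsmodels-style front door: a pipeline model and its fitted results.

``MagePipeline`` bundles the configured stages (dimensionality reduction,
optional dragonfly feature selection, optional Adam/RanAdam tuning, one of
the five classifiers) over an expression matrix; ``fit()`` runs the
stratified k-fold evaluation and returns a :class:`PipelineResults` whose
``summary()`` prints per-fold and aggregate metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec
from .data import ExpressionMatrix
from .evaluation import CrossValidationResult, cross_validate
from .feature_selection import DragonflyConfig

__all__ = ["MagePipeline", "PipelineResults"]


class MagePipeline:
    """Binary expression-classification pipeline as a fittable model.

    Parameters
    ----------
    data : ExpressionMatrix
        Genes x samples matrix with two-class labels.
    dimre : {"fft", "mm"}
        Gene-axis reduction method; ``n_out`` defaults to one tenth of the
        gene count.
    classifier : str or ClassifierSpec
        One of nr, nb, dt, rf, svm-rbf.
    select : bool or DragonflyConfig
        Enable binary dragonfly wrapper selection on the reduced features.
    tuner : {None, "adam", "ranadam"}
        Scalar hyper-parameter tuning inside each training partition.
    """

    def __init__(
        self,
        data: ExpressionMatrix,
        classifier="nb",
        dimre: str = "fft",
        n_out: int | None = None,
        select=False,
        tuner: str | None = None,
        tuner_cfg=None,
        tunable: str | None = None,
        k: int = 10,
        seed: int = 0,
    ):
        self.data = data
        if isinstance(classifier, str):
            classifier = ClassifierSpec(kind=classifier, seed=seed)
        self.classifier = classifier
        self.dimre = dimre
        self.n_out = n_out
        if select is True:
            select = DragonflyConfig(seed=seed)
        self.selector_cfg = select or None
        self.tuner = tuner
        self.tuner_cfg = tuner_cfg
        self.tunable = tunable
        self.k = k
        self.seed = seed

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, labels, **kwargs) -> "MagePipeline":
        """Build from a genes x samples DataFrame plus a label sequence."""
        m = ExpressionMatrix(
            values=frame.to_numpy(dtype=float),
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            labels=list(labels),
        )
        return cls(m, **kwargs)

    def fit(self) -> "PipelineResults":
        cv = cross_validate(
            self.data,
            self.classifier,
            dimre=self.dimre,
            n_out=self.n_out,
            selector_cfg=self.selector_cfg,
            tuner=self.tuner,
            tuner_cfg=self.tuner_cfg,
            tunable=self.tunable,
            k=self.k,
            seed=self.seed,
        )
        return PipelineResults(model=self, cv=cv)


@dataclass
class PipelineResults:
    """Fitted-pipeline results: per-fold metrics, aggregates, diagnostics."""

    model: MagePipeline
    cv: CrossValidationResult

    @property
    def metrics(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.cv.per_fold]
        return pd.DataFrame(rows, index=[f"fold{j}" for j in range(len(rows))])

    @property
    def mean(self) -> dict:
        return self.cv.mean

    @property
    def sd(self) -> dict:
        return self.cv.sd

    def summary(self) -> str:
        m = self.model
        cm = self.cv.pooled_cm
        lines = [
            "MAGE classification pipeline (stratified %d-fold CV)" % m.k,
            "=" * 58,
            f"samples: {m.data.n_samples}  genes: {m.data.n_genes}  "
            f"classes: {m.data.positive_label}/{m.data.negative_label}",
            f"dimre: {m.dimre}  classifier: {m.classifier.kind}  "
            f"selection: {'dragonfly' if m.selector_cfg else 'none'}  "
            f"tuner: {m.tuner or 'none'}  seed: {m.seed}",
            "-" * 58,
            f"pooled confusion: TP={cm.tp} FN={cm.fn} FP={cm.fp} TN={cm.tn}",
            "-" * 58,
            f"{'metric':<12}{'mean':>12}{'sd':>12}",
        ]
        for key in ("accuracy", "f1", "error_rate", "youden", "mcc", "kappa", "mse"):
            lines.append(f"{key:<12}{self.mean[key]:>12.4f}{self.sd[key]:>12.4f}")
        lines.append("-" * 58)
        lines.append(
            "train MSE mean: %.3e   test MSE mean: %.3e"
            % (float(np.mean(self.cv.train_mse)), float(np.mean(self.cv.test_mse)))
        )
        return "\n".join(lines)
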