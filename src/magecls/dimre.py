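"""Dimensionality reduction of expression matrices.

Two reducers operate on the gene axis:

* FFT — each sample's gene vector is treated as a discrete signal, its
  DFT ``X(c) = sum_n x_n W_N^{cn}`` (twiddle factor ``W_N = exp(-2*pi*i/N)``)
  is taken, and the magnitudes of the lowest ``n_out`` frequency
  coefficients become the features.
* Mixture model — every gene's expression across samples is fitted with
  one- and two-component univariate Gaussian mixtures by EM; the model with
  the smaller BIC (``k ln n - 2 ln L``) wins, and genes are ranked by their
  bimodality evidence ``delta_BIC = BIC_1 - BIC_2``. The top ``n_out``
  genes' raw expression values are retained as features (an unsupervised
  bimodality filter).

The default output size is ``floor(n_genes / 10)`` for both, mapping the
Gordon gene count 12,533 to 1253 features per sample.

Also here: the per-class statistical summary (mean, variance, skewness,
non-excess kurtosis, mean pairwise sample correlation, Welch t-test) and a
regularized first canonical correlation between class blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from scipy import linalg, stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .data import ExpressionMatrix

__all__ = [
    "FFTSpectrum",
    "MMFitResult",
    "ReducedFeatures",
    "StatsSummary",
    "fft_forward",
    "fft_inverse",
    "fft_reduce",
    "fit_gene_mixture",
    "mm_reduce",
    "MMReducer",
    "class_stats_summary",
    "first_canonical_correlation",
    "default_n_out",
]


@dataclass
class FFTSpectrum:
    coefficients: np.ndarray  # complex, length n_points
    n_points: int


@dataclass
class MMFitResult:
    """One- vs two-component Gaussian mixture fit for a single gene."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    bic_1: float
    bic_2: float
    n_params: int
    n_obs: int

    @property
    def delta_bic(self) -> float:
        """Bimodality evidence: positive favours the two-component model."""
        return self.bic_1 - self.bic_2


@dataclass
class ReducedFeatures:
    """Samples x features matrix with provenance of each output feature."""

    values: np.ndarray
    method: str  # "fft" or "mm"
    n_out: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class StatsSummary:
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    pcc: float | None
    t_stat: float
    p_value: float
    cca: float | None


def default_n_out(n_genes: int) -> int:
    return n_genes // 10


def fft_forward(x, N: int | None = None) -> FFTSpectrum:
    """Forward DFT of a real signal, zero-padded to ``N`` points."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot transform an empty signal")
    if N is None:
        N = x.size
    if N < x.size:
        raise ValueError("N must be >= len(x)")
    if N > x.size:
        x = np.concatenate([x, np.zeros(N - x.size)])
    return FFTSpectrum(coefficients=np.fft.fft(x), n_points=N)


def fft_inverse(s: FFTSpectrum) -> np.ndarray:
    """Inverse DFT; returns the real part (inputs are real signals)."""
    if len(s.coefficients) != s.n_points:
        raise ValueError("spectrum length disagrees with n_points")
    return np.fft.ifft(s.coefficients).real


def fft_reduce(m: ExpressionMatrix, n_out: int | None = None) -> ReducedFeatures:
    """Magnitudes of the ``n_out`` lowest-frequency DFT coefficients per sample.

    The gene ordering of the input defines the "time" axis; the reduction
    is applied sample-by-sample, so it is invariant to sample ordering.
    """
    if n_out is None:
        n_out = default_n_out(m.n_genes)
    if not 1 <= n_out <= m.n_genes:
        raise ValueError(f"n_out={n_out} must lie in [1, {m.n_genes}]")
    spectra = np.fft.fft(m.values, axis=0)  # genes axis per sample
    feats = np.abs(spectra[:n_out, :]).T  # samples x features
    prov = {j: f"frequency_index={j}" for j in range(n_out)}
    return ReducedFeatures(values=feats, method="fft", n_out=n_out, provenance=prov)


def fit_gene_mixture(
    values,
    max_components: int = 2,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> MMFitResult:
    """EM-fit 1- and 2-component univariate Gaussian mixtures; pick by BIC.

    BIC = k ln(n) - 2 ln L with k = 2 (one component: mean, variance) or
    k = 5 (two components: two means, two variances, one weight); the model
    minimising BIC is selected. A variance floor of 1e-6 x the data
    variance guards degenerate components; constant input returns the
    one-component model at the floor.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations per gene")
    if max_components not in (1, 2):
        raise ValueError("max_components must be 1 or 2")
    data_var = float(np.var(x))
    floor = 1e-6 * data_var if data_var > 0 else 1e-6

    if data_var == 0.0:
        # all values identical: single component at the variance floor
        ll = float(np.sum(stats.norm.logpdf(x, loc=x[0], scale=np.sqrt(floor))))
        bic1 = 2 * np.log(n) - 2 * ll
        return MMFitResult(
            n_components=1,
            weights=np.array([1.0]),
            means=np.array([x[0]]),
            variances=np.array([floor]),
            log_likelihood=ll,
            bic_1=bic1,
            bic_2=np.inf,
            n_params=2,
            n_obs=n,
        )

    X = x[:, None]
    fits = {}
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            reg_covar=floor,
            max_iter=max_iter,
            tol=tol,
            n_init=1 if k == 1 else 3,
            init_params="k-means++",
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gm.fit(X)
        n_params = 3 * k - 1  # k means, k variances, k-1 free weights
        ll = float(gm.score(X)) * n
        fits[k] = (gm, n_params * np.log(n) - 2.0 * ll, ll, n_params)

    bic_1 = fits[1][1]
    bic_2 = fits[2][1] if max_components == 2 else np.inf
    best_k = 1 if bic_1 <= bic_2 else 2
    gm, bic, ll, n_params = fits[best_k]
    order = np.argsort(gm.means_.ravel())
    return MMFitResult(
        n_components=best_k,
        weights=gm.weights_.ravel()[order],
        means=gm.means_.ravel()[order],
        variances=gm.covariances_.ravel()[order],
        log_likelihood=ll,
        bic_1=bic_1,
        bic_2=bic_2,
        n_params=n_params,
        n_obs=n,
    )


class MMReducer:
    """Mixture-model gene filter with a fit/transform split.

    ``fit`` ranks genes on the supplied (training) samples by
    ``delta_BIC = BIC_1 - BIC_2`` descending (ties by gene index
    ascending); ``transform`` extracts the selected genes' raw expression,
    so held-out samples never influence the ranking.
    """

    def __init__(self, n_out: int | None = None, seed: int = 0):
        self.n_out = n_out
        self.seed = seed
        self.selected_: np.ndarray | None = None
        self.delta_bic_: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "MMReducer":
        n_genes = values.shape[0]
        n_out = self.n_out if self.n_out is not None else default_n_out(n_genes)
        if not 1 <= n_out <= n_genes:
            raise ValueError(f"n_out={n_out} must lie in [1, {n_genes}]")
        deltas = np.empty(n_genes)
        for g in range(n_genes):
            deltas[g] = fit_gene_mixture(values[g], seed=self.seed).delta_bic
        # stable sort on -delta keeps ascending gene index within ties
        order = np.argsort(-deltas, kind="stable")
        self.selected_ = np.sort(order[:n_out])
        self.delta_bic_ = deltas
        self._n_out = n_out
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.selected_ is None:
            raise RuntimeError("MMReducer.transform called before fit")
        return values[self.selected_, :].T


def mm_reduce(
    m: ExpressionMatrix, n_out: int | None = None, seed: int = 0
) -> ReducedFeatures:
    """Reduce by keeping the ``n_out`` most bimodal genes (by delta BIC)."""
    red = MMReducer(n_out=n_out, seed=seed).fit(m.values)
    feats = red.transform(m.values)
    prov = {
        j: f"gene_id={m.gene_ids[g]} delta_bic={red.delta_bic_[g]:.6g}"
        for j, g in enumerate(red.selected_)
    }
    return ReducedFeatures(
        values=feats, method="mm", n_out=feats.shape[1], provenance=prov
    )


def _mean_pairwise_sample_corr(block: np.ndarray) -> float | None:
    """Mean off-diagonal Pearson correlation between sample columns."""
    n_samples = block.shape[1]
    if n_samples < 2:
        return None
    sds = block.std(axis=0)
    if np.any(sds == 0):
        return None
    c = np.corrcoef(block.T)
    iu = np.triu_indices(n_samples, k=1)
    return float(np.mean(c[iu]))


def class_stats_summary(r: ReducedFeatures, labels) -> dict[str, StatsSummary]:
    """Per-class pooled statistics of a reduced feature matrix.

    Skewness is the adjusted Fisher-Pearson coefficient; kurtosis is
    reported on the Pearson (non-excess) convention, so a Gaussian scores
    3. The Welch two-sided t statistic and p-value compare the pooled
    entries of the two classes and are shared by both summaries, as is the
    first canonical correlation between the class blocks (computed after
    truncating both to the smaller class's sample count).
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    blocks = {c: r.values[labels == c, :].T for c in classes}  # features x samples
    pooled = {c: blocks[c].ravel() for c in classes}
    t_stat, p_value = stats.ttest_ind(pooled[classes[0]], pooled[classes[1]], equal_var=False)

    n_min = min(b.shape[1] for b in blocks.values())
    if n_min >= 2:
        a = blocks[classes[0]][:, :n_min].T
        b = blocks[classes[1]][:, :n_min].T
        cca = first_canonical_correlation(a, b)
    else:
        cca = None

    out = {}
    for c in classes:
        v = pooled[c]
        out[c] = StatsSummary(
            mean=float(np.mean(v)),
            variance=float(np.var(v, ddof=1)),
            skewness=float(stats.skew(v, bias=False)),
            kurtosis=float(stats.kurtosis(v, fisher=False, bias=False)),
            pcc=_mean_pairwise_sample_corr(blocks[c]),
            t_stat=float(t_stat),
            p_value=float(p_value),
            cca=cca,
        )
    return out


def first_canonical_correlation(a: np.ndarray, b: np.ndarray, ridge: float = 1e-6) -> float:
    """First canonical correlation between two sample x feature matrices.

    Columns are standardized; within-set covariances receive a ridge term
    so rank-deficient inputs never fail. The result is clipped to [0, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = min(a.shape[0], b.shape[0])
    a, b = a[:n], b[:n]

    def _std(m):
        m = m - m.mean(axis=0)
        s = m.std(axis=0)
        s[s == 0] = 1.0
        return m / s

    a, b = _std(a), _std(b)
    saa = a.T @ a / n + ridge * np.eye(a.shape[1])
    sbb = b.T @ b / n + ridge * np.eye(b.shape[1])
    sab = a.T @ b / n
    m = linalg.solve(saa, sab) @ linalg.solve(sbb, sab.T)
    eigs = np.real(linalg.eigvals(m))
    rho2 = float(np.max(eigs)) if eigs.size else 0.0
    return float(np.clip(np.sqrt(max(rho2, 0.0)), 0.0, 1.0))
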