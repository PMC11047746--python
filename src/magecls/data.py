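"""Expression-matrix I/O, synthetic data generation and stratified folds.

The on-disk layout mirrors the Gordon lung-cancer convention: a delimited
text matrix with genes as rows, tissue samples as columns, and a final row
of class labels ("ADCA" for adenocarcinoma, "MPM" for mesothelioma).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_POSITIVE = "ADCA"
DEFAULT_NEGATIVE = "MPM"

__all__ = [
    "ExpressionMatrix",
    "CVPlan",
    "SyntheticSpec",
    "read_mage_matrix",
    "write_mage_matrix",
    "generate_synthetic_mage",
    "make_stratified_folds",
]


class MageFormatError(ValueError):
    """Malformed matrix file (ragged rows, bad numeric cell, bad label)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample class labels.

    ``labels`` holds exactly two distinct strings for classification tasks;
    ``positive_label`` names the class treated as positive (Gordon
    convention: ADCA = adenocarcinoma positive, MPM = mesothelioma
    negative).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: list[str]
    positive_label: str = DEFAULT_POSITIVE
    negative_label: str = DEFAULT_NEGATIVE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length must equal the gene count")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length must equal the sample count")
        if len(self.labels) != n_samples:
            raise ValueError("labels length must equal the sample count")
        if np.isnan(self.values).any():
            raise ValueError("expression values contain missing entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Labels as a 0/1 integer vector (1 = positive class)."""
        return np.asarray(
            [1 if l == self.positive_label else 0 for l in self.labels],
            dtype=int,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class CVPlan:
    """Fold assignment for stratified k-fold cross-validation."""

    fold_assignment: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignment != fold)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic Gordon-like expression matrix.

    Defaults reproduce the Gordon shape (12,533 genes, 150 positive vs 31
    negative samples). ``effect_size`` is the class-mean shift of the
    informative genes in units of the within-class noise SD;
    ``intra_class_corr`` is the target within-class gene-gene Pearson
    correlation, induced by one shared latent factor per sample.
    """

    n_genes: int = 12_533
    n_pos: int = 150
    n_neg: int = 31
    n_informative: int = 200
    effect_size: float = 1.5
    intra_class_corr: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("each class needs at least one sample")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("n_informative must lie in [0, n_genes]")
        if not 0.0 <= self.intra_class_corr < 1.0:
            raise ValueError("intra_class_corr must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _parse_block(rows: list[list[str]], path: str) -> np.ndarray:
    width = len(rows[0])
    block = np.empty((len(rows), width), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != width:
            raise MageFormatError(
                f"{path}: ragged row {i} (expected {width} cells, got {len(row)})"
            )
        for j, cell in enumerate(row):
            try:
                block[i, j] = float(cell)
            except ValueError as exc:
                raise MageFormatError(
                    f"{path}: cannot parse numeric cell at row {i}, column {j}: {cell!r}"
                ) from exc
    return block


def read_mage_matrix(
    path,
    dialect: str = "csv",
    positive_label: str = DEFAULT_POSITIVE,
    negative_label: str = DEFAULT_NEGATIVE,
    header: bool = True,
) -> ExpressionMatrix:
    """Load a genes x samples matrix whose final row is the class labels.

    ``header=True`` expects a first row of sample identifiers; otherwise
    samples are named S0..S(n-1). The value block must parse to floats and
    the final row may only contain the two configured label strings.
    """
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    rows = [ln.split(sep) for ln in lines]
    if len(rows) < 2:
        raise MageFormatError(f"{path}: need at least one gene row plus the label row")

    if header:
        first = rows.pop(0)
        sample_ids = [c.strip() for c in first[1:]]
    else:
        sample_ids = None

    label_row = rows.pop(-1)
    gene_rows = rows
    gene_ids = [r[0].strip() for r in gene_rows]
    value_rows = [r[1:] for r in gene_rows]
    labels = [c.strip() for c in label_row[1:]]

    allowed = {positive_label, negative_label}
    for lab in labels:
        if lab not in allowed:
            raise MageFormatError(
                f"{path}: unknown class label {lab!r}; expected one of {sorted(allowed)}"
            )
    values = _parse_block(value_rows, str(path))
    if sample_ids is None:
        sample_ids = [f"S{j}" for j in range(values.shape[1])]
    if len(labels) != values.shape[1]:
        raise MageFormatError(
            f"{path}: label row has {len(labels)} entries for {values.shape[1]} samples"
        )
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        labels=labels,
        positive_label=positive_label,
        negative_label=negative_label,
    )


def write_mage_matrix(m: ExpressionMatrix, path, dialect: str = "csv") -> None:
    """Serialize in the label-last-row layout; round-trips bit-for-bit."""
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    buf = io.StringIO()
    buf.write("gene" + sep + sep.join(m.sample_ids) + "\n")
    for gid, row in zip(m.gene_ids, m.values):
        buf.write(gid + sep + sep.join(repr(float(v)) for v in row) + "\n")
    buf.write("class" + sep + sep.join(m.labels) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def generate_synthetic_mage(spec: SyntheticSpec) -> ExpressionMatrix:
    """Draw a synthetic two-class expression matrix.

    Model per gene g and sample j:

        x[g, j] = baseline_g + effect_g * 1{j positive} + lam * factor_j + eps

    with log-normal baselines (microarray intensity scale), a single
    latent factor shared by all genes of a sample (within-class gene-gene
    correlation ``rho = lam^2 / (lam^2 + noise_sd^2)``) and i.i.d. Gaussian
    noise. Exactly ``n_informative`` genes get class-mean difference
    ``effect_size * noise_sd``; all other genes are class-exchangeable.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    labels = [DEFAULT_POSITIVE] * spec.n_pos + [DEFAULT_NEGATIVE] * spec.n_neg

    baseline = rng.lognormal(mean=2.0, sigma=1.0, size=spec.n_genes)
    rho = spec.intra_class_corr
    lam = spec.noise_sd * np.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0
    factor = rng.standard_normal(n)
    noise = rng.standard_normal((spec.n_genes, n)) * spec.noise_sd

    values = baseline[:, None] + lam * factor[None, :] + noise
    is_pos = np.array([1.0] * spec.n_pos + [0.0] * spec.n_neg)
    effect = spec.effect_size * spec.noise_sd
    values[: spec.n_informative] += effect * is_pos[None, :]

    gene_ids = [f"g{i}" for i in range(spec.n_genes)]
    sample_ids = [f"S{j}" for j in range(n)]
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        labels=labels,
    )


def make_stratified_folds(labels, k: int, seed: int) -> CVPlan:
    """Assign samples to k folds, stratified by class.

    Each class is shuffled independently and dealt round-robin across the
    folds, so per-class fold counts differ by at most one. Deterministic
    given ``seed``.
    """
    labels = list(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    assignment = np.full(n, -1, dtype=int)
    # deal each class's shuffled indices round-robin, rotating the starting
    # fold between classes so the remainder does not pile onto fold 0
    start = 0
    for cls in sorted(set(labels)):
        idx = np.array([i for i, l in enumerate(labels) if l == cls])
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            assignment[i] = (start + pos) % k
        start = (start + len(idx)) % k
    return CVPlan(fold_assignment=assignment, k=k, seed=seed)
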