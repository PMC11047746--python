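# Methods

This note documents the models, the defaults and the judgement calls in
`magecls`, in the order the pipeline runs them.

## Data model and synthetic generator

An `ExpressionMatrix` is a genes × samples real matrix with two-class
sample labels (positive = adenocarcinoma/`ADCA`, negative =
mesothelioma/`MPM` by convention). The loader accepts delimited text with
the labels in the last row, rejects ragged rows, non-numeric cells and
unknown label strings, and round-trips through the writer bit-for-bit
(values are serialized with `repr(float)`, which is exact for binary64).

The generator draws, for gene g and sample j,

    x[g, j] = baseline_g + effect_g · 1{j in positive class}
              + λ · factor_j + ε[g, j]

with log-normal baselines (median e² ≈ 7.4, mimicking the right-skewed
intensity scale of array data), i.i.d. Gaussian noise ε with SD
`noise_sd`, and one latent factor per sample shared by all genes. The
factor loading λ = noise_sd·√(ρ/(1−ρ)) makes the within-class gene–gene
correlation equal ρ (`intra_class_corr`). Exactly `n_informative` genes
receive the mean shift `effect_size · noise_sd`.

Defaults are the Gordon-like study conditions: 12,533 genes, 150 + 31
samples, ρ = 0.3, noise_sd = 1, and — where a test needs informative
structure — 200 informative genes at effect 1.5. What the generator does
*not* emulate: platform-specific probe effects, intensity-dependent
variance, batch structure, and gene–gene correlation beyond the single
shared factor. Tests passing on this generator therefore show algorithmic
correctness and sensible statistical behaviour, not clinical performance
on real arrays.

Class imbalance is preserved as-is; no rebalancing or normalisation is
applied anywhere, matching the pipeline this package reimplements.

Stratified folds are built by shuffling each class independently
(one integer seed) and dealing indices round-robin across folds, with the
starting fold rotated between classes so remainders spread out. Per-class
fold counts therefore differ by at most one; for 150/31 with k = 10 each
fold holds exactly 15 positives and 3–4 negatives.

## Dimensionality reduction

**FFT.** The gene axis (in file order) is treated as the signal axis.
Per sample, the DFT is taken (via numpy's FFT; unit tests pin it to the
O(N²) definition within 1e-9) and the magnitudes of the `n_out` lowest
frequencies are the features — real-valued, sample-order invariant, no
fitting, so cross-validation applies it directly. Default
`n_out = ⌊n_genes/10⌋` (12,533 → 1253).

**Mixture model.** Each gene's values across the *training* samples are
fitted with 1- and 2-component univariate Gaussian mixtures (EM,
k-means++ initialisation, 200 iterations, tolerance 1e-6, variance floor
1e-6 × the gene's variance via the EM regulariser; constant genes short-
circuit to one component at the floor). Component count minimises
BIC = k·ln n − 2·ln L with k = 2 and 5 free parameters respectively.
Genes are ranked by ΔBIC = BIC₁ − BIC₂ descending (ties broken by gene
index), and the top `n_out` genes' raw expression values form the
features. Retaining genes — rather than mixture parameters or
responsibilities — is this module's main interpretive choice: it keeps
the reduction unsupervised, invertible to gene identities, and swappable
behind the `ReducedFeatures` contract.

**Statistics.** The per-class summary reports pooled mean, sample
variance, adjusted Fisher–Pearson skewness, *non-excess* (Pearson)
kurtosis (a Gaussian scores 3 — the convention is stated because the
excess convention differs by 3), the mean pairwise Pearson correlation
between samples, and a Welch two-sided t-test between the pooled class
entries. The first canonical correlation between class blocks uses
standardized covariances with a 1e-6 ridge on the within-set blocks and
truncates both classes to the smaller sample count, so rank-deficient or
unbalanced inputs never fail; the result is clipped to [0, 1].

## Binary dragonfly feature selection

Agents carry a binary mask over features plus a continuous step vector.
Each iteration computes, per agent over the global neighbourhood (no
radius schedule):

    S = −Σ_j (X − X_j)      separation
    A = mean_j ΔX_j          alignment
    C = centroid − X         cohesion
    F = X⁺ − X               food (best mask seen)
    E = X⁻ + X               enemy (worst mask this iteration)

and updates ΔX ← sS + aA + cC + fF + eE + wΔX with weights s = a = 0.1,
c = 0.7, f = e = 1.0 and inertia w decayed linearly 0.9 → 0.4. The enemy
term is additive by design here; `enemy_repulsion="subtract"` switches to
the conventional repulsive form. Steps are clipped to ±0.75 so the
V-shaped transfer T(Δx) = |Δx/√(Δx²+1)| keeps flip probabilities below
~0.6 and the search can exploit; positions are projected back onto the
mask vertices every iteration so the behaviours act on masks, not on a
detached continuous state.

Two stabilisers matter in practice and are on by default:

- *greedy acceptance*: an agent reverts to its previous mask when the
  proposed flips worsen its fitness — without it, good masks are
  destroyed faster than food attraction can rebuild them;
- *memetic refinement*: one single-bit trial flip of the best mask per
  iteration, kept on improvement. One flip per iteration is deliberate:
  heavier local search over-prunes features whose removal is
  error-neutral on the inner folds, which can include genuinely
  informative but redundant ones.

Fitness is `α·error + (1−α)·(selected/total)` with α = 0.99, the error
being a stratified 3-fold cross-validation error of a wrapped classifier
(Gaussian NB by default — cheap and deterministic) computed on the
training partition only. Empty masks are repaired by forcing one random
bit; a fitness failure assigns the worst score and the run continues.
Best-so-far fitness is non-increasing by construction, and the whole
search is deterministic given the seed.

A caveat worth knowing: wrapper fitness can be gamed by chance — with
many candidate features the swarm can assemble noise sets that fit the
inner folds. At the default 181-sample scale the inner error resolution
(1/181) also means masks differing by one redundant informative feature
are often fitness-equivalent, so recovery benchmarks should read
"informative features in the best mask" as a median over seeds, which is
how the tests phrase it.

## Classifiers

All five sit behind `fit(spec, X, y) → TrainedModel` / `predict`.
Single-class training data yields a constant predictor with a warning.
Defaults: NR T₁ = 0.85, T₂ = 0.65, b₀ = 0.01; NB α = 0.06, prior = 0.15;
DT depth 10; RF 100 trees, depth 10, √p features per split; SVM-RBF
γ = 1, R = 1.

**Nonlinear regression (bespoke).** Per class, the target profile T is
the training centroid. For a sample x, d = Σᵢ|Tᵢ − xᵢ|² and the cuboid
a(n₁) = n₁d + n₂²d² + n₃³d³ with n₂ = n₁/10, n₃ = n₂/10 is minimised
over the grid n₁ ∈ {0.01, …, 1.00} (every grid point satisfies
n₁ > n₂ > n₃ > 0). Since a is increasing in n₁ for d ≥ 0 the minimiser
is the smallest grid value; the score is s = min(a) + b₀. The predicted
class is the one with the smaller score. b₀ defaults to the fixed 0.01
and is otherwise estimated as the mean squared deviation of training
scores about their class means (a least-squares estimate). The
thresholds T₁/T₂ are retained as optional per-class score-acceptance
gates behind `use_acceptance_thresholds` (off by default) because their
role is genuinely underdetermined; the default decision rule is the
plain score argmin.

**Gaussian NB** is hand-written (~40 lines) because its smoothing
semantics are specific: α is *added* to every per-feature variance
estimate (not scaled by the largest variance), and the configured prior
is assigned to the minority class with the complement to the majority.
Posteriors are normalised in log space and sum to 1 within 1e-9.

**DT / RF / SVM** delegate to scikit-learn (Gini default, information
gain selectable; bootstrap + majority vote; SMO). Dual feasibility of
the SVM solution — 0 ≤ vᵢ ≤ R and Σ vᵢyᵢ = 0 — is exposed by
`svm_dual_feasibility` and asserted in tests, so the delegation is
verifiable rather than assumed.

## Adam / RanAdam tuning

One scalar hyper-parameter per run (default mapping: NR → b₀, NB → α,
DT/RF → impurity threshold, SVM → γ; coordinate-wise looping is left to
the caller). The "gradient" is the finite difference of the validation
error-rate trajectory: ER₁/w_init at the first step, then
(ER_t − ER_{t−1})/(w_t − w_{t−1}) with a zero-gradient guard below
|Δw| < 1e-12; w_init = 0 is rejected at validation. The Adam update uses
the standard √Ŝ + ε denominator; `literal_paper_update=True` restores
the variant without the square root for comparison. Per-classifier
constants (β₁, β₂, ε, Lr) and initial (w, v, s) ship in `ADAM_DEFAULTS`
(e.g. SVM-RBF: 0.35, 0.65, 0.32, 0.45, w = 0.5, v = 0.1, s = 0.2).

RanAdam wraps each Adam iterate in one Controlled Randomisation trial:
with probability `sar` the candidate is adjusted multiplicatively by
`bandwidth · rand3` (an additive ±bandwidth move is available via
`additive_cr`); a candidate that violates [lb, ub] is clamped and then
re-randomised to `lb + rand4·bandwidth` (rand4 ∈ (0, 0.1)). The
candidate replaces the iterate only when it lowers the best error seen,
so best-ER is non-increasing. Constants: bandwidth 0.0095, considering
rate 0.6, adjusting rate 0.9, 100 iterations or the MSE convergence
criterion. Because the multiplicative move shrinks candidates toward the
lower bound, RanAdam's exploration concentrates near lb — which is
exactly what lets it escape a shallow basin when the deep optimum sits
low in the range, and a limitation to know when it does not. Bandwidth 0
disables the CR trial entirely, making RanAdam bit-identical to Adam
(the only reading consistent with a zero-width exploration
neighbourhood). Adam iterates inside RanAdam are clamped to [lb, ub] so
the whole trace respects the bounds.

Evaluation failures at a candidate score ER = 1 and the run continues.
Both tuners return the best-seen value, not the last iterate, and are
bit-reproducible given the seed.

## Evaluation

Confusion counts follow the positive = adenocarcinoma convention.
Accuracy, F1, error rate and Youden index are reported in percent; MCC
and Cohen's kappa on [−1, 1] (kappa from observed vs marginal chance
agreement — the standard definition). Zero-denominator cases return 0
and set a `degenerate` flag rather than raising. The suite is pinned to
scikit-learn's implementations on 1,000 random confusion matrices at
1e-9 in tests.

`cross_validate` fits every stage with state — mixture-model gene
ranking, the dragonfly mask, the tuned hyper-parameter, the classifier —
on the training folds only; the FFT reduction is stateless per sample
and applied globally. Leakage is tested by tampering with held-out
values and asserting the fitted state is unchanged. Fold aggregation is
the unweighted mean and SD of per-fold metrics, plus the pooled
confusion matrix and per-fold train/test MSE (labels mapped to {0, 1}).

## Problem sizes and runtime

The shipped tests run the full-scale dimensionality contract (12,533 ×
181, seconds), mixture recovery at 50 × 2 genes of 200 observations
(~40 s), dragonfly recovery at 200 features × 181 samples × 10 seeds
(~1 min with the NB wrapper), and the tuners on closed-form surfaces
(seconds). Mixture-model reduction inside cross-validation refits every
gene per fold; at 10 folds it is comfortable up to a few hundred genes,
and the per-gene EM cost is the knob to watch beyond that.

## Known limitations

- The wrapper fitness inherits the optimism of inner-CV error; selected
  masks are tuned to the training partition and should be judged on the
  held-out folds only (which `cross_validate` enforces).
- The mixture-model reduction scores bimodality, not class association;
  a gene bimodal for reasons unrelated to the labels ranks high.
- RanAdam tunes one scalar; joint tuning is a coordinate loop, with no
  interaction handling.
- The NR classifier's T₁/T₂ acceptance thresholds are an interpretive
  reconstruction and ship disabled.
- The synthetic generator's single-factor correlation structure is a
  deliberate simplification; see the generator section.
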