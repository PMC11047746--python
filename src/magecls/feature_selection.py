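"""Binary dragonfly optimisation for wrapper feature selection.

A swarm of agents carries a continuous position X and step (velocity)
dX per feature dimension, plus a binary mask. Each iteration combines the
five swarming behaviours

    separation  S_i = -sum_j (X - X_j)
    alignment   A_i = mean of neighbour steps
    cohesion    C_i = centroid(neighbours) - X
    food        F_i = X+ - X        (X+ = best position seen)
    enemy       E_i = X- + X        (X- = worst position in the population)

into a step update dX <- s*S + a*A + c*C + f*F + e*E + w*dX, with the
position advanced by the step. The enemy term is additive by default
(the ``enemy_repulsion="subtract"`` flag gives the conventional X- - X).
Bits flip with probability T(dx) = |dx / sqrt(dx^2 + 1)| (a V-shaped
transfer function), and a mask is scored by the wrapper fitness

    fitness(mask) = alpha * error_rate + (1 - alpha) * n_selected / n_features

with the error rate an inner stratified 3-fold CV error of a wrapped
classifier on the training partition only. Lower fitness is better; the
best mask ever seen is returned, so best-so-far fitness never increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifiers import ClassifierSpec, fit as fit_classifier, predict
from .data import make_stratified_folds

__all__ = [
    "DragonflyConfig",
    "DragonflySwarm",
    "FeatureMask",
    "compute_behaviours",
    "update_swarm",
    "dragonfly_select",
    "make_wrapper_fitness",
    "mask_fitness",
]


@dataclass
class DragonflyConfig:
    n_agents: int = 20
    max_iter: int = 50
    s: float = 0.1  # separation weight
    a: float = 0.1  # alignment weight
    c: float = 0.7  # cohesion weight
    f: float = 1.0  # food attraction
    e: float = 1.0  # enemy distraction
    w_start: float = 0.9  # inertia, decayed linearly to w_end
    w_end: float = 0.4
    fitness_alpha: float = 0.99
    step_clip: float = 0.75
    enemy_repulsion: str = "add"  # "add" (as modelled) or "subtract"
    greedy: bool = True  # elitist per-agent mask acceptance
    local_flips: int = 1  # single-bit refinements of the food mask per iteration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        for name in ("s", "a", "c", "f", "e"):
            if getattr(self, name) < 0:
                raise ValueError(f"behaviour weight {name} must be >= 0")
        if not 0 < self.fitness_alpha < 1:
            raise ValueError("fitness_alpha must lie in (0, 1)")
        if self.enemy_repulsion not in ("add", "subtract"):
            raise ValueError("enemy_repulsion must be 'add' or 'subtract'")

    def inertia(self, t: int) -> float:
        if self.max_iter <= 1:
            return self.w_start
        frac = t / (self.max_iter - 1)
        return self.w_start + (self.w_end - self.w_start) * min(frac, 1.0)


@dataclass
class DragonflySwarm:
    positions: np.ndarray  # agents x dims, continuous
    steps: np.ndarray  # agents x dims
    masks: np.ndarray  # agents x dims, uint8
    fitness: np.ndarray  # per-agent fitness of the current masks
    food: np.ndarray  # best position seen (continuous)
    food_mask: np.ndarray
    food_fitness: float
    enemy: np.ndarray  # worst position in the current population
    t: int = 0


@dataclass
class FeatureMask:
    bits: np.ndarray
    fitness: float
    trace: list = field(default_factory=list)  # best-so-far fitness per iteration

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())


def compute_behaviours(swarm: DragonflySwarm, agent: int, neighbours) -> tuple:
    """Separation, alignment, cohesion, food and enemy vectors for one agent.

    An empty neighbourhood yields zero S, A and C.
    """
    x = swarm.positions[agent]
    nb = np.asarray(list(neighbours), dtype=int)
    if nb.size == 0:
        S = A = C = np.zeros_like(x)
    else:
        Xn = swarm.positions[nb]
        S = -np.sum(x[None, :] - Xn, axis=0)
        A = swarm.steps[nb].mean(axis=0)
        C = Xn.mean(axis=0) - x
    F = swarm.food - x
    E = swarm.enemy + x
    return S, A, C, F, E


def _transfer(dx: np.ndarray) -> np.ndarray:
    """V-shaped transfer: |dx / sqrt(dx^2 + 1)|, the bit-flip probability."""
    return np.abs(dx / np.sqrt(dx * dx + 1.0))


def update_swarm(
    swarm: DragonflySwarm, cfg: DragonflyConfig, rng: np.random.Generator
) -> DragonflySwarm:
    """One synchronous swarm iteration (continuous step + mask flips)."""
    n_agents, dims = swarm.positions.shape
    w = cfg.inertia(swarm.t)
    new_steps = np.empty_like(swarm.steps)
    for i in range(n_agents):
        nb = [j for j in range(n_agents) if j != i]
        S, A, C, F, E = compute_behaviours(swarm, i, nb)
        if cfg.enemy_repulsion == "subtract":
            E = swarm.enemy - swarm.positions[i]
        step = cfg.s * S + cfg.a * A + cfg.c * C + cfg.f * F + cfg.e * E + w * swarm.steps[i]
        new_steps[i] = np.clip(step, -cfg.step_clip, cfg.step_clip)
    swarm.steps = new_steps
    swarm.positions = swarm.positions + swarm.steps

    flip = rng.uniform(size=(n_agents, dims)) < _transfer(swarm.steps)
    swarm.masks = np.where(flip, 1 - swarm.masks, swarm.masks).astype(np.uint8)
    for i in range(n_agents):  # a mask must select at least one feature
        if swarm.masks[i].sum() == 0:
            swarm.masks[i, rng.integers(dims)] = 1
    swarm.t += 1
    return swarm


def mask_fitness(mask: np.ndarray, error_rate: float, alpha: float) -> float:
    frac = float(mask.sum()) / mask.size
    return alpha * error_rate + (1.0 - alpha) * frac


def make_wrapper_fitness(
    X,
    y,
    spec: ClassifierSpec | None = None,
    n_splits: int = 3,
    seed: int = 0,
    alpha: float = 0.99,
):
    """Build fitness(mask) from an inner stratified CV of a wrapped classifier.

    Only the supplied (training-partition) data is touched, so no held-out
    information can leak into the selection. Default wrapped classifier:
    Gaussian naive Bayes (cheap and deterministic).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if spec is None:
        spec = ClassifierSpec(kind="nb")
    plan = make_stratified_folds(list(y), k=n_splits, seed=seed)

    def fitness(mask: np.ndarray) -> float:
        cols = np.flatnonzero(mask)
        if cols.size == 0:
            return np.inf
        errors = 0
        for fold in range(n_splits):
            tr, te = plan.train_indices(fold), plan.test_indices(fold)
            model = fit_classifier(spec, X[np.ix_(tr, cols)], y[tr])
            errors += int(np.sum(predict(model, X[np.ix_(te, cols)]) != y[te]))
        er = errors / len(y)
        return mask_fitness(mask, er, alpha)

    return fitness


def dragonfly_select(
    X, y=None, fitness=None, cfg: DragonflyConfig | None = None
) -> FeatureMask:
    """Run the binary dragonfly search and return the best mask seen.

    ``fitness`` maps a 0/1 mask to a real score (lower is better); when
    omitted it is built by :func:`make_wrapper_fitness` from ``X`` and
    ``y``. Deterministic given ``cfg.seed``.
    """
    if cfg is None:
        cfg = DragonflyConfig()
    X = np.asarray(X, dtype=float)
    dims = X.shape[1]
    if dims < 2:
        raise ValueError("need at least 2 features to select from")
    if fitness is None:
        if y is None:
            raise ValueError("either a fitness function or labels are required")
        fitness = make_wrapper_fitness(X, y, seed=cfg.seed, alpha=cfg.fitness_alpha)

    rng = np.random.default_rng(cfg.seed)
    masks = (rng.uniform(size=(cfg.n_agents, dims)) < 0.5).astype(np.uint8)
    for i in range(cfg.n_agents):
        if masks[i].sum() == 0:
            masks[i, rng.integers(dims)] = 1
    positions = rng.uniform(-1.0, 1.0, size=(cfg.n_agents, dims))
    steps = np.zeros((cfg.n_agents, dims))

    def eval_all(mk):
        vals = np.empty(cfg.n_agents)
        for i in range(cfg.n_agents):
            try:
                vals[i] = fitness(mk[i])
            except Exception:
                vals[i] = np.inf  # failed mask scores worst, run continues
        return vals

    fit_vals = eval_all(masks)
    best = int(np.argmin(fit_vals))
    worst = int(np.argmax(fit_vals))
    # binary search space: positions live on the mask vertices, so food
    # attraction and cohesion pull agents toward good masks
    positions = masks.astype(float)
    swarm = DragonflySwarm(
        positions=positions,
        steps=steps,
        masks=masks,
        fitness=fit_vals,
        food=masks[best].astype(float),
        food_mask=masks[best].copy(),
        food_fitness=float(fit_vals[best]),
        enemy=masks[worst].astype(float),
    )
    trace = [swarm.food_fitness]
    dims_count = dims
    for _ in range(cfg.max_iter):
        prev_masks = swarm.masks.copy()
        prev_fitness = swarm.fitness.copy()
        update_swarm(swarm, cfg, rng)
        new_fitness = eval_all(swarm.masks)
        if cfg.greedy:
            # elitist acceptance: an agent keeps its previous mask when the
            # proposed flips worsen its fitness
            worse = new_fitness > prev_fitness
            swarm.masks[worse] = prev_masks[worse]
            new_fitness[worse] = prev_fitness[worse]
        swarm.positions = swarm.masks.astype(float)  # project back to vertices
        swarm.fitness = new_fitness
        i_best = int(np.argmin(swarm.fitness))
        i_worst = int(np.argmax(swarm.fitness))
        if swarm.fitness[i_best] < swarm.food_fitness:
            swarm.food_fitness = float(swarm.fitness[i_best])
            swarm.food = swarm.masks[i_best].astype(float)
            swarm.food_mask = swarm.masks[i_best].copy()
        swarm.enemy = swarm.masks[i_worst].astype(float)
        # memetic refinement: single-bit trial flips on the food mask
        for _ in range(cfg.local_flips):
            j = int(rng.integers(dims_count))
            cand = swarm.food_mask.copy()
            cand[j] = 1 - cand[j]
            if cand.sum() == 0:
                continue
            try:
                f_cand = fitness(cand)
            except Exception:
                continue
            if f_cand < swarm.food_fitness:
                swarm.food_fitness = float(f_cand)
                swarm.food_mask = cand
                swarm.food = cand.astype(float)
        trace.append(swarm.food_fitness)

    return FeatureMask(
        bits=swarm.food_mask.astype(np.uint8),
        fitness=swarm.food_fitness,
        trace=trace,
    )
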