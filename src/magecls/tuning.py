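"""Derivative-free Adam and RanAdam hyper-parameter tuning.

A single scalar hyper-parameter w is tuned against a validation error
rate ER(w). The gradient is a finite difference of the ER trajectory:

    g_1 = ER_1 / w_init                      (first iteration)
    g_t = (ER_t - ER_{t-1}) / (w_t - w_{t-1})  (later iterations)

fed into the Adam moment recursion

    v_t = b1*v_{t-1} + (1-b1)*g_t        s_t = b2*s_{t-1} + (1-b2)*g_t^2
    V^ = v_t / (1-b1^t)                  S^ = s_t / (1-b2^t)
    w_{t+1} = w_t - Lr * V^ / (sqrt(S^) + eps)

RanAdam wraps each Adam iterate in a Controlled Randomisation (CR) move
governed by a solution-considering rate, a solution-adjusting rate and a
bandwidth; a perturbed candidate is kept only when it lowers the best
error rate seen. With bandwidth 0 the CR neighbourhood is empty and
RanAdam reduces exactly to Adam.

Per-classifier Adam constants (beta1, beta2, eps, Lr) and initial values
(w, v, s) follow the tuned defaults shipped in ``ADAM_DEFAULTS``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AdamConfig",
    "RanAdamConfig",
    "TuningState",
    "ADAM_DEFAULTS",
    "adam_config_for",
    "estimate_gradient",
    "adam_step",
    "adam_tune",
    "ranadam_perturb",
    "ranadam_tune",
]

# classifier kind -> (beta1, beta2, eps, lr, w_init, v0, s0)
ADAM_DEFAULTS: dict[str, tuple[float, ...]] = {
    "nr": (0.5, 0.5, 0.2, 0.28, 0.42, 0.1, 0.15),
    "nb": (0.6, 0.4, 0.26, 0.32, 0.5, 0.1, 0.2),
    "rf": (0.45, 0.55, 0.38, 0.4, 0.38, 0.1, 0.25),
    "dt": (0.55, 0.45, 0.33, 0.41, 0.6, 0.15, 0.2),
    "svm-rbf": (0.35, 0.65, 0.32, 0.45, 0.5, 0.1, 0.2),
}


@dataclass
class AdamConfig:
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    lr: float = 0.01
    w_init: float = 0.5
    v0: float = 0.0
    s0: float = 0.0
    max_iter: int = 100
    conv_mse: float = 0.0  # stop when (ER_t - ER_{t-1})^2 <= conv_mse; 0 disables
    literal_paper_update: bool = False  # drop the sqrt in the denominator

    def __post_init__(self) -> None:
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1, beta2 must lie in (0, 1)")
        if self.epsilon <= 0 or self.lr <= 0:
            raise ValueError("epsilon and lr must be positive")
        if self.w_init == 0:
            raise ValueError("w_init must be nonzero (first-step gradient divides by it)")


def adam_config_for(kind: str, **overrides) -> AdamConfig:
    """AdamConfig preloaded with the per-classifier default constants."""
    b1, b2, eps, lr, w, v, s = ADAM_DEFAULTS[kind]
    cfg = AdamConfig(beta1=b1, beta2=b2, epsilon=eps, lr=lr, w_init=w, v0=v, s0=s)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class RanAdamConfig:
    adam: AdamConfig
    lb: float = 0.0
    ub: float = 1.0
    bandwidth: float = 0.0095
    scr: float = 0.6  # solution considering rate
    sar: float = 0.9  # solution adjusting rate
    rand4_max: float = 0.1
    max_iter: int = 100
    seed: int = 0
    additive_cr: bool = False  # w + bandwidth*(2*rand3-1) instead of w*bandwidth*rand3

    def __post_init__(self) -> None:
        if not self.lb < self.ub:
            raise ValueError("lb must be < ub")
        if not (0 < self.scr < 1 and 0 < self.sar < 1):
            raise ValueError("scr and sar must lie in (0, 1)")
        if self.bandwidth < 0:
            raise ValueError("bandwidth must be >= 0")


@dataclass
class TuningState:
    """Trajectory of one scalar tuning run."""

    t: int = 0
    w: float = 0.0
    v: float = 0.0
    s: float = 0.0
    v_hat: float = 0.0
    s_hat: float = 0.0
    w_init: float = 0.0
    er_history: list = field(default_factory=list)
    w_history: list = field(default_factory=list)
    best_w: float = np.nan
    best_er: float = np.inf

    def record(self, w: float, er: float) -> None:
        self.w_history.append(w)
        self.er_history.append(er)
        if er < self.best_er:
            self.best_er = er
            self.best_w = w


def estimate_gradient(state: TuningState) -> float:
    """Finite-difference gradient of the error rate along the trajectory."""
    if not state.er_history:
        raise ValueError("er_history is empty")
    if len(state.er_history) == 1:
        return state.er_history[0] / state.w_init
    d_er = state.er_history[-1] - state.er_history[-2]
    d_w = state.w_history[-1] - state.w_history[-2]
    if abs(d_w) < 1e-12:
        return 0.0
    return d_er / d_w


def adam_step(state: TuningState, g: float, cfg: AdamConfig) -> TuningState:
    """One Adam moment update of w (modifies and returns ``state``)."""
    t = state.t
    if t < 1:
        raise ValueError("adam_step requires t >= 1")
    state.v = cfg.beta1 * state.v + (1.0 - cfg.beta1) * g
    state.s = cfg.beta2 * state.s + (1.0 - cfg.beta2) * g * g
    state.v_hat = state.v / (1.0 - cfg.beta1**t)
    state.s_hat = state.s / (1.0 - cfg.beta2**t)
    denom = (
        cfg.epsilon + state.s_hat
        if cfg.literal_paper_update
        else np.sqrt(state.s_hat) + cfg.epsilon
    )
    state.w = state.w - cfg.lr * state.v_hat / denom
    return state


def _safe_eval(eval_fn, w: float) -> float:
    try:
        er = float(eval_fn(w))
    except Exception:  # a failing candidate scores worst, the run continues
        return 1.0
    return min(max(er, 0.0), 1.0)


def adam_tune(eval_fn, cfg: AdamConfig) -> tuple[float, TuningState]:
    """Tune one scalar hyper-parameter by Adam on finite-difference ER.

    ``eval_fn(w) -> error rate in [0, 1]``. Returns the best-seen value
    (not the last iterate) and the full trajectory.
    """
    state = TuningState(w=cfg.w_init, v=cfg.v0, s=cfg.s0, w_init=cfg.w_init)
    for t in range(1, cfg.max_iter + 1):
        state.t = t
        er = _safe_eval(eval_fn, state.w)
        state.record(state.w, er)
        g = estimate_gradient(state)
        adam_step(state, g, cfg)
        if cfg.conv_mse > 0 and len(state.er_history) >= 2:
            if (state.er_history[-1] - state.er_history[-2]) ** 2 <= cfg.conv_mse:
                break
    return state.best_w, state


def ranadam_perturb(w: float, cfg: RanAdamConfig, rng: np.random.Generator) -> float:
    """One Controlled Randomisation move; the result always lies in [lb, ub].

    Draws rand1..rand3 ~ U(0,1) and rand4 ~ U(0, rand4_max). The candidate
    is kept as-is when rand1 < scr; when rand2 < sar it is adjusted
    (multiplicative bandwidth move, or an additive one under
    ``additive_cr``); a candidate that violates a bound is clamped and
    re-randomised to lb + rand4*bandwidth.
    """
    r1, r2, r3 = rng.uniform(0.0, 1.0, size=3)
    r4 = rng.uniform(0.0, cfg.rand4_max)
    cand = w
    if r1 < cfg.scr:
        cand = w
    if r2 < cfg.sar:
        if cfg.additive_cr:
            cand = cand + cfg.bandwidth * (2.0 * r3 - 1.0)
        else:
            cand = cand * cfg.bandwidth * r3
    violated = cand < cfg.lb or cand > cfg.ub
    cand = min(max(cand, cfg.lb), cfg.ub)
    if violated:
        cand = cfg.lb + r4 * cfg.bandwidth
        cand = min(max(cand, cfg.lb), cfg.ub)
    return float(cand)


def ranadam_tune(eval_fn, cfg: RanAdamConfig) -> tuple[float, TuningState]:
    """Adam with a CR exploration around each iterate (min-ER acceptance).

    Every outer iteration performs the Adam update, then draws one CR
    candidate near the current iterate; the candidate replaces the iterate
    only if its error rate improves on the best seen. Deterministic given
    ``cfg.seed``; with bandwidth 0 the trace equals Adam's exactly.
    """
    acfg = cfg.adam
    rng = np.random.default_rng(cfg.seed)
    w0 = min(max(acfg.w_init, cfg.lb), cfg.ub)
    state = TuningState(w=w0, v=acfg.v0, s=acfg.s0, w_init=w0)
    max_iter = min(cfg.max_iter, acfg.max_iter) if acfg.max_iter else cfg.max_iter
    for t in range(1, max_iter + 1):
        state.t = t
        er = _safe_eval(eval_fn, state.w)
        state.record(state.w, er)
        g = estimate_gradient(state)
        adam_step(state, g, cfg.adam)
        state.w = min(max(state.w, cfg.lb), cfg.ub)
        if cfg.bandwidth > 0.0:
            cand = ranadam_perturb(state.w, cfg, rng)
            er_cand = _safe_eval(eval_fn, cand)
            if er_cand < state.best_er:
                state.best_er = er_cand
                state.best_w = cand
                state.w = cand  # carry the accepted candidate forward
        if acfg.conv_mse > 0 and len(state.er_history) >= 2:
            if (state.er_history[-1] - state.er_history[-2]) ** 2 <= acfg.conv_mse:
                break
    return state.best_w, state
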