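"""Gaussian-process Bayesian optimization with expected improvement.

Minimizes a black-box loss l(eta) over a mixed search space.  A
zero-mean GP with a squared-exponential kernel (inputs encoded into the
unit cube, losses standardized, jitter 1e-8) models the loss surface;
candidates are proposed by maximizing the closed-form expected
improvement over the incumbent,

    EI(x) = (l* - m(x)) * Phi(z) + s(x) * phi(z),   z = (l* - m(x)) / s(x),

where m, s are the GP posterior mean and standard deviation and l* the
best observed loss.  Integer parameters use continuous relaxation +
rounding; categorical parameters are one-hot encoded; log-scale
parameters are searched in log space.

The design is deliberately small and deterministic: Latin-hypercube
initialization, random-candidate + L-BFGS-refined acquisition
maximization, fixed kernel length-scale (0.2 in encoded units).  Failed
objective evaluations are recorded as the worst observed loss and
flagged, so one bad configuration cannot halt a tuning run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "Param",
    "SearchSpace",
    "BOState",
    "gp_posterior",
    "expected_improvement",
    "optimize_hyperparameters",
]


@dataclass(frozen=True)
class Param:
    name: str
    kind: str  # "continuous" | "integer" | "categorical"
    bounds: tuple[float, float] | None = None
    choices: tuple | None = None
    log: bool = False

    def __post_init__(self) -> None:
        if self.kind in ("continuous", "integer"):
            if self.bounds is None or not np.all(np.isfinite(self.bounds)) \
                    or self.bounds[0] >= self.bounds[1]:
                raise InvalidConfigError(f"{self.name}: need finite lower < upper")
            if self.log and self.bounds[0] <= 0:
                raise InvalidConfigError(f"{self.name}: log scale needs positive bounds")
        elif self.kind == "categorical":
            if not self.choices:
                raise InvalidConfigError(f"{self.name}: categorical needs choices")
        else:
            raise InvalidConfigError(f"{self.name}: unknown kind {self.kind}")

    @property
    def width(self) -> int:
        return len(self.choices) if self.kind == "categorical" else 1


@dataclass(frozen=True)
class SearchSpace:
    params: tuple[Param, ...]

    def __post_init__(self) -> None:
        if not self.params:
            raise InvalidConfigError("search space must contain parameters")

    @property
    def dim(self) -> int:
        return sum(p.width for p in self.params)

    def decode(self, u: np.ndarray) -> dict[str, Any]:
        """Unit-cube vector -> concrete configuration."""
        cfg: dict[str, Any] = {}
        i = 0
        for p in self.params:
            if p.kind == "categorical":
                block = u[i:i + p.width]
                cfg[p.name] = p.choices[int(np.argmax(block))]
                i += p.width
            else:
                lo, hi = p.bounds
                if p.log:
                    val = float(np.exp(np.log(lo) + u[i] * (np.log(hi) - np.log(lo))))
                else:
                    val = float(lo + u[i] * (hi - lo))
                cfg[p.name] = int(round(val)) if p.kind == "integer" else val
                i += 1
        return cfg


@dataclass
class BOState:
    """Observed (encoded point, loss) pairs plus GP kernel settings."""

    space: SearchSpace
    X: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    losses: np.ndarray = field(default_factory=lambda: np.zeros(0))
    flags: list[bool] = field(default_factory=list)
    length_scale: float = 0.2
    jitter: float = 1e-8

    def add(self, u: np.ndarray, loss: float, failed: bool = False) -> None:
        u = np.atleast_2d(u)
        self.X = u if self.X.size == 0 else np.vstack([self.X, u])
        self.losses = np.append(self.losses, loss)
        self.flags.append(failed)

    @property
    def best(self) -> tuple[np.ndarray, float]:
        if len(self.losses) == 0:
            raise InvalidInputError("no observations yet")
        i = int(np.argmin(self.losses))
        return self.X[i], float(self.losses[i])


def _kernel(A: np.ndarray, B: np.ndarray, ls: float) -> np.ndarray:
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
    return np.exp(-0.5 * d2 / ls ** 2)


def gp_posterior(state: BOState, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GP posterior mean and variance at encoded point(s) ``u``.

    With no observations the prior (standardized mean 0, variance 1 on the
    loss scale's standard deviation) is returned.
    """
    U = np.atleast_2d(np.asarray(u, dtype=float))
    if len(state.losses) == 0:
        return np.zeros(len(U)), np.ones(len(U))
    y = state.losses
    y_mean = y.mean()
    y_sd = y.std() if y.std() > 1e-12 else 1.0
    yn = (y - y_mean) / y_sd
    K = _kernel(state.X, state.X, state.length_scale)
    K[np.diag_indices_from(K)] += state.jitter
    Lc = np.linalg.cholesky(K)
    alpha = np.linalg.solve(Lc.T, np.linalg.solve(Lc, yn))
    Ks = _kernel(U, state.X, state.length_scale)
    mean_n = Ks @ alpha
    v = np.linalg.solve(Lc, Ks.T)
    var_n = np.maximum(1.0 - np.sum(v ** 2, axis=0), 0.0)
    return mean_n * y_sd + y_mean, var_n * y_sd ** 2


def expected_improvement(state: BOState, u: np.ndarray) -> np.ndarray:
    """Closed-form EI (for minimization) at encoded point(s); >= 0."""
    if len(state.losses) == 0:
        raise InvalidInputError("EI needs at least one observation")
    mean, var = gp_posterior(state, u)
    best = float(np.min(state.losses))
    sd = np.sqrt(var)
    out = np.zeros_like(mean)
    pos = sd > 1e-12
    z = (best - mean[pos]) / sd[pos]
    out[pos] = (best - mean[pos]) * stats.norm.cdf(z) + sd[pos] * stats.norm.pdf(z)
    out[~pos] = np.maximum(best - mean[~pos], 0.0)
    return np.maximum(out, 0.0)


def _propose(state: BOState, rng: np.random.Generator,
             n_candidates: int = 512, n_restarts: int = 8) -> np.ndarray:
    d = state.space.dim
    cand = rng.random((n_candidates, d))
    ei = expected_improvement(state, cand)
    order = np.argsort(ei)[::-1][:n_restarts]
    best_u, best_ei = cand[order[0]], ei[order[0]]
    for idx in order:
        res = optimize.minimize(
            lambda u: -float(expected_improvement(state, u)[0]),
            cand[idx], method="L-BFGS-B", bounds=[(0.0, 1.0)] * d)
        if res.success and -res.fun > best_ei:
            best_ei, best_u = -res.fun, np.clip(res.x, 0, 1)
    return best_u


def optimize_hyperparameters(objective: Callable[[dict], float],
                             space: SearchSpace, budget: int = 25,
                             n_init: int = 5, seed: int = 0
                             ) -> tuple[dict, float, list[dict]]:
    """Run the GP-EI loop; returns (best config, best loss, history).

    ``history`` has one record per evaluation: config, loss, failed flag.
    Deterministic given ``seed``.
    """
    if not (1 <= n_init <= budget):
        raise InvalidConfigError("need 1 <= n_init <= budget")
    rng = np.random.default_rng(seed)
    state = BOState(space=space)
    sampler = qmc.LatinHypercube(d=space.dim, seed=seed)
    init = sampler.random(n=n_init)
    history: list[dict] = []

    def evaluate(u: np.ndarray) -> None:
        cfg = space.decode(u)
        try:
            loss = float(objective(cfg))
            failed = not np.isfinite(loss)
        except Exception:
            loss, failed = np.nan, True
        if failed:
            loss = float(np.max(state.losses)) if len(state.losses) else 1e6
        state.add(u, loss, failed)
        history.append({"config": cfg, "loss": loss, "failed": failed})

    for u in init:
        evaluate(u)
    for _ in range(budget - n_init):
        evaluate(_propose(state, rng))
    u_best, l_best = state.best
    return space.decode(u_best), l_best, history
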