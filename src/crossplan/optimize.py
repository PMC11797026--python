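"""Bayesian optimization of crossbreeding population structure.

The objective is the expected per-season profit of the whole system as a
function of downstream structure: tier productive lifetimes (yMA, yMB,
yMC, yHAB, ...) and nucleus dam counts (nDA, nDB, nDC).  The production
target and the nucleus genetic-gain schedules are held fixed, so each
evaluation only re-runs the deterministic gene-flow and economic layers
-- the expensive nucleus simulation happens once per run and is cached.

The surrogate is Gaussian-process regression (Matern-5/2 kernel, small
observation-noise floor, inputs scaled to the unit cube); candidates are
scored by expected improvement, with multi-point proposals via the
constant-liar strategy.  Integer variables are handled by sampling the
continuous relaxation and rounding.  A uniform random search over the
same space with the same evaluation pipeline serves as the baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .config import ProgramConfig
from .crossbreed import run_whole
from .nucleus import run_core


# ---------------------------------------------------------------------------
# search space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variable:
    name: str
    kind: str                 # "integer" | "continuous"
    lower: float
    upper: float

    def clip_round(self, x: float) -> float:
        x = min(max(x, self.lower), self.upper)
        return float(round(x)) if self.kind == "integer" else float(x)


@dataclass
class SearchSpace:
    """Bounded mixed integer/continuous variables plus fixed context."""

    variables: list[Variable]
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for v in self.variables:
            if v.lower > v.upper:
                raise ValueError(f"variable {v.name}: lower > upper")
            if v.kind == "integer" and (
                v.lower != int(v.lower) or v.upper != int(v.upper)
            ):
                raise ValueError(f"integer variable {v.name} has non-integral bounds")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def dim(self) -> int:
        return len(self.variables)

    def lattice_size(self) -> float:
        """Number of distinct points (inf if any variable is continuous)."""
        size = 1.0
        for v in self.variables:
            if v.kind != "integer":
                return float("inf")
            size *= v.upper - v.lower + 1
        return size

    def to_unit(self, X: np.ndarray) -> np.ndarray:
        lo = np.array([v.lower for v in self.variables])
        hi = np.array([v.upper for v in self.variables])
        span = np.where(hi > lo, hi - lo, 1.0)
        return (np.asarray(X, float) - lo) / span

    def point_dict(self, x: np.ndarray) -> dict[str, float]:
        return {v.name: v.clip_round(xi) for v, xi in zip(self.variables, x)}

    def from_unit_row(self, u: np.ndarray) -> np.ndarray:
        """Map a unit-cube row to the (rounded, clipped) native scale."""
        out = np.empty(self.dim)
        for k, v in enumerate(self.variables):
            if v.kind == "integer":
                # stratified floor so saturated integer ranges enumerate fully
                val = np.floor(v.lower + u[k] * (v.upper - v.lower + 1))
                out[k] = min(max(val, v.lower), v.upper)
            else:
                out[k] = v.lower + u[k] * (v.upper - v.lower)
        return out

    def contains(self, x: np.ndarray) -> bool:
        for v, xi in zip(self.variables, x):
            if not (v.lower - 1e-9 <= xi <= v.upper + 1e-9):
                return False
            if v.kind == "integer" and abs(xi - round(xi)) > 1e-9:
                return False
        return True


def space_from_config(config: ProgramConfig) -> SearchSpace:
    """Build the search space from [optimize.bounds]; the structure
    variables (lifetimes, dam counts) are all integers."""
    variables = [
        Variable(name, "integer", lo, hi)
        for name, (lo, hi) in config.optimize.bounds.items()
    ]
    if not variables:
        raise ValueError("[optimize.bounds] is empty")
    fixed = {}
    if config.system is not None:
        fixed["n_target"] = float(config.system.n_target)
    return SearchSpace(variables=variables, fixed=fixed)


# ---------------------------------------------------------------------------
# records and results
# ---------------------------------------------------------------------------


@dataclass
class EvalRecord:
    point: dict[str, float]
    profit: float
    iteration: int
    source: str                # "initial" | "proposed" | "random"


@dataclass
class OptResult:
    history: list[EvalRecord]
    space: SearchSpace

    @property
    def best(self) -> EvalRecord:
        return max(self.history, key=lambda r: r.profit)

    def history_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.history:
            row = {"iteration": r.iteration, "source": r.source,
                   "profit": r.profit}
            row.update(r.point)
            rows.append(row)
        return pd.DataFrame(rows)

    def best_by_iteration(self) -> pd.DataFrame:
        df = self.history_frame()
        df["cummax_profit"] = df["profit"].cummax()
        return df.groupby("iteration", as_index=False).agg(
            mean_profit=("profit", "mean"),
            best_profit=("cummax_profit", "max"),
        )


# ---------------------------------------------------------------------------
# initial design
# ---------------------------------------------------------------------------


def initial_design(space: SearchSpace, n: int, seed: int) -> np.ndarray:
    """Latin-hypercube design on the unit cube, mapped to the space.

    Integer variables use stratified flooring, so a one-dimensional
    integer range of exactly n values yields each value once.
    """
    if n < 2:
        raise ValueError("initial design needs n >= 2")
    if n > space.lattice_size():
        raise ValueError(
            f"design size {n} exceeds the {int(space.lattice_size())} distinct "
            "integer lattice points"
        )
    sampler = qmc.LatinHypercube(d=space.dim, seed=seed)
    U = sampler.random(n)
    return np.vstack([space.from_unit_row(u) for u in U])


# ---------------------------------------------------------------------------
# surrogate and acquisition
# ---------------------------------------------------------------------------


@dataclass
class Surrogate:
    gp: GaussianProcessRegressor
    space: SearchSpace
    y_mean: float
    y_std: float

    def predict(self, X: np.ndarray, return_std: bool = False):
        U = self.space.to_unit(np.atleast_2d(X))
        if return_std:
            m, s = self.gp.predict(U, return_std=True)
            return m * self.y_std + self.y_mean, s * self.y_std
        return self.gp.predict(U) * self.y_std + self.y_mean


def fit_surrogate(
    history: list[EvalRecord], space: SearchSpace, seed: int = 0
) -> Surrogate:
    """Gaussian-process regression over the evaluated points."""
    if len(history) < 2:
        raise ValueError("need at least two evaluations to fit a surrogate")
    X = np.array([[r.point[n] for n in space.names] for r in history])
    if np.allclose(X, X[0]):
        raise ValueError("degenerate history: all evaluated points identical")
    y = np.array([r.profit for r in history], dtype=float)
    y_mean = float(y.mean())
    y_std = float(y.std()) or 1.0
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * Matern(length_scale=np.full(space.dim, 0.3),
                 length_scale_bounds=(1e-2, 1e2), nu=2.5)
        + WhiteKernel(1e-6, (1e-10, 1e-1))
    )
    gp = GaussianProcessRegressor(
        kernel=kernel, normalize_y=False, n_restarts_optimizer=2,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gp.fit(space.to_unit(X), (y - y_mean) / y_std)
    return Surrogate(gp=gp, space=space, y_mean=y_mean, y_std=y_std)


def expected_improvement(
    surrogate: Surrogate, X: np.ndarray, best: float, xi: float = 0.0
) -> np.ndarray:
    """EI for maximization; non-negative by construction."""
    mu, sd = surrogate.predict(X, return_std=True)
    sd = np.maximum(sd, 1e-12)
    z = (mu - best - xi) / sd
    return np.maximum((mu - best - xi) * norm.cdf(z) + sd * norm.pdf(z), 0.0)


def propose(
    surrogate: Surrogate,
    space: SearchSpace,
    q: int,
    seed: int,
    history: list[EvalRecord] | None = None,
    n_candidates: int = 1024,
) -> list[dict[str, float]]:
    """q expected-improvement proposals via the constant-liar strategy.

    Each round scores a random candidate cloud, takes the EI argmax, then
    refits with the incumbent-best value lied at the chosen point so the
    batch spreads out.  Proposals are pairwise distinct and distinct from
    the history.
    """
    rng = np.random.default_rng(seed)
    seen: set[tuple] = set()
    for r in history or []:
        seen.add(tuple(r.point[n] for n in space.names))
    work_history = list(history or [])
    out: list[dict[str, float]] = []
    surr = surrogate
    best = max((r.profit for r in work_history), default=float(surr.y_mean))
    for _ in range(q):
        U = rng.random((n_candidates, space.dim))
        cand = np.vstack([space.from_unit_row(u) for u in U])
        ei = expected_improvement(surr, cand, best)
        order = np.argsort(-ei)
        chosen = None
        for idx in order:
            key = tuple(space.point_dict(cand[idx]).values())
            if key not in seen:
                chosen = cand[idx]
                break
        if chosen is None:  # space exhausted; fall back to a random point
            chosen = space.from_unit_row(rng.random(space.dim))
        point = space.point_dict(chosen)
        out.append(point)
        seen.add(tuple(point.values()))
        # constant liar: pretend the point scored the incumbent best
        work_history = work_history + [
            EvalRecord(point=point, profit=best, iteration=-1, source="liar")
        ]
        try:
            surr = fit_surrogate(work_history, space,
                                 seed=int(rng.integers(2**31 - 1)))
        except ValueError:
            pass
    return out


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def _make_profit_objective(config: ProgramConfig) -> Callable[[dict], float]:
    """Per-season profit of the whole system as a function of the search
    variables, with the nucleus simulations run once and cached."""
    import copy

    base_reports = {
        b: run_core(config, breed=b) for b in config.system.breeds
    }
    breeds = config.system.breeds

    def objective(point: dict[str, float]) -> float:
        cfg = copy.deepcopy(config)
        for name, value in point.items():
            if name.startswith("yM") and len(name) == 3:
                cfg.system.tier_lifetimes[f"M_{name[2]}"] = int(value)
            elif name.startswith("yH"):
                cfg.system.tier_lifetimes["H_" + name[2:]] = int(value)
            elif name.startswith("nD"):
                cfg.nuclei[name[2:]].n_dams = int(value)
            else:
                raise ValueError(f"unknown structure variable {name!r}")
        rep = run_whole(cfg, nucleus_reports=base_reports)
        return rep.profit.per_season_mean

    objective.fixed_context = {  # type: ignore[attr-defined]
        "n_target": config.system.n_target if config.system else 0,
        **{f"g{b}": float(np.sum(r.mean_delta_g()))
           for b, r in base_reports.items()},
    }
    return objective


def run_opt(
    config: ProgramConfig,
    objective: Callable[[dict], float] | None = None,
    seed: int | None = None,
) -> OptResult:
    """Bayesian optimization: initial design, then ``iterations`` rounds
    of surrogate fit -> q proposals -> evaluation."""
    space = space_from_config(config)
    seed = config.run.seed if seed is None else seed
    if objective is None:
        objective = _make_profit_objective(config)
    n0 = config.optimize.initial_points or min(
        2 * space.dim, int(space.lattice_size())
    )
    n0 = max(n0, 2)
    rng = np.random.default_rng(seed)

    history: list[EvalRecord] = []
    for x in initial_design(space, n0, seed):
        point = space.point_dict(x)
        history.append(EvalRecord(point, float(objective(point)), 0, "initial"))

    for it in range(1, config.optimize.iterations + 1):
        surr = fit_surrogate(history, space, seed=int(rng.integers(2**31 - 1)))
        points = propose(
            surr, space, config.optimize.proposals,
            seed=int(rng.integers(2**31 - 1)), history=history,
        )
        for point in points:
            history.append(
                EvalRecord(point, float(objective(point)), it, "proposed")
            )
    return OptResult(history=history, space=space)


def random_search(
    config: ProgramConfig,
    budget: int | None = None,
    seed: int | None = None,
    objective: Callable[[dict], float] | None = None,
) -> OptResult:
    """Uniform sampling over the same space with the same evaluation and
    recording pipeline; iteration numbers mirror the Bayesian schedule so
    per-iteration distributions are directly comparable."""
    space = space_from_config(config)
    seed = config.run.seed if seed is None else seed
    if objective is None:
        objective = _make_profit_objective(config)
    q = config.optimize.proposals
    n0 = config.optimize.initial_points or min(
        2 * space.dim, int(space.lattice_size())
    )
    n0 = max(n0, 2)
    if budget is None:
        budget = n0 + config.optimize.iterations * q
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    history: list[EvalRecord] = []
    for i in range(budget):
        x = space.from_unit_row(rng.random(space.dim))
        point = space.point_dict(x)
        iteration = 0 if i < n0 else (i - n0) // q + 1
        history.append(
            EvalRecord(point, float(objective(point)), iteration, "random")
        )
    return OptResult(history=history, space=space)


# ---------------------------------------------------------------------------
# synthetic objectives for validation
# ---------------------------------------------------------------------------


def make_quadratic_objective(
    space: SearchSpace,
    optimum: dict[str, float],
    peak: float = 100.0,
    curvature: float = 60.0,
) -> Callable[[dict], float]:
    """Separable concave test objective with a known maximum ``peak`` at
    ``optimum``; used to validate optimizer behavior."""

    spans = {v.name: max(v.upper - v.lower, 1.0) for v in space.variables}

    def f(point: dict[str, float]) -> float:
        pen = sum(
            ((point[k] - optimum[k]) / spans[k]) ** 2 for k in optimum
        )
        return peak - curvature * pen / max(len(optimum), 1)

    return f
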