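"""Parameter estimation: scaled fit error, intermediate-bound penalty and the
two-stage (pattern search + bounded local refinement) optimizer.

The cost is the scaled sum of squared residuals

    cost = sum_conditions sum_species sum_times
           (y_exp - y_pred)^2 / max_t(y_exp)

with y_exp the replicate mean by default.  The per-species scaling by the
peak level keeps low-abundance metabolites from being swamped by abundant
ones.  Because PGH2/PGH3 (and PD) are unmeasurable, their simulated profiles
are constrained below 10 pmol/ug DNA through a smooth quadratic hinge
penalty, which keeps the objective differentiable for the local stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import KineticParameters, ReactionNetwork
from .simulation import (
    InputProfiles,
    Trajectory,
    dense_grid,
    simulate,
)

__all__ = [
    "ExperimentDataset",
    "FitConfig",
    "FitResult",
    "scaled_fit_error",
    "penalized_cost",
    "direct_search",
    "local_refine",
    "fit",
    "default_bounds",
]


@dataclass
class ExperimentDataset:
    """Replicate time-course measurements for one experimental condition.

    ``values`` has shape (n_species, n_times, n_replicates) in pmol/ug DNA.
    """

    condition: str
    species: list[str]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.species), self.times.size, self.values.shape[-1])
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != (species, times, reps) {expected}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must strictly increase")
        if np.any(self.values < 0):
            raise ValueError("measurements must be nonnegative")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[-1]

    @property
    def n_times(self) -> int:
        return self.times.size

    def replicates(self, species: str) -> np.ndarray:
        """(n_times, n_replicates) replicate matrix for one species."""
        return self.values[self.species.index(species)].copy()

    def mean(self, species: str) -> np.ndarray:
        return self.values[self.species.index(species)].mean(axis=1)

    @property
    def means(self) -> np.ndarray:
        return self.values.mean(axis=2)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sp in enumerate(self.species):
            for j, t in enumerate(self.times):
                for r in range(self.n_replicates):
                    rows.append((self.condition, t, sp, r + 1, self.values[i, j, r]))
        return pd.DataFrame(
            rows, columns=["condition", "time_min", "species", "replicate", "value"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str | None = None) -> "ExperimentDataset":
        if condition is not None:
            df = df[df["condition"] == condition]
        conds = df["condition"].unique()
        if len(conds) != 1:
            raise ValueError("dataset frame must contain exactly one condition")
        species = list(dict.fromkeys(df["species"]))  # first-appearance order
        times = np.sort(df["time_min"].unique())
        reps = np.sort(df["replicate"].unique())
        values = np.full((len(species), times.size, reps.size), np.nan)
        t_idx = {t: j for j, t in enumerate(times)}
        r_idx = {r: k for k, r in enumerate(reps)}
        s_idx = {s: i for i, s in enumerate(species)}
        for row in df.itertuples(index=False):
            values[s_idx[row.species], t_idx[row.time_min], r_idx[row.replicate]] = row.value
        if np.any(np.isnan(values)):
            raise ValueError("dataset is not complete over (species, time, replicate)")
        return cls(str(conds[0]), species, times, values)


# ---------------------------------------------------------------------------
# cost functions


def _species_error(y_exp: np.ndarray, y_pred: np.ndarray) -> float | None:
    """Eq-style scaled SSE for one species; None when the species carries no
    signal (all-zero measurements) and cannot be scaled."""
    peak = float(np.max(y_exp))
    if peak <= 0.0:
        return None
    return float(np.sum((y_exp - y_pred) ** 2) / peak)


def scaled_fit_error(
    params: KineticParameters,
    datasets: Mapping[str, ExperimentDataset],
    network: ReactionNetwork,
    profiles: Mapping[str, InputProfiles],
    weights: Mapping[str, float] | None = None,
    trajectories: Mapping[str, Trajectory] | None = None,
    use_replicates: bool = False,
) -> float:
    """Scaled fit error across conditions and measured species.

    ``weights`` default to 1 per species; a zero weight removes the species
    from the sum (the leave-one-out mechanism).  Pass precomputed
    ``trajectories`` (on each dataset's grid) to avoid re-integration.
    With ``use_replicates`` the sum runs over individual replicates instead
    of replicate means.
    """
    weights = dict(weights or {})
    # gather (y_exp, y_pred) per species pooled over the jointly fitted
    # conditions: one peak scale per species, so a condition in which the
    # species sits at a negligible level cannot blow up the denominator
    pooled: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for cond, ds in datasets.items():
        if trajectories is not None and cond in trajectories:
            traj = trajectories[cond]
        else:
            traj = simulate(network, params, profiles[cond], t_eval=ds.times)
        for sp in ds.species:
            if weights.get(sp, 1.0) == 0.0:
                continue
            if sp not in traj.names:
                raise KeyError(f"measured species {sp!r} absent from the model")
            pred = traj[sp]
            if use_replicates:
                reps = ds.replicates(sp)
                pooled.setdefault(sp, []).append(
                    (reps.ravel(), np.repeat(pred, reps.shape[1]))
                )
            else:
                pooled.setdefault(sp, []).append((ds.mean(sp), pred))
    total = 0.0
    for sp, pairs in pooled.items():
        y_exp = np.concatenate([p[0] for p in pairs])
        y_pred = np.concatenate([p[1] for p in pairs])
        err = _species_error(y_exp, y_pred)
        if err is None:
            warnings.warn(
                f"species {sp!r} has all-zero measurements; excluded from "
                "the scaled fit error",
                stacklevel=2,
            )
            continue
        total += weights.get(sp, 1.0) * err
    return total


def intermediate_penalty(
    params: KineticParameters,
    network: ReactionNetwork,
    profiles: Mapping[str, InputProfiles],
    weight: float = 1e3,
    bound: float = 10.0,
    dense_trajectories: Mapping[str, Trajectory] | None = None,
) -> float:
    """Quadratic hinge penalty on unmeasured-intermediate maxima.

    weight * sum_intermediates max(0, max_t x(t) - bound)^2, with the
    maximum scanned on a dense 0.1 min grid.
    """
    from .network import UNMEASURED_INTERMEDIATES

    total = 0.0
    for cond, prof in profiles.items():
        if dense_trajectories is not None and cond in dense_trajectories:
            traj = dense_trajectories[cond]
        else:
            traj = simulate(network, params, prof, t_eval=dense_grid())
        for name in UNMEASURED_INTERMEDIATES:
            if name in traj.names:
                excess = max(0.0, float(traj[name].max()) - bound)
                total += excess**2
    return weight * total


def penalized_cost(
    params: KineticParameters,
    datasets: Mapping[str, ExperimentDataset],
    network: ReactionNetwork,
    profiles: Mapping[str, InputProfiles],
    weights: Mapping[str, float] | None = None,
    penalty_weight: float = 1e3,
    bound: float = 10.0,
    use_replicates: bool = False,
) -> float:
    """Scaled fit error plus the intermediate-bound penalty.

    A single dense integration per condition serves both terms (the dense
    grid contains every measurement time).
    """
    fit_err, pen, _ = _cost_components(
        params, datasets, network, profiles, weights,
        penalty_weight, bound, use_replicates,
    )
    return fit_err + pen


def _cost_components(
    params, datasets, network, profiles, weights,
    penalty_weight, bound, use_replicates, step=0.1,
):
    """(fit_error, penalty, dense trajectories) with one simulation per condition."""
    dense_trajs: dict[str, Trajectory] = {}
    data_trajs: dict[str, Trajectory] = {}
    for cond, ds in datasets.items():
        grid = np.unique(
            np.concatenate([dense_grid(max(60.0, ds.times[-1]), step), ds.times])
        )
        traj = simulate(network, params, profiles[cond], t_eval=grid)
        dense_trajs[cond] = traj
        sel = np.searchsorted(grid, ds.times)
        data_trajs[cond] = Trajectory(
            ds.times, traj.states[sel], traj.names, cond
        )
    fit_err = scaled_fit_error(
        params, datasets, network, profiles, weights,
        trajectories=data_trajs, use_replicates=use_replicates,
    )
    pen = intermediate_penalty(
        params, network, profiles, penalty_weight, bound,
        dense_trajectories=dense_trajs,
    )
    return fit_err, pen, dense_trajs


# ---------------------------------------------------------------------------
# optimizers


def direct_search(
    fun: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    start: np.ndarray,
    seed: int = 0,
    budget: int = 2000,
    initial_mesh: float = 0.25,
    min_mesh: float = 1e-6,
) -> tuple[np.ndarray, float, int]:
    """Mesh-based compass (poll-and-expand) direct search.

    Polls +/- one mesh step per coordinate in a seeded random order; the
    mesh doubles after a successful sweep and halves otherwise.  Steps are
    scaled per parameter by max(|start|, 1e-3), so the search explores each
    constant at its own magnitude.  Deterministic given (seed, start).
    ``budget`` caps the number of cost evaluations beyond the start point;
    budget 0 returns the start.
    """
    lb = np.array([b[0] for b in bounds], dtype=float)
    ub = np.array([b[1] for b in bounds], dtype=float)
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("direct search requires finite bounds")
    x = np.clip(np.asarray(start, dtype=float), lb, ub)
    f = float(fun(x))
    if not np.isfinite(f):
        raise ValueError(f"cost is non-finite at the start point ({f})")
    evals = 0
    if budget <= 0:
        return x, f, evals

    rng = np.random.default_rng(seed)
    scale = np.maximum(np.abs(x), 1e-3)
    mesh = float(initial_mesh)
    n = x.size
    while evals < budget and mesh >= min_mesh:
        improved = False
        for i in rng.permutation(n):
            for sign in (1.0, -1.0):
                cand = x.copy()
                cand[i] = np.clip(x[i] + sign * mesh * scale[i], lb[i], ub[i])
                if cand[i] == x[i]:
                    continue
                fc = float(fun(cand))
                evals += 1
                if np.isfinite(fc) and fc < f:
                    x, f = cand, fc
                    improved = True
                    break
                if evals >= budget:
                    break
            if improved or evals >= budget:
                break
        if improved:
            # expansion is uncapped (steps are clipped into the bounds), so
            # the search can traverse the whole box from a small start
            mesh = min(mesh * 2.0, 1e6)
        else:
            mesh *= 0.5
    return x, f, evals


def local_refine(
    fun: Callable[[np.ndarray], float],
    start: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    tol: float = 1e-8,
    maxiter: int = 100,
    maxfun: int = 3000,
) -> tuple[np.ndarray, float, int]:
    """Bounded local minimization (L-BFGS-B with numerical gradients).

    Guaranteed non-ascent: the better of the start and the solver output is
    returned.
    """
    from scipy.optimize import minimize

    start = np.asarray(start, dtype=float)
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])
    if np.any(start < lb) or np.any(start > ub):
        raise ValueError("start point must lie within bounds")
    f0 = float(fun(start))
    if not np.isfinite(f0):
        raise ValueError(f"cost is non-finite at the start point ({f0})")

    def safe(x: np.ndarray) -> float:
        val = float(fun(x))
        return val if np.isfinite(val) else 1e30

    # finite-difference step scaled to each parameter's magnitude: the ODE
    # solution carries O(rtol) noise, so an absolute 1e-8 step would
    # differentiate solver noise for constants of magnitude ~1e-2
    eps = np.maximum(1e-3 * np.abs(start), 1e-6)
    res = minimize(
        safe,
        start,
        method="L-BFGS-B",
        bounds=list(zip(lb, ub)),
        options={"ftol": tol, "maxiter": maxiter, "maxfun": maxfun, "eps": eps},
    )
    if np.isfinite(res.fun) and res.fun < f0:
        return np.asarray(res.x), float(res.fun), int(res.nfev)
    return start, f0, int(res.nfev)


# ---------------------------------------------------------------------------
# fit pipeline


def default_bounds(network: ReactionNetwork) -> dict[str, tuple[float, float]]:
    """Default box bounds: [0, 100] for kinetic constants, [0, 1] for the
    arbitrary-unit initial enzyme levels (fixing the enzyme scale)."""
    out: dict[str, tuple[float, float]] = {}
    for name in network.param_names:
        out[name] = (0.0, 1.0) if name.startswith("X0_") else (0.0, 100.0)
    return out


@dataclass
class FitConfig:
    """Settings for the two-stage fit."""

    conditions: tuple[str, ...] = ("ctrl", "EPA")
    penalty_weight: float = 1e3
    bound: float = 10.0
    budget: int = 2000           # stage-1 cost evaluations
    rounds: int = 1              # optional repeats of the two-stage pair
    stage2_tol: float = 1e-8
    stage2_maxiter: int = 100
    stage2_maxfun: int = 3000
    initial_mesh: float = 0.25
    penalty_step: float = 0.5    # min; intermediate scan step inside the search
    weights: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    start: KineticParameters | None = None
    use_replicates: bool = False

    def with_weight(self, species: str, weight: float) -> "FitConfig":
        w = dict(self.weights)
        w[species] = weight
        return replace(self, weights=w)


@dataclass
class FitResult:
    """Outcome of a model fit."""

    params: KineticParameters
    x0: dict[str, float]
    cost: float
    penalty: float
    start_cost: float
    stage1_cost: float
    stage2_cost: float
    trajectories: dict[str, Trajectory]
    dense_trajectories: dict[str, Trajectory]
    seed: int
    n_evals_stage1: int
    n_evals_stage2: int
    config: FitConfig

    def to_json_dict(self) -> dict:
        return {
            "parameters": self.params.as_dict(),
            "X0": self.x0,
            "cost": self.cost,
            "penalty": self.penalty,
            "stage_costs": {
                "start": self.start_cost,
                "stage1": self.stage1_cost,
                "stage2": self.stage2_cost,
            },
            "seeds": {"fit": self.seed},
            "n_evals": {
                "stage1": self.n_evals_stage1,
                "stage2": self.n_evals_stage2,
            },
        }


def fit(
    datasets: Mapping[str, ExperimentDataset],
    network: ReactionNetwork,
    profiles: Mapping[str, InputProfiles],
    config: FitConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Estimate all kinetic parameters and initial enzyme levels jointly
    across the configured conditions.

    Stage 1 is a seeded pattern search over the penalized cost; stage 2 a
    bounded local refinement from the stage-1 point.  The initial enzyme
    levels are part of the single parameter vector and therefore shared
    across conditions by construction.
    """
    config = config or FitConfig()
    conds = [c for c in config.conditions if c in datasets]
    if not conds:
        raise ValueError(
            f"no configured condition in the data: {config.conditions} "
            f"vs {tuple(datasets)}"
        )
    ds = {c: datasets[c] for c in conds}
    prof = {c: profiles[c] for c in conds}
    for c, d in ds.items():
        if d.values.size == 0:
            raise ValueError(f"empty dataset for condition {c!r}")

    names = network.param_names
    bounds_map = default_bounds(network)
    bounds_map.update(config.bounds)
    bounds = [bounds_map[n] for n in names]

    if config.start is not None:
        x_start = config.start.to_vector(names)
    else:
        # small-magnitude cold start: kinetic constants in this system are
        # O(1e-2..1); starting low avoids immediate intermediate blow-up
        x_start = np.array([lo + 0.05 * (hi - lo) for lo, hi in bounds])
        x_start = np.minimum(x_start, 0.1)
    x_start = np.clip(x_start, [b[0] for b in bounds], [b[1] for b in bounds])

    def objective(vec: np.ndarray) -> float:
        try:
            p = KineticParameters.from_vector(names, vec)
            f_err, pen, _ = _cost_components(
                p, ds, network, prof, config.weights,
                config.penalty_weight, config.bound, config.use_replicates,
                step=config.penalty_step,
            )
            return f_err + pen
        except (RuntimeError, ValueError, OverflowError, FloatingPointError):
            return np.inf

    f_start = objective(x_start)
    x2 = x_start
    f1 = f2 = float(f_start)
    n1 = n2 = 0
    for rnd in range(max(config.rounds, 1)):
        x1, f1_r, n1_r = direct_search(
            objective, bounds, x2, seed=seed + rnd, budget=config.budget,
            initial_mesh=config.initial_mesh,
        )
        x2, f2_r, n2_r = local_refine(
            objective, x1, bounds,
            tol=config.stage2_tol,
            maxiter=config.stage2_maxiter,
            maxfun=config.stage2_maxfun,
        )
        f1, f2 = float(f1_r), float(f2_r)
        n1 += n1_r
        n2 += n2_r

    params = KineticParameters.from_vector(names, x2)
    fit_err, pen, dense_trajs = _cost_components(
        params, ds, network, prof, config.weights,
        config.penalty_weight, config.bound, config.use_replicates,
    )
    trajs = {
        c: simulate(network, params, prof[c], t_eval=ds[c].times) for c in conds
    }
    return FitResult(
        params=params,
        x0=params.x0(network),
        cost=fit_err,
        penalty=pen,
        start_cost=float(f_start),
        stage1_cost=float(f1),
        stage2_cost=float(f2),
        trajectories=trajs,
        dense_trajectories=dense_trajs,
        seed=seed,
        n_evals_stage1=n1,
        n_evals_stage2=n2,
        config=config,
    )
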