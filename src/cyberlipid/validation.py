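"""Model validation: lack-of-fit F-test, leave-one-out-metabolite
cross-validation, and the activity-switch analysis.

The F-test compares the model's lack of fit against the pure (replicate)
experimental error:

    F = [ sum_cond sum_t (Y - Xbar)^2 / (ne*nt) ]
        / [ sum_cond sum_t sum_r (X - Xbar)^2 / (ne*nt*(nr-1)) ]

A fit *passes* when F is below the lower-tail critical value: the fit error
is then smaller than the replicate error, so the model cannot be rejected
for lack of fit.  Degrees of freedom are computed from the dataset actually
supplied (ne conditions, nt time points, nr replicates), never hard-coded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import (
    ExperimentDataset,
    FitConfig,
    FitResult,
    _species_error,
    fit,
)
from .network import ReactionNetwork, simplified_v, switch_ratio
from .simulation import InputProfiles

__all__ = [
    "ValidationReport",
    "SwitchAnalysis",
    "f_statistic",
    "f_critical",
    "f_test_report",
    "loo_metabolite_cv",
    "switch_surface",
]


def f_statistic(
    fitted: Mapping[str, np.ndarray],
    replicates: Mapping[str, np.ndarray],
) -> float:
    """Lack-of-fit F statistic for one metabolite.

    ``fitted`` maps condition -> simulated values on the measurement grid
    (length nt); ``replicates`` maps condition -> replicate matrix
    (nt, nr).  Requires nr >= 2 for a nonzero pure-error degree of freedom.
    """
    conds = list(fitted)
    if set(conds) != set(replicates):
        raise ValueError("fitted and replicate conditions differ")
    ne = len(conds)
    if ne == 0:
        raise ValueError("at least one condition is required")
    num = 0.0
    den = 0.0
    nt = None
    nr = None
    for c in conds:
        y = np.asarray(fitted[c], dtype=float)
        x = np.asarray(replicates[c], dtype=float)
        if x.ndim != 2:
            raise ValueError(f"replicates for {c!r} must be (times, replicates)")
        if nt is None:
            nt, nr = x.shape
        elif x.shape != (nt, nr):
            raise ValueError("replicate shapes differ across conditions")
        if y.shape != (nt,):
            raise ValueError(f"fitted values for {c!r} do not match the grid")
        xbar = x.mean(axis=1)
        num += float(np.sum((y - xbar) ** 2))
        den += float(np.sum((x - xbar[:, None]) ** 2))
    if nr < 2:
        raise ValueError("F-test requires at least 2 replicates (nr >= 2)")
    df1 = ne * nt
    df2 = ne * nt * (nr - 1)
    if den == 0.0:
        return 0.0 if num == 0.0 else np.inf
    return (num / df1) / (den / df2)


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Lower-tail ``alpha`` quantile of the F(df1, df2) distribution."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.ppf(alpha, df1, df2))


@dataclass
class ValidationReport:
    """Per-metabolite lack-of-fit F values against the critical value."""

    table: pd.DataFrame  # columns: metabolite, F, df1, df2, critical, passed
    alpha: float
    ne: int
    nt: int
    nr: int

    @property
    def all_passed(self) -> bool:
        return bool(self.table["passed"].all())

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def f_test_report(
    fit_result: FitResult,
    datasets: Mapping[str, ExperimentDataset],
    alpha: float = 0.05,
) -> ValidationReport:
    """F-test every measured metabolite of a fit across its conditions."""
    conds = [c for c in fit_result.trajectories if c in datasets]
    if len(conds) < 1:
        raise ValueError("fit and datasets share no condition")
    ds = {c: datasets[c] for c in conds}
    first = ds[conds[0]]
    ne, nt, nr = len(conds), first.n_times, first.n_replicates
    df1 = ne * nt
    df2 = ne * nt * (nr - 1)
    crit = f_critical(alpha, df1, df2)

    common = set(first.species)
    for c in conds[1:]:
        missing = common.symmetric_difference(ds[c].species)
        for sp in sorted(missing):
            warnings.warn(
                f"metabolite {sp!r} not measured in every condition; skipped",
                stacklevel=2,
            )
        common &= set(ds[c].species)

    rows = []
    for sp in sorted(common):
        fitted = {c: fit_result.trajectories[c][sp] for c in conds}
        reps = {c: ds[c].replicates(sp) for c in conds}
        fval = f_statistic(fitted, reps)
        rows.append((sp, fval, df1, df2, crit, fval < crit))
    table = pd.DataFrame(
        rows, columns=["metabolite", "F", "df1", "df2", "critical", "passed"]
    )
    return ValidationReport(table=table, alpha=alpha, ne=ne, nt=nt, nr=nr)


def loo_metabolite_cv(
    datasets: Mapping[str, ExperimentDataset],
    network: ReactionNetwork,
    profiles: Mapping[str, InputProfiles],
    config: FitConfig | None = None,
    metabolite: str = "PGD2",
    seed: int = 0,
) -> tuple[FitResult, float, dict[str, float]]:
    """Leave-one-out-metabolite cross-validation.

    Refits with the held-out metabolite's weight set to zero in the cost —
    its kinetics remain in the ODE system — then scores the *predicted*
    held-out profile against its (unused) measurements with the same scaled
    error as the cost.  Returns (refit, held-out error, per-species errors
    of the fitted species for context).
    """
    config = config or FitConfig()
    some = next(iter(datasets.values()))
    if metabolite not in some.species:
        raise ValueError(f"unknown or unmeasured metabolite {metabolite!r}")
    if metabolite not in network.state_names:
        raise ValueError(f"metabolite {metabolite!r} is not a model state")

    result = fit(
        datasets, network, profiles,
        config=config.with_weight(metabolite, 0.0),
        seed=seed,
    )
    held_out = 0.0
    fitted_errors: dict[str, float] = {}
    for cond, traj in result.trajectories.items():
        ds = datasets[cond]
        for sp in ds.species:
            err = _species_error(ds.mean(sp), traj[sp])
            if err is None:
                continue
            if sp == metabolite:
                held_out += err
            else:
                fitted_errors[sp] = fitted_errors.get(sp, 0.0) + err
    return result, held_out, fitted_errors


@dataclass
class SwitchAnalysis:
    """Simplified activity-control surfaces over an (AA, EPA) grid."""

    aa_grid: np.ndarray
    epa_grid: np.ndarray
    v2: np.ndarray  # vPGH2simp, shape (len(epa_grid), len(aa_grid))
    v3: np.ndarray
    ratio: float    # [AA]switch / [EPA]switch = kPGH3 / kPGH2

    def to_frame(self) -> pd.DataFrame:
        aa, epa = np.meshgrid(self.aa_grid, self.epa_grid)
        return pd.DataFrame(
            {
                "AA": aa.ravel(),
                "EPA": epa.ravel(),
                "vPGH2simp": self.v2.ravel(),
                "vPGH3simp": self.v3.ravel(),
            }
        )


def switch_surface(
    aa_grid: np.ndarray,
    epa_grid: np.ndarray,
    k_pgh2: float,
    k_pgh3: float,
) -> SwitchAnalysis:
    """Evaluate the simplified activity controls over a concentration grid.

    Because the shared eCOX level cancels, dominance depends only on the
    weighted concentrations kPGH2*[AA] vs kPGH3*[EPA]; both surfaces equal
    1 along the ray [AA]/[EPA] = kPGH3/kPGH2.
    """
    aa_grid = np.asarray(aa_grid, dtype=float)
    epa_grid = np.asarray(epa_grid, dtype=float)
    if aa_grid.size == 0 or epa_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if k_pgh2 <= 0 or k_pgh3 <= 0:
        raise ValueError("rate constants must be positive")
    aa, epa = np.meshgrid(aa_grid, epa_grid)
    v2, v3 = simplified_v(aa, epa, k_pgh2, k_pgh3)
    return SwitchAnalysis(
        aa_grid=aa_grid,
        epa_grid=epa_grid,
        v2=v2,
        v3=v3,
        ratio=switch_ratio(k_pgh2, k_pgh3),
    )
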