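"""Bayesian power by Monte Carlo, plus a deterministic semi-analytic oracle.

Bayesian power is the probability that the Bayes factor favoring the true
hypothesis exceeds the evidence threshold: ``eta0`` conditions on H0 being the
data-generating truth, ``eta1`` on H1, and the reported criterion is
``eta = min`` over the hypotheses requested. The Monte-Carlo estimator is the
exact fraction of simulated datasets (successfully fitted) whose BF clears the
threshold; fitted estimates are computed once per dataset and shared across
prior fractions, since the posterior does not depend on ``b``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bayesfactor import bf_for_truth
from .design import DesignError, TimeGrid, TrialDesign
from .fit import fit_many
from .simulate import allocate_conditions, child_rng, _outcome_matrix

__all__ = [
    "PowerEstimate",
    "estimate_power",
    "analytic_power_oracle",
    "oracle_power_estimate",
    "power_grid",
    "FitCache",
]


@dataclass
class PowerEstimate:
    """Monte-Carlo power at one sample size.

    ``per_b`` maps the prior-fraction multiplier J to ``(eta0, eta1, eta)``;
    entries are NaN for hypotheses that were not requested. ``m_effective``
    and ``excluded`` count successful and discarded fits per truth.
    """

    n_subjects: int
    eta0: float
    eta1: float
    eta: float
    per_b: Dict[int, Tuple[float, float, float]]
    m_effective: Dict[str, int] = field(default_factory=dict)
    excluded: Dict[str, int] = field(default_factory=dict)
    singular: Dict[str, int] = field(default_factory=dict)


class FitCache:
    """Per-(truth, N) cache of fitted estimates for one design.

    Lets the sensitivity analysis reuse Monte-Carlo fits whenever two
    prior-fraction searches evaluate the same sample size: the simulated data
    and the fitted (beta2_hat, se2) do not depend on ``b``.
    """

    def __init__(self, design: TrialDesign, method: str = "reml") -> None:
        self.design = design
        self.method = method
        self._store: Dict[Tuple[str, int], Tuple[np.ndarray, np.ndarray, int, int]] = {}

    def estimates(self, truth: str, n_subjects: int):
        key = (truth, int(n_subjects))
        if key not in self._store:
            self._store[key] = _fitted_estimates(
                self.design, truth, int(n_subjects), self.method
            )
        return self._store[key]


def _fitted_estimates(
    design: TrialDesign, truth: str, n_subjects: int, method: str
) -> Tuple[np.ndarray, np.ndarray, int, int]:
    """Simulate ``m`` datasets, fit each; retry failures once, then exclude."""
    m = design.m_datasets
    cond = allocate_conditions(n_subjects)
    outcomes = [
        _outcome_matrix(design, truth, n_subjects, child_rng(design.seed, truth, n_subjects, k))
        for k in range(m)
    ]
    rows = fit_many(
        outcomes, cond, design.times, method=method,
        condition_main_effect=design.condition_main_effect,
    )
    ok = (rows[:, 9] > 0) & (rows[:, 4] > 0)
    failed = np.flatnonzero(~ok)
    for k in failed:
        retry_y = _outcome_matrix(
            design, truth, n_subjects, child_rng(design.seed, truth, n_subjects, int(k), retry=1)
        )
        row = fit_many(
            [retry_y], cond, design.times, method=method,
            condition_main_effect=design.condition_main_effect,
        )[0]
        if row[9] > 0 and row[4] > 0:
            rows[k] = row
            ok[k] = True
    excluded = int((~ok).sum())
    if excluded == m:
        raise DesignError(
            f"all {m} fits failed at N={n_subjects}: the design is degenerate "
            "(check the variance components and time grid)"
        )
    kept = rows[ok]
    singular = int((kept[:, 10] > 0).sum())
    return kept[:, 3].copy(), kept[:, 4].copy(), excluded, singular


def _warn_hu_bound(design: TrialDesign) -> None:
    if design.test == "Hu" and design.bf_threshold >= 2:
        warnings.warn(
            "BF_1u = fit1/0.5 is bounded above by 2; with test='Hu' and "
            f"BF_thres={design.bf_threshold} the power for H1 is identically 0",
            UserWarning,
            stacklevel=3,
        )


def estimate_power(
    design: TrialDesign,
    n_subjects: int,
    j_values: Optional[Sequence[int]] = None,
    method: str = "reml",
    cache: Optional[FitCache] = None,
) -> PowerEstimate:
    """Monte-Carlo Bayesian power at sample size ``n_subjects``.

    For each requested true hypothesis, ``m_datasets`` trials are simulated
    and fitted; for every prior-fraction multiplier J the BF named by the
    design's test selector is evaluated at ``b = J / N_eff`` and compared with
    the threshold.
    """
    if n_subjects < 4:
        raise DesignError("need at least 4 subjects (2 per arm)")
    j_values = tuple(j_values) if j_values is not None else (design.j_fraction,)
    _warn_hu_bound(design)
    if cache is None:
        cache = FitCache(design, method)
    n_eff = design.n_eff(n_subjects)
    etas: Dict[str, Dict[int, float]] = {}
    m_eff: Dict[str, int] = {}
    excl: Dict[str, int] = {}
    sing: Dict[str, int] = {}
    for truth in design.hypotheses:
        beta2s, se2s, excluded, singular = cache.estimates(truth, n_subjects)
        m_eff[truth] = beta2s.size
        excl[truth] = excluded
        sing[truth] = singular
        etas[truth] = {}
        for j in j_values:
            b = j / n_eff
            bfs = bf_for_truth(beta2s, se2s, b, truth, design.test)
            etas[truth][j] = float(np.mean(bfs > design.bf_threshold))
    per_b: Dict[int, Tuple[float, float, float]] = {}
    for j in j_values:
        e0 = etas.get("H0", {}).get(j, math.nan)
        e1 = etas.get("H1", {}).get(j, math.nan)
        e_min = min(v for v in (e0, e1) if not math.isnan(v))
        per_b[j] = (e0, e1, e_min)
    j0 = design.j_fraction if design.j_fraction in j_values else j_values[0]
    eta0, eta1, eta = per_b[j0]
    return PowerEstimate(
        n_subjects=int(n_subjects),
        eta0=eta0,
        eta1=eta1,
        eta=eta,
        per_b=per_b,
        m_effective=m_eff,
        excluded=excl,
        singular=sing,
    )


def analytic_power_oracle(
    design: TrialDesign,
    n_subjects: int,
    truth: str = "H1",
    j: Optional[int] = None,
    b: Optional[float] = None,
) -> float:
    """Deterministic power approximation with the standard error held fixed.

    Treats the estimate as ``beta2_hat ~ N(beta2_true, se^2)`` with ``se`` the
    analytic design value, and integrates the exceedance region of the BF
    (which is a smooth function of ``z = beta2_hat / se``) exactly, using root
    bracketing on the log-BF. No data are simulated and nothing is fitted, so
    it is an independent check on the Monte-Carlo pipeline, up to its one
    approximation: the per-dataset estimated SE is replaced by its analytic
    value.
    """
    if truth not in ("H0", "H1"):
        raise DesignError("truth must be 'H0' or 'H1'")
    se = design.analytic_se(n_subjects)
    if b is None:
        b = design.b(n_subjects, j)
    z_mean = (design.beta2 / se) if truth == "H1" else 0.0
    lo = min(z_mean, 0.0) - 10.0
    hi = max(z_mean, 0.0) + 10.0
    grid = np.linspace(lo, hi, 4001)
    bfs = bf_for_truth(grid * se, np.full(grid.size, se * se), b, truth, design.test)
    with np.errstate(divide="ignore"):
        g = np.log(bfs) - np.log(design.bf_threshold)
    above = g > 0
    if not above.any():
        return 0.0
    # refine every sign change, then sum posterior-predictive mass over the
    # passing intervals under z ~ N(z_mean, 1)
    edges = [lo]
    flips = np.flatnonzero(np.diff(above))
    for i in flips:
        z1, z2 = grid[i], grid[i + 1]
        fun = lambda z: float(
            np.log(bf_for_truth(np.array([z * se]), np.array([se * se]), b, truth, design.test)[0])
            - np.log(design.bf_threshold)
        )
        edges.append(optimize.brentq(fun, z1, z2, xtol=1e-12))
    edges.append(hi)
    power = 0.0
    for i in range(len(edges) - 1):
        mid = 0.5 * (edges[i] + edges[i + 1])
        idx = min(np.searchsorted(grid, mid), grid.size - 1)
        if above[max(idx - 1, 0)] or above[idx]:
            a = -np.inf if i == 0 else edges[i]
            c = np.inf if i == len(edges) - 2 else edges[i + 1]
            power += stats.norm.cdf(c - z_mean) - stats.norm.cdf(a - z_mean)
    return float(min(max(power, 0.0), 1.0))


def oracle_power_estimate(
    design: TrialDesign, n_subjects: int, j: Optional[int] = None
) -> PowerEstimate:
    """Deterministic :class:`PowerEstimate` built from the analytic oracle.

    Drop-in replacement for :func:`estimate_power` in the sample-size search
    (no simulation, no fitting); used to validate the search logic.
    """
    jj = design.j_fraction if j is None else j
    e0 = (
        analytic_power_oracle(design, n_subjects, "H0", jj)
        if "H0" in design.hypotheses
        else math.nan
    )
    e1 = (
        analytic_power_oracle(design, n_subjects, "H1", jj)
        if "H1" in design.hypotheses
        else math.nan
    )
    eta = min(v for v in (e0, e1) if not math.isnan(v))
    return PowerEstimate(
        n_subjects=int(n_subjects),
        eta0=e0,
        eta1=e1,
        eta=eta,
        per_b={jj: (e0, e1, eta)},
    )


def power_grid(
    design: TrialDesign,
    n_subjects: Iterable[int],
    durations: Optional[Iterable[float]] = None,
    frequencies: Optional[Iterable[float]] = None,
    method: str = "reml",
) -> pd.DataFrame:
    """Power sweep over N x D x f, one row per cell.

    When durations/frequencies are given, the time grid is rebuilt as
    ``T_j = (j-1)/f`` up to ``D`` (with the design's log settings); otherwise
    the design's own grid is used for every N.
    """
    rows = []
    ds = list(durations) if durations is not None else [None]
    fs = list(frequencies) if frequencies is not None else [None]
    from dataclasses import replace

    for d in ds:
        for f in fs:
            if d is None or f is None:
                dsn = design
            else:
                grid = TimeGrid.from_duration(
                    d, f, design.time_grid.log_growth, design.time_grid.log_shift
                )
                dsn = replace(design, time_grid=grid)
            for n in n_subjects:
                est = estimate_power(dsn, int(n), method=method)
                rows.append(
                    {
                        "D": d if d is not None else dsn.time_grid.raw_times[-1],
                        "f": f if f is not None else math.nan,
                        "N": int(n),
                        "eta0": est.eta0,
                        "eta1": est.eta1,
                        "eta": est.eta,
                    }
                )
    return pd.DataFrame(rows)
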