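"""Design algebra for two-arm longitudinal trials with person-level growth curves.

A trial measures ``N`` subjects at a common set of ``n`` occasions ``T_1..T_n``
and models the outcome with a two-level growth model: person-specific intercepts
and time slopes (bivariate-normal random effects) plus a fixed
treatment-by-time interaction ``beta2`` that carries the intervention effect.
Log-linear growth is linear growth on the log-transformed time axis.

This module holds everything that can be computed from the design alone, before
any data exist: time grids, the analytic standard error of the interaction
estimate, the effective sample size of the correlated longitudinal sample, and
the fraction ``b`` of information used to build the default Bayes-factor prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "DesignError",
    "TimeGrid",
    "VarianceComponents",
    "EffectSpec",
    "TrialDesign",
    "build_time_grid",
    "transform_times",
    "beta2_from_effect",
    "analytic_se_beta2",
    "gls_se_beta2",
    "effective_sample_size",
    "b_fraction",
]


class DesignError(ValueError):
    """Raised when a trial design is internally inconsistent or degenerate."""


def build_time_grid(duration: float, frequency: float) -> np.ndarray:
    """Measurement times for a study of duration ``D`` observed ``f`` times per unit.

    The grid is ``T_j = (j - 1)/f`` for ``j = 1, ..., f*D + 1``: the first
    measurement is at baseline (time 0) and the last at time ``D``.

    Parameters
    ----------
    duration : float
        Study duration ``D`` in study time units (> 0).
    frequency : float
        Observations per unit time ``f`` (> 0). ``f * D`` must be a whole
        number, otherwise the grid would not terminate at ``D``.

    Returns
    -------
    numpy.ndarray of shape ``(f*D + 1,)``
    """
    if duration <= 0:
        raise DesignError(f"duration must be positive, got {duration}")
    if frequency <= 0:
        raise DesignError(f"frequency must be positive, got {frequency}")
    fd = frequency * duration
    if abs(fd - round(fd)) > 1e-9:
        raise DesignError(
            f"frequency * duration = {fd} is not a whole number; the grid "
            "T_j = (j-1)/f presumes a whole count of measurement intervals. "
            "Pass explicit time points for irregular designs."
        )
    n = int(round(fd)) + 1
    return np.arange(n, dtype=float) / frequency


def transform_times(
    times: Sequence[float], log_growth: bool = False, log_shift: float = 0.0
) -> np.ndarray:
    """Apply the (optional) log transform that turns linear into log-linear growth.

    Returns ``times`` unchanged when ``log_growth`` is false, otherwise
    ``ln(t + log_shift)`` element-wise. The natural log is order preserving, so
    a strictly increasing grid stays strictly increasing.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise DesignError("times must be a 1-d vector with at least 2 entries")
    if np.any(np.diff(t) <= 0):
        raise DesignError("times must be strictly increasing")
    if not log_growth:
        return t.copy()
    if log_shift < 0:
        raise DesignError(f"log_shift must be non-negative, got {log_shift}")
    shifted = t + log_shift
    if np.any(shifted <= 0):
        bad = t[shifted <= 0][0]
        raise DesignError(
            f"cannot log-transform time {bad} (t + shift = {bad + log_shift} <= 0); "
            "supply a positive log_shift (a shift of 1 keeps baseline at log(1)=0)"
        )
    return np.log(shifted)


def beta2_from_effect(delta: float, var_u1: float) -> float:
    """Interaction coefficient implied by a standardized effect size.

    ``beta2 = delta * sqrt(var_u1)``: the slope difference between arms
    expressed in units of the between-person slope standard deviation.
    """
    if delta < 0:
        raise DesignError(
            "delta must be non-negative; a negative expected effect is handled "
            "by the direction flag (testing beta2 < 0 with |delta| is "
            "equivalent to testing beta2 > 0 after sign reflection)"
        )
    if var_u1 < 0:
        raise DesignError(f"var_u1 must be non-negative, got {var_u1}")
    return float(delta) * float(np.sqrt(var_u1))


@dataclass(frozen=True)
class TimeGrid:
    """A common measurement schedule, possibly on the log time scale.

    ``transformed_times`` is the axis on which growth is linear and on which
    both simulation and model fitting operate.
    """

    raw_times: np.ndarray
    log_growth: bool = False
    log_shift: float = 0.0
    transformed_times: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_times, dtype=float)
        if raw.ndim != 1 or raw.size < 2:
            raise DesignError("a time grid needs at least two occasions")
        if raw[0] < 0:
            raise DesignError("the first measurement time must be >= 0")
        object.__setattr__(self, "raw_times", raw)
        object.__setattr__(
            self,
            "transformed_times",
            transform_times(raw, self.log_growth, self.log_shift),
        )

    @classmethod
    def from_duration(
        cls, duration: float, frequency: float, log_growth: bool = False, log_shift: float = 0.0
    ) -> "TimeGrid":
        return cls(build_time_grid(duration, frequency), log_growth, log_shift)

    @property
    def n_occasions(self) -> int:
        return self.raw_times.size


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of the two-level growth model.

    ``var_e`` is the level-1 residual variance, ``var_u0``/``var_u1`` the
    between-person intercept/slope variances and ``cov_u01`` their covariance;
    the 2x2 random-effect covariance must be positive semi-definite.
    """

    var_e: float
    var_u0: float = 0.0
    var_u1: float = 0.0
    cov_u01: float = 0.0

    def __post_init__(self) -> None:
        if self.var_e < 0:
            raise DesignError(f"var_e must be >= 0, got {self.var_e}")
        if self.var_u0 < 0 or self.var_u1 < 0:
            raise DesignError("random-effect variances must be >= 0")
        if self.cov_u01**2 > self.var_u0 * self.var_u1 + 1e-300:
            raise DesignError(
                "cov_u01^2 exceeds var_u0 * var_u1: the random-effect "
                "covariance matrix is not positive semi-definite"
            )

    @property
    def sigma_u(self) -> np.ndarray:
        """The 2x2 random-effect covariance matrix."""
        return np.array(
            [[self.var_u0, self.cov_u01], [self.cov_u01, self.var_u1]], dtype=float
        )

    def marginal_variance(self, t: np.ndarray | float) -> np.ndarray | float:
        """Var(Y) at time ``t``: var_u0 + 2 t cov + t^2 var_u1 + var_e."""
        t = np.asarray(t, dtype=float)
        return self.var_u0 + 2.0 * t * self.cov_u01 + t**2 * self.var_u1 + self.var_e


@dataclass(frozen=True)
class EffectSpec:
    """Fixed-effect specification: grand intercept, control slope, effect size.

    ``delta`` is the standardized interaction effect (non-negative); a negative
    expected effect is expressed with ``direction=-1`` and ``delta=|delta|``,
    which is equivalent under sign reflection of the hypothesis. An explicit
    ``beta2`` overrides the standardized parameterization (needed e.g. when
    the slope variance is zero, where ``delta * sqrt(var_u1)`` degenerates).
    """

    delta: float
    beta0: float = 0.0
    beta1: float = 0.0
    direction: int = 1
    beta2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise DesignError(
                "delta must be >= 0; use direction=-1 for a negative expected effect"
            )
        if self.direction not in (-1, 1):
            raise DesignError("direction must be +1 or -1")


def _time_ss(times: np.ndarray, centered: bool) -> float:
    t = np.asarray(times, dtype=float)
    s = float(np.sum((t - t.mean()) ** 2)) if centered else float(np.sum(t**2))
    return s


def analytic_se_beta2(
    vc: VarianceComponents,
    times: Sequence[float],
    n_subjects: int,
    centered: bool = True,
) -> float:
    """Analytic standard error of the interaction estimate for a balanced trial.

    ``sqrt(4 (var_e + var_u1 * S) / (N * S))`` with ``S`` the time sum of
    squares. With ``centered=True`` (the default) ``S = sum((T_j - mean T)^2)``,
    which is the exact sampling variance of the treatment-by-time coefficient
    in the balanced two-arm growth model with arm-specific intercepts;
    ``centered=False`` uses the raw ``sum(T_j^2)``, exact only when the
    intercept variance is zero. See ``gls_se_beta2`` for the full-information
    variant without a condition main effect.
    """
    if n_subjects < 2:
        raise DesignError("need at least 2 subjects")
    if vc.var_e <= 0:
        raise DesignError("analytic SE requires var_e > 0")
    s = _time_ss(np.asarray(times, dtype=float), centered)
    if s <= 0:
        raise DesignError("time sum of squares is zero (single distinct time)")
    return float(np.sqrt(4.0 * (vc.var_e + vc.var_u1 * s) / (n_subjects * s)))


def gls_se_beta2(
    vc: VarianceComponents,
    times: Sequence[float],
    n_subjects: int,
    condition_main_effect: bool = True,
) -> float:
    """Exact GLS standard error of ``beta2`` under known variance components.

    Computed from the per-subject marginal covariance
    ``V = var_e I + Z Sigma_u Z'`` (``Z = [1, T]``) and the balanced two-arm
    information matrix. With a condition main effect this equals the centered
    variant of :func:`analytic_se_beta2`; without it the variance is
    ``4 / (N * T' V^{-1} T)``, which is smaller because the common intercept
    borrows strength across arms.
    """
    if n_subjects < 2:
        raise DesignError("need at least 2 subjects")
    if vc.var_e <= 0:
        raise DesignError("GLS SE requires var_e > 0")
    t = np.asarray(times, dtype=float)
    n = t.size
    w = np.column_stack([np.ones(n), t])
    v = vc.var_e * np.eye(n) + w @ vc.sigma_u @ w.T
    vinv = np.linalg.inv(v)
    if condition_main_effect:
        winfo = w.T @ vinv @ w  # 2x2
        var = 4.0 * np.linalg.inv(winfo)[1, 1] / n_subjects
    else:
        var = 4.0 / (n_subjects * float(t @ vinv @ t))
    return float(np.sqrt(var))


def effective_sample_size(
    vc: VarianceComponents,
    times: Sequence[float],
    n_subjects: int,
    centered: bool = True,
) -> float:
    """Effective sample size of the correlated longitudinal sample.

    The size of a hypothetical independent sample carrying the same
    information about ``beta2``. A weight ``w`` is formed as the ratio of the
    OLS variance of the interaction coefficient under a working model with all
    ``N*n`` observations independent and homoscedastic (variance equal to the
    average marginal variance over the grid) to the actual variance from
    :func:`analytic_se_beta2`; then ``N_eff = w * N * n``, clamped to
    ``[N, N*n]`` since the truth must lie between fully dependent and fully
    independent observations.
    """
    t = np.asarray(times, dtype=float)
    n = t.size
    if n < 2:
        raise DesignError("need at least 2 occasions")
    if n_subjects < 2:
        raise DesignError("need at least 2 subjects")
    var_actual = analytic_se_beta2(vc, t, n_subjects, centered=centered) ** 2
    sigma_bar2 = (
        vc.var_e
        + vc.var_u0
        + (2.0 / n) * float(np.sum(t)) * vc.cov_u01
        + (1.0 / n) * float(np.sum(t**2)) * vc.var_u1
    )
    s = _time_ss(t, centered)
    var_indep = 4.0 * sigma_bar2 / (n_subjects * s)
    weight = var_indep / var_actual
    n_eff = weight * n_subjects * n
    return float(min(max(n_eff, float(n_subjects)), float(n_subjects * n)))


def b_fraction(j: int, n_eff: float) -> float:
    """Prior fraction ``b = J / N_eff`` (minimal training sample principle)."""
    if j not in (1, 2, 3):
        raise DesignError(f"J must be 1, 2 or 3, got {j}")
    if n_eff <= 0:
        raise DesignError("N_eff must be positive")
    return float(j) / float(n_eff)


@dataclass(frozen=True)
class TrialDesign:
    """Complete specification of a two-arm longitudinal trial design.

    Bundles the measurement schedule, variance components, effect size and
    the Bayes-factor evaluation settings (threshold, target power, Monte-Carlo
    size, prior fraction multiplier, hypothesis and comparison selectors).
    """

    time_grid: TimeGrid
    vc: VarianceComponents
    effect: EffectSpec
    bf_threshold: float = 3.0
    eta_target: float = 0.8
    m_datasets: int = 1000
    j_fraction: int = 1
    hypothesis: Literal["H0", "H1", "both"] = "both"
    test: Literal["alt", "Hc", "Hu"] = "alt"
    seed: Optional[int] = None
    condition_main_effect: bool = True
    se_centered: bool = True

    def __post_init__(self) -> None:
        if self.bf_threshold <= 0:
            raise DesignError("bf_threshold must be > 0")
        if not 0 < self.eta_target < 1:
            raise DesignError("eta_target must be in (0, 1)")
        if self.m_datasets < 1:
            raise DesignError("m_datasets must be >= 1")
        if self.j_fraction not in (1, 2, 3):
            raise DesignError("j_fraction must be 1, 2 or 3")
        if self.hypothesis not in ("H0", "H1", "both"):
            raise DesignError(f"unknown hypothesis selector {self.hypothesis!r}")
        if self.test not in ("alt", "Hc", "Hu"):
            raise DesignError(f"unknown test selector {self.test!r}")

    @property
    def times(self) -> np.ndarray:
        """Times on the analysis scale (log-transformed when requested)."""
        return self.time_grid.transformed_times

    @property
    def n_occasions(self) -> int:
        return self.time_grid.n_occasions

    @property
    def beta2(self) -> float:
        """Generating interaction coefficient under H1."""
        if self.effect.beta2 is not None:
            return float(self.effect.beta2)
        return beta2_from_effect(self.effect.delta, self.vc.var_u1)

    def analytic_se(self, n_subjects: int) -> float:
        return analytic_se_beta2(self.vc, self.times, n_subjects, centered=self.se_centered)

    def n_eff(self, n_subjects: int) -> float:
        return effective_sample_size(
            self.vc, self.times, n_subjects, centered=self.se_centered
        )

    def b(self, n_subjects: int, j: Optional[int] = None) -> float:
        return b_fraction(self.j_fraction if j is None else j, self.n_eff(n_subjects))

    @property
    def hypotheses(self) -> tuple[str, ...]:
        """The true data-generating hypotheses requested for power."""
        return ("H0", "H1") if self.hypothesis == "both" else (self.hypothesis,)
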