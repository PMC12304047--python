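"""Approximate adjusted fractional Bayes factors for one growth parameter.

The Bayes factor is built from a frequentist estimate and its standard error:
the posterior of ``beta2`` is approximated by ``N(beta2_hat, se2)`` and the
default prior by ``N(0, se2 / b)``, a normal centered at the constraint
boundary whose variance is inflated by the reciprocal of the information
fraction ``b``. For each hypothesis the *fit* is the share of the posterior in
agreement with it (density at the point for an equality constraint, tail mass
for an inequality) and the *complexity* the same share under the prior; a BF
against the unconstrained hypothesis is fit/complexity, and a BF between two
hypotheses is the ratio of those ratios.

Supported constraints are exactly ``beta2 = 0``, ``beta2 > 0`` and its
complement ``beta2 <= 0``; a ``beta2 < 0`` research hypothesis is handled by
sign reflection. All densities are evaluated on the log scale internally so
extreme ``|beta2_hat| / SE`` cannot underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .design import DesignError

__all__ = ["BFResult", "fit_and_complexity", "aafbf", "bf_for_truth"]

_LOG_HALF = float(np.log(0.5))


def _check(se2, b) -> None:
    if np.any(np.asarray(se2) <= 0):
        raise DesignError("se2 must be positive")
    b = np.asarray(b)
    if np.any(b <= 0) or np.any(b > 1):
        raise DesignError("the prior fraction b must lie in (0, 1]")


def _log_parts(beta2_hat, se2, b):
    """Log fit and complexity of H0 (density) and H1 (upper-tail mass)."""
    beta2_hat = np.asarray(beta2_hat, dtype=float)
    se = np.sqrt(np.asarray(se2, dtype=float))
    log_fit0 = stats.norm.logpdf(0.0, loc=beta2_hat, scale=se)
    log_comp0 = stats.norm.logpdf(0.0, loc=0.0, scale=se / np.sqrt(b))
    z = beta2_hat / se
    log_fit1 = stats.norm.logsf(-z)  # P(beta2 > 0 | posterior)
    log_fitc = stats.norm.logcdf(-z)  # P(beta2 <= 0 | posterior)
    return log_fit0, log_comp0, log_fit1, log_fitc


@dataclass(frozen=True)
class BFResult:
    """All fits, complexities and Bayes factors for one estimate at one b."""

    beta2_hat: float
    se2: float
    b: float
    fit0: float
    comp0: float
    fit1: float
    comp1: float
    bf_0u: float
    bf_1u: float
    bf_01: float
    bf_10: float
    bf_1c: float
    bf_0c: float

    @property
    def post_mean(self) -> float:
        return self.beta2_hat

    @property
    def post_var(self) -> float:
        return self.se2

    @property
    def prior_var(self) -> float:
        return self.se2 / self.b


def fit_and_complexity(
    beta2_hat: float, se2: float, b: float, hypothesis: Literal["H0", "H1", "Hc"]
) -> tuple[float, float]:
    """Fit and complexity of one hypothesis.

    H0 (``beta2 = 0``): posterior density at 0 and prior density at 0.
    H1 (``beta2 > 0``): posterior upper-tail mass and complexity exactly 0.5
    (the prior is symmetric about the boundary, whatever ``b``).
    Hc (``beta2 <= 0``): the complements, ``1 - fit1`` and 0.5.
    """
    _check(se2, b)
    log_fit0, log_comp0, log_fit1, log_fitc = _log_parts(beta2_hat, se2, b)
    if hypothesis == "H0":
        return float(np.exp(log_fit0)), float(np.exp(log_comp0))
    if hypothesis == "H1":
        return float(np.exp(log_fit1)), 0.5
    if hypothesis == "Hc":
        return float(np.exp(log_fitc)), 0.5
    raise DesignError(f"unknown hypothesis {hypothesis!r}")


def aafbf(beta2_hat: float, se2: float, b: float, direction: int = 1) -> BFResult:
    """All Bayes factors for one estimate, standard error and prior fraction.

    ``direction=-1`` reflects the estimate so that a ``beta2 < 0`` research
    hypothesis is evaluated as ``beta2 > 0`` on the mirrored scale.
    """
    _check(se2, b)
    if direction not in (1, -1):
        raise DesignError("direction must be +1 or -1")
    bh = direction * float(beta2_hat)
    log_fit0, log_comp0, log_fit1, log_fitc = _log_parts(bh, se2, b)
    log_bf_0u = log_fit0 - log_comp0
    log_bf_1u = log_fit1 - _LOG_HALF
    log_bf_cu = log_fitc - _LOG_HALF
    np_err = np.errstate(over="ignore")  # extreme |z| saturates to inf honestly
    with np_err:
        return _build_result(
            bh, se2, b, log_fit0, log_comp0, log_fit1, log_bf_0u, log_bf_1u,
            log_fitc, log_bf_cu,
        )


def _build_result(bh, se2, b, log_fit0, log_comp0, log_fit1, log_bf_0u,
                  log_bf_1u, log_fitc, log_bf_cu) -> BFResult:
    return BFResult(
        beta2_hat=bh,
        se2=float(se2),
        b=float(b),
        fit0=float(np.exp(log_fit0)),
        comp0=float(np.exp(log_comp0)),
        fit1=float(np.exp(log_fit1)),
        comp1=0.5,
        bf_0u=float(np.exp(log_bf_0u)),
        bf_1u=float(np.exp(log_bf_1u)),
        bf_01=float(np.exp(log_bf_0u - log_bf_1u)),
        bf_10=float(np.exp(log_bf_1u - log_bf_0u)),
        bf_1c=float(np.exp(log_fit1 - log_fitc)),
        bf_0c=float(np.exp(log_bf_0u - log_bf_cu)),
    )


def bf_for_truth(
    beta2_hat: np.ndarray,
    se2: np.ndarray,
    b: float,
    truth: Literal["H0", "H1"],
    test: Literal["alt", "Hc", "Hu"],
    direction: int = 1,
) -> np.ndarray:
    """Vectorized BF favoring the true hypothesis, as the power engine needs it.

    Under an H0 truth: ``alt`` gives BF_01, ``Hu`` gives BF_0u and ``Hc`` also
    gives BF_0u — the complement of an equality constraint is (up to a null
    set) the unconstrained hypothesis, so H0 is compared against Hu. Under an
    H1 truth: ``alt`` gives BF_10, ``Hc`` gives BF_1c = fit1/(1-fit1) and
    ``Hu`` gives BF_1u, which is bounded above by 2.
    """
    _check(se2, b)
    bh = direction * np.asarray(beta2_hat, dtype=float)
    log_fit0, log_comp0, log_fit1, log_fitc = _log_parts(bh, se2, b)
    log_bf_0u = log_fit0 - log_comp0
    log_bf_1u = log_fit1 - _LOG_HALF
    with np.errstate(over="ignore"):
        if truth == "H0":
            if test == "alt":
                return np.exp(log_bf_0u - log_bf_1u)
            return np.exp(log_bf_0u)
        if truth == "H1":
            if test == "alt":
                return np.exp(log_bf_1u - log_bf_0u)
            if test == "Hc":
                return np.exp(log_fit1 - log_fitc)
            return np.exp(log_bf_1u)
    raise DesignError(f"truth must be 'H0' or 'H1', got {truth!r}")
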