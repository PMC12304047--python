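"""Growth-model estimation: the Model/Results surface over the balanced fitter.

`GrowthModel` fits the two-level growth model to one balanced trial dataset by
REML (default) or ML and returns a `GrowthModelResults` carrying the fixed
effects, their standard errors, the variance-component estimates and
convergence diagnostics. The Bayes-factor machinery consumes exactly two of
these numbers: the interaction estimate ``beta2_hat`` and its squared standard
error ``se2_beta2``.

By default the fixed part is ``1 + time + condition + condition:time``; the
reduced structure without the condition main effect (randomization guarantees
equal baseline means in expectation) is available via
``condition_main_effect=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from ._balanced import _fit_many, _fit_one, suffstats
from .design import DesignError, VarianceComponents
from .simulate import TrialData

__all__ = ["GrowthModel", "GrowthModelResults", "fit_growth_model", "gls_beta2"]


@dataclass(frozen=True)
class GrowthModelResults:
    """Estimates from one growth-model fit.

    ``fixed_effects`` is keyed by term name; ``se2_beta2`` is the squared
    standard error of the treatment-by-time coefficient, strictly positive
    whenever the fit converged on noisy data.
    """

    beta2_hat: float
    se2_beta2: float
    fixed_effects: dict
    vc_hat: VarianceComponents
    converged: bool
    singular: bool
    method: str

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fixed_effects)

    @property
    def se_beta2(self) -> float:
        return float(np.sqrt(self.se2_beta2))

    def summary(self) -> str:
        lines = [
            f"Two-level growth model ({self.method.upper()})",
            "-" * 44,
            f"{'term':<18}{'estimate':>12}",
        ]
        for name, val in self.fixed_effects.items():
            lines.append(f"{name:<18}{val:>12.6f}")
        lines += [
            "-" * 44,
            f"beta2 (condition:time)  {self.beta2_hat:.6f}  SE {self.se_beta2:.6f}",
            f"var_e {self.vc_hat.var_e:.6g}  var_u0 {self.vc_hat.var_u0:.6g}  "
            f"var_u1 {self.vc_hat.var_u1:.6g}  cov {self.vc_hat.cov_u01:.6g}",
            f"converged: {self.converged}  singular: {self.singular}",
        ]
        return "\n".join(lines)


def _unpack(row: np.ndarray, main_effect: bool, method: str) -> GrowthModelResults:
    names = ["intercept", "time"]
    fe = {"intercept": float(row[0]), "time": float(row[1])}
    if main_effect:
        fe["condition"] = float(row[2])
    fe["condition:time"] = float(row[3])
    vc = VarianceComponents(
        var_e=max(float(row[5]), 0.0),
        var_u0=max(float(row[6]), 0.0),
        var_u1=max(float(row[7]), 0.0),
        cov_u01=float(row[8]),
    )
    return GrowthModelResults(
        beta2_hat=float(row[3]),
        se2_beta2=float(row[4]),
        fixed_effects=fe,
        vc_hat=vc,
        converged=bool(row[9]),
        singular=bool(row[10]),
        method=method,
    )


class GrowthModel:
    """Two-level linear growth model for a balanced two-arm trial.

    Parameters
    ----------
    data : TrialData or pandas.DataFrame
        Balanced trial data; a DataFrame must be in long format with columns
        ``subject, condition, time, y``.
    condition_main_effect : bool
        Include a condition main effect in the fixed part (default True).
    """

    def __init__(
        self,
        data: Union[TrialData, pd.DataFrame],
        condition_main_effect: bool = True,
    ) -> None:
        if isinstance(data, pd.DataFrame):
            data = TrialData.from_frame(data)
        if not isinstance(data, TrialData):
            raise DesignError("data must be a TrialData or a long-format DataFrame")
        counts = np.bincount(data.condition, minlength=2)
        if counts.min() < 2:
            raise DesignError("need at least 2 subjects per arm")
        self.data = data
        self.condition_main_effect = bool(condition_main_effect)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, condition_main_effect: bool = True
    ) -> "GrowthModel":
        return cls(df, condition_main_effect=condition_main_effect)

    def fit(self, method: str = "reml") -> GrowthModelResults:
        method = method.lower()
        if method not in ("reml", "ml"):
            raise DesignError(f"method must be 'reml' or 'ml', got {method!r}")
        d = self.data
        counts, trq, wqw, ws = suffstats(d.outcomes, d.condition, d.times)
        p_mat = _w_gram(d.times)
        p = 4 if self.condition_main_effect else 3
        row = _fit_one(p_mat, counts, trq, wqw, ws, d.n_occasions, p, method == "reml")
        return _unpack(row, self.condition_main_effect, method)


def _w_gram(times: np.ndarray) -> np.ndarray:
    w = np.column_stack([np.ones(times.size), times])
    return w.T @ w


def fit_growth_model(
    data: Union[TrialData, pd.DataFrame],
    method: str = "reml",
    condition_main_effect: bool = True,
) -> GrowthModelResults:
    """Convenience wrapper: ``GrowthModel(data).fit(method)``."""
    return GrowthModel(data, condition_main_effect=condition_main_effect).fit(method)


def fit_many(
    outcome_list, condition: np.ndarray, times: np.ndarray,
    method: str = "reml", condition_main_effect: bool = True,
) -> np.ndarray:
    """Fit a batch of datasets sharing one design; rows as in ``_fit_one``.

    ``outcome_list`` is an iterable of ``(N, n)`` outcome matrices. This is the
    fast path used by the power engine.
    """
    w = np.column_stack([np.ones(times.size), times])
    p_mat = w.T @ w
    ys = np.stack([np.asarray(y, dtype=float) for y in outcome_list])
    m = ys.shape[0]
    is_t = condition == 1
    counts = np.empty((m, 2))
    trq = np.empty((m, 2))
    wqw = np.empty((m, 2, 2, 2))
    ws = np.empty((m, 2, 2))
    for g, mask in enumerate((~is_t, is_t)):
        yg = ys[:, mask, :]
        counts[:, g] = mask.sum()
        trq[:, g] = np.einsum("mij,mij->m", yg, yg)
        bg = yg @ w
        wqw[:, g] = np.einsum("mik,mil->mkl", bg, bg)
        ws[:, g] = bg.sum(axis=1)
    p = 4 if condition_main_effect else 3
    return _fit_many(p_mat, counts, trq, wqw, ws, times.size, p, method.lower() == "reml")


def gls_beta2(
    data: Union[TrialData, pd.DataFrame],
    vc_known: VarianceComponents,
    condition_main_effect: bool = True,
) -> GrowthModelResults:
    """GLS fixed effects with *known* variance components.

    The marginal covariance per subject is ``V = var_e I + W Sigma_u W'``.
    Used as a fast oracle in tests and the semi-analytic power check; for
    balanced data its standard error reproduces the analytic design formula
    exactly.
    """
    if isinstance(data, pd.DataFrame):
        data = TrialData.from_frame(data)
    t = data.times
    n = t.size
    w = np.column_stack([np.ones(n), t])
    v = vc_known.var_e * np.eye(n) + w @ vc_known.sigma_u @ w.T
    try:
        vinv = np.linalg.inv(v)
    except np.linalg.LinAlgError as err:
        raise DesignError("singular marginal covariance") from err
    p = 4 if condition_main_effect else 3
    # per-arm design maps (see _balanced._design_blocks)
    a_c = np.zeros((2, p)); a_t = np.zeros((2, p))
    a_c[0, 0] = a_c[1, 1] = a_t[0, 0] = a_t[1, 1] = 1.0
    if p == 4:
        a_t[0, 2] = a_t[1, 3] = 1.0
    else:
        a_t[1, 2] = 1.0
    winfo = w.T @ vinv @ w
    m_mat = np.zeros((p, p))
    u = np.zeros(p)
    for g, a_g in enumerate((a_c, a_t)):
        yg = data.outcomes[data.condition == g]
        m_mat += yg.shape[0] * a_g.T @ winfo @ a_g
        u += a_g.T @ (w.T @ vinv @ yg.sum(axis=0))
    cov = np.linalg.inv(m_mat)
    beta = cov @ u
    fe = {"intercept": float(beta[0]), "time": float(beta[1])}
    if p == 4:
        fe["condition"] = float(beta[2])
    fe["condition:time"] = float(beta[p - 1])
    return GrowthModelResults(
        beta2_hat=float(beta[p - 1]),
        se2_beta2=float(cov[p - 1, p - 1]),
        fixed_effects=fe,
        vc_hat=vc_known,
        converged=True,
        singular=False,
        method="gls",
    )
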