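"""Simulation of trial datasets from the two-level growth model.

Outcomes follow
``Y_ij = beta0 + beta1 T_j + beta2 C_i T_j + u0_i + u1_i T_j + e_ij``
with ``(u0, u1) ~ N(0, Sigma_u)`` and ``e_ij ~ N(0, var_e)``. Under an H0
truth the generating ``beta2`` is 0; under H1 it is ``delta * sqrt(var_u1)``.
Simulation always operates on the transformed (analysis) time scale, so a
log-growth dataset is exactly a linear-growth dataset on log time.

Reproducibility: dataset ``k`` under truth ``h`` at sample size ``N`` draws
from a dedicated child stream derived from ``(master seed, h, N, k)``, so any
single dataset can be regenerated in isolation and execution order is
irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .design import DesignError, TrialDesign

__all__ = ["TrialData", "allocate_conditions", "child_rng", "simulate_dataset"]

_TRUTH_CODE = {"H0": 0, "H1": 1}


def allocate_conditions(n_subjects: int) -> np.ndarray:
    """Deterministic two-arm allocation: controls first, then treated.

    ``floor(N/2)`` subjects receive the treatment (C=1); with odd ``N`` the
    extra subject goes to control.
    """
    if n_subjects < 2:
        raise DesignError("need at least 2 subjects for two arms")
    n_treat = n_subjects // 2
    cond = np.zeros(n_subjects, dtype=np.int64)
    cond[n_subjects - n_treat :] = 1
    return cond


def child_rng(
    master_seed: Optional[int], truth: str, n_subjects: int, k: int, retry: int = 0
) -> np.random.Generator:
    """RNG for dataset ``k`` under ``truth`` at sample size ``n_subjects``."""
    entropy = 0 if master_seed is None else int(master_seed)
    key = (_TRUTH_CODE[truth], int(n_subjects), int(k), int(retry))
    return np.random.default_rng(np.random.SeedSequence(entropy=entropy, spawn_key=key))


@dataclass(frozen=True)
class TrialData:
    """A simulated (or loaded) balanced trial dataset.

    ``outcomes`` is the ``(N, n)`` outcome matrix with subjects in rows,
    ``condition`` the per-subject arm indicator and ``times`` the common
    occasion grid on the analysis scale.
    """

    outcomes: np.ndarray
    condition: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.outcomes, dtype=float)
        c = np.asarray(self.condition)
        t = np.asarray(self.times, dtype=float)
        if y.ndim != 2 or y.shape != (c.size, t.size):
            raise DesignError(
                f"outcomes shape {y.shape} does not match {c.size} subjects "
                f"x {t.size} occasions"
            )
        if not np.all(np.isin(c, (0, 1))):
            raise DesignError("condition must be binary 0/1")
        object.__setattr__(self, "outcomes", y)
        object.__setattr__(self, "condition", c.astype(np.int64))
        object.__setattr__(self, "times", t)

    @property
    def n_subjects(self) -> int:
        return self.outcomes.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.outcomes.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long format with columns ``subject, condition, time, y``."""
        n, m = self.outcomes.shape
        return pd.DataFrame(
            {
                "subject": np.repeat(np.arange(1, n + 1), m),
                "condition": np.repeat(self.condition, m),
                "time": np.tile(self.times, n),
                "y": self.outcomes.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialData":
        """Rebuild from a long-format frame (inverse of :meth:`to_frame`).

        Requires a balanced layout: every subject observed at the same set of
        times and a condition constant within subject.
        """
        required = {"subject", "condition", "time", "y"}
        if not required.issubset(df.columns):
            raise DesignError(f"long format needs columns {sorted(required)}")
        wide = df.pivot_table(index="subject", columns="time", values="y")
        if wide.isna().any().any():
            raise DesignError("unbalanced data: not every subject has every time")
        cond = df.groupby("subject")["condition"].agg(["min", "max"])
        if (cond["min"] != cond["max"]).any():
            raise DesignError("condition varies within a subject")
        cond = cond["min"].reindex(wide.index).to_numpy()
        return cls(wide.to_numpy(float), cond, wide.columns.to_numpy(float))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialData":
        return cls.from_frame(pd.read_csv(path))


def _outcome_matrix(
    design: TrialDesign, truth: str, n_subjects: int, rng: np.random.Generator
) -> np.ndarray:
    t = design.times
    cond = allocate_conditions(n_subjects)
    beta2 = design.beta2 if truth == "H1" else 0.0
    eff = design.effect
    mean = eff.beta0 + eff.beta1 * t[None, :] + beta2 * cond[:, None] * t[None, :]
    # Random effects via Cholesky of Sigma_u; a tiny diagonal jitter-free
    # eigen route covers the rank-deficient boundary (e.g. var_u1 = 0).
    sigma_u = design.vc.sigma_u
    try:
        chol = np.linalg.cholesky(sigma_u)
    except np.linalg.LinAlgError:
        evals, evecs = np.linalg.eigh(sigma_u)
        chol = evecs * np.sqrt(np.clip(evals, 0.0, None))
    u = rng.standard_normal((n_subjects, 2)) @ chol.T
    e = rng.standard_normal((n_subjects, t.size)) * np.sqrt(design.vc.var_e)
    return mean + u[:, [0]] + u[:, [1]] * t[None, :] + e


def simulate_dataset(
    design: TrialDesign,
    truth: str = "H1",
    n_subjects: Optional[int] = None,
    k: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> TrialData:
    """Simulate one balanced trial dataset under the given true hypothesis.

    Parameters
    ----------
    design : TrialDesign
    truth : {"H0", "H1"}
        The data-generating hypothesis: ``beta2 = 0`` under H0, the design's
        effect-size-implied ``beta2`` under H1.
    n_subjects : int, optional
        Sample size to simulate (defaults to nothing smaller than 2 per arm).
    k : int
        Dataset index within a Monte-Carlo batch; selects the child stream.
    rng : numpy.random.Generator, optional
        Explicit generator; overrides the seed/``k`` child-stream discipline.
    """
    if truth not in _TRUTH_CODE:
        raise DesignError(f"truth must be 'H0' or 'H1', got {truth!r}")
    n = int(n_subjects) if n_subjects is not None else 100
    if rng is None:
        rng = child_rng(design.seed, truth, n, k)
    y = _outcome_matrix(design, truth, n, rng)
    return TrialData(y, allocate_conditions(n), design.times)
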