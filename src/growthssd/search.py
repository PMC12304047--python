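"""Binary search for the minimal sample size meeting the Bayesian power target.

Power is assumed nondecreasing in N (true up to Monte-Carlo noise for the
tests considered here). The search halves the interval [n_min, n_max]: the
midpoint is evaluated with fresh Monte-Carlo datasets; if it meets the target
under every requested hypothesis it becomes the new upper bound, otherwise the
new lower bound. The returned N is the smallest evaluated size that met the
target once the interval has shrunk to a single step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

from .design import DesignError, TrialDesign
from .power import FitCache, PowerEstimate, estimate_power

__all__ = ["SearchBounds", "SSDResult", "PowerUnattainableError", "find_sample_size", "sensitivity_analysis"]


class PowerUnattainableError(DesignError):
    """The target power is not reached even at the maximal sample size."""


@dataclass(frozen=True)
class SearchBounds:
    """Sample-size bracket for the search (defaults 30 .. 1000)."""

    n_min: int = 30
    n_max: int = 1000

    def __post_init__(self) -> None:
        if self.n_min < 4 or self.n_max < 4:
            raise DesignError("bounds must allow at least 2 subjects per arm")
        if self.n_min >= self.n_max:
            raise DesignError("n_min must be smaller than n_max")


@dataclass
class SSDResult:
    """Outcome of one sample-size determination.

    ``trace`` records every evaluated N with its power and the halving
    decision; ``per_b`` holds (n_final, eta0, eta1) per prior-fraction
    multiplier when a sensitivity analysis was run.
    """

    n_final: int
    eta0_final: float
    eta1_final: float
    j_fraction: int
    trace: List[Tuple[int, float, float, str]] = field(default_factory=list)
    per_b: Dict[int, Tuple[int, float, float]] = field(default_factory=dict)
    notes: List[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Bayesian sample size determination", "-" * 40]
        if self.per_b and len(self.per_b) > 1:
            for j, (n, e0, e1) in sorted(self.per_b.items()):
                lines.append(
                    f"b = {j}/N_eff: N = {n}   eta0 = {_fmt(e0)}  eta1 = {_fmt(e1)}"
                )
        else:
            lines.append(
                f"N = {self.n_final}   eta0 = {_fmt(self.eta0_final)}  "
                f"eta1 = {_fmt(self.eta1_final)}  (b = {self.j_fraction}/N_eff)"
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


def _fmt(x: float) -> str:
    return "n/a" if x != x else f"{x:.3f}"


def _meets(est: PowerEstimate, design: TrialDesign, j: int) -> bool:
    e0, e1, _ = est.per_b[j]
    ok = True
    if "H0" in design.hypotheses:
        ok &= e0 >= design.eta_target
    if "H1" in design.hypotheses:
        ok &= e1 >= design.eta_target
    return ok


def _search_one(
    design: TrialDesign,
    bounds: SearchBounds,
    j: int,
    power_fn: Callable[[int, int], PowerEstimate],
) -> SSDResult:
    lo, hi = bounds.n_min, bounds.n_max
    trace: List[Tuple[int, float, float, str]] = []
    evaluated: Dict[int, PowerEstimate] = {}

    def evaluate(n: int) -> PowerEstimate:
        if n not in evaluated:
            evaluated[n] = power_fn(n, j)
        return evaluated[n]

    while hi - lo > 1:
        mid = (lo + hi) // 2
        est = evaluate(mid)
        e0, e1, _ = est.per_b[j]
        if _meets(est, design, j):
            trace.append((mid, e0, e1, "meets target -> new upper bound"))
            hi = mid
        else:
            trace.append((mid, e0, e1, "below target -> new lower bound"))
            lo = mid

    notes: List[str] = []
    if hi not in evaluated:
        # every midpoint failed; the upper bound itself was never measured
        est = evaluate(hi)
        e0, e1, _ = est.per_b[j]
        if _meets(est, design, j):
            trace.append((hi, e0, e1, "upper bound meets target"))
        else:
            trace.append((hi, e0, e1, "upper bound below target"))
            raise PowerUnattainableError(
                f"power at n_max={bounds.n_max} is eta0={_fmt(e0)}, eta1={_fmt(e1)}, "
                f"below the target {design.eta_target}; increase n_max, the study "
                "duration/frequency, or relax the threshold"
            )
    n_final = hi
    if n_final == bounds.n_min + 1:
        est_min = evaluate(bounds.n_min)
        if _meets(est_min, design, j):
            e0, e1, _ = est_min.per_b[j]
            trace.append((bounds.n_min, e0, e1, "lower bound already meets target"))
            n_final = bounds.n_min
            notes.append(
                f"the lower search bound n_min={bounds.n_min} already meets the "
                "target; the minimal adequate N may be smaller"
            )
    e0, e1, _ = evaluated[n_final].per_b[j]

    _warn_nonmonotone(trace, notes)
    return SSDResult(
        n_final=n_final,
        eta0_final=e0,
        eta1_final=e1,
        j_fraction=j,
        trace=trace,
        notes=notes,
    )


def _warn_nonmonotone(trace, notes: List[str]) -> None:
    seen = sorted({(n, e0, e1) for n, e0, e1, _ in trace})
    drops = []
    for (n1, a0, a1), (n2, b0, b1) in zip(seen, seen[1:]):
        drop0 = a0 == a0 and b0 == b0 and b0 < a0 - 1e-12
        drop1 = a1 == a1 and b1 == b1 and b1 < a1 - 1e-12
        if n2 > n1 and (drop0 or drop1):
            drops.append((n1, n2))
    if drops:
        pairs = ", ".join(f"{a}->{b}" for a, b in drops[:4])
        more = "" if len(drops) <= 4 else f" (+{len(drops) - 4} more)"
        msg = (
            f"Monte-Carlo power decreased between evaluated sizes {pairs}{more}; "
            "the binary search assumes monotone power and tolerates this noise"
        )
        notes.append(msg)
        warnings.warn(msg, UserWarning, stacklevel=3)


def find_sample_size(
    design: TrialDesign,
    bounds: SearchBounds = SearchBounds(),
    method: str = "reml",
    power_fn: Optional[Callable[[int, int], PowerEstimate]] = None,
    cache: Optional[FitCache] = None,
) -> SSDResult:
    """Minimal N in ``bounds`` whose power meets the design's target.

    ``power_fn(n, j) -> PowerEstimate`` may replace the Monte-Carlo engine
    (e.g. with the deterministic oracle) for testing.
    """
    j = design.j_fraction
    if power_fn is None:
        cache = cache or FitCache(design, method)
        power_fn = lambda n, jj: estimate_power(design, n, j_values=(jj,), method=method, cache=cache)
    return _search_one(design, bounds, j, power_fn)


def sensitivity_analysis(
    design: TrialDesign,
    bounds: SearchBounds = SearchBounds(),
    method: str = "reml",
    power_fn: Optional[Callable[[int, int], PowerEstimate]] = None,
) -> SSDResult:
    """Run the search for each prior fraction b = J/N_eff, J = 1, 2, 3.

    Fitted Monte-Carlo estimates are shared across the three searches whenever
    they evaluate the same sample size (the fit does not depend on b). The
    returned result reports the design's own J as primary and all three in
    ``per_b``.
    """
    cache = None
    if power_fn is None:
        cache = FitCache(design, method)
        power_fn = lambda n, jj: estimate_power(design, n, j_values=(jj,), method=method, cache=cache)
    per_b: Dict[int, Tuple[int, float, float]] = {}
    results: Dict[int, SSDResult] = {}
    for j in (1, 2, 3):
        res = _search_one(design, bounds, j, power_fn)
        results[j] = res
        per_b[j] = (res.n_final, res.eta0_final, res.eta1_final)
    primary = results.get(design.j_fraction, results[1])
    return SSDResult(
        n_final=primary.n_final,
        eta0_final=primary.eta0_final,
        eta1_final=primary.eta1_final,
        j_fraction=primary.j_fraction,
        trace=[t for j in (1, 2, 3) for t in results[j].trace],
        per_b=per_b,
        notes=[n for j in (1, 2, 3) for n in results[j].notes],
    )
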