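"""Exact Galton-Watson theory for a single matrilineal founder.

A lineage starts from one female at generation 0.  Each female
independently bears daughters according to a fixed offspring law with
PGF f(s) = sum_k p_k s^k.  Writing q_n for the probability the lineage
is extinct at or before generation n, the classical recursion is

    q_0 = 0,    q_{n+1} = f(q_n),

which increases monotonically to q*, the smallest fixed point of f on
[0, 1].  When the mean number of daughters per woman m <= 1 (and the law
is not the degenerate exactly-one-daughter law) q* = 1: extinction is
certain.  When m > 1, q* < 1 and survival forever has positive
probability.

The extinction generation T is the smallest n >= 1 with zero females
alive, so a founder with no daughters has T = 1 and
E[T] = sum_{n>=0} (1 - q_n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, ParameterError, QuantileUnreachableError
from .offspring import OffspringDistribution

__all__ = [
    "ExtinctionCurve",
    "pgf_eval",
    "classify_criticality",
    "extinction_probability",
    "extinction_cdf",
    "mean_extinction_time",
    "extinction_quantile",
    "dual_subcritical",
]

_MEAN_TOL = 1e-12


@dataclass(frozen=True)
class ExtinctionCurve:
    """Per-generation cumulative extinction probabilities.

    ``q[n]`` is the probability the lineage founded by one female at
    generation 0 is extinct at or before generation n (``q[0] == 0``);
    ``q_star`` is its limit, the smallest PGF fixed point in [0, 1].
    """

    q: tuple[float, ...]
    q_star: float
    horizon: int
    converged: bool
    source_dist_label: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.q)
        if q[0] != 0.0:
            raise ParameterError("extinction curve must start at q[0] = 0")
        if np.any(np.diff(q) < -1e-15) or np.any(q < 0) or np.any(q > 1):
            raise ParameterError("extinction curve must be non-decreasing in [0, 1]")
        if np.any(q > self.q_star + 1e-12):
            raise ParameterError("extinction curve exceeds its limit q_star")


def pgf_eval(dist: OffspringDistribution, s: float) -> float:
    """Evaluate the probability generating function f(s) = sum p_k s^k."""
    if 1.0 < s <= 1.0 + 1e-9:
        s = 1.0  # absorb one-ulp overshoot from fixed-point iterates
    if not 0.0 <= s <= 1.0:
        raise ParameterError(f"PGF argument must be in [0, 1], got {s}")
    sup, prob = dist.as_arrays()
    # s**0 = 1 even at s = 0, which is exactly the constant term we want.
    return float(prob @ np.power(float(s), sup))


def classify_criticality(dist: OffspringDistribution) -> str:
    """Classify the offspring law by its mean m.

    Returns one of ``subcritical`` (m < 1), ``critical`` (m == 1 with
    P(X=1) < 1), ``supercritical`` (m > 1) or ``degenerate_unit``
    (P(X=1) == 1, the immortal single-file lineage).
    """
    if dist.pmf_dict().get(1, 0.0) == 1.0:
        return "degenerate_unit"
    if dist.mean < 1.0 - _MEAN_TOL:
        return "subcritical"
    if dist.mean > 1.0 + _MEAN_TOL:
        return "supercritical"
    return "critical"


def extinction_probability(
    dist: OffspringDistribution, tol: float = 1e-12, max_iter: int = 1_000_000
) -> float:
    """Smallest root of f(s) = s in [0, 1].

    Subcritical and critical laws return exactly 1.0 (extinction is
    certain) and the degenerate one-daughter law returns 0.0; only the
    supercritical case requires iteration, s <- f(s) from s = 0, which
    converges monotonically to the smallest fixed point.
    """
    if not tol > 0:
        raise ParameterError(f"tol must be positive, got {tol}")
    cls = classify_criticality(dist)
    if cls == "degenerate_unit":
        return 0.0
    if cls in ("subcritical", "critical"):
        return 1.0
    s = 0.0
    for _ in range(max_iter):
        s_next = pgf_eval(dist, s)
        if abs(s_next - s) < tol:
            return s_next
        s = s_next
    raise ConvergenceError(
        f"fixed-point iteration did not converge in {max_iter} steps; "
        f"last iterate {s!r} in bracket [0, 1]"
    )


def extinction_cdf(
    dist: OffspringDistribution, horizon: int = 10_000, tol: float = 1e-12
) -> ExtinctionCurve:
    """Iterate q_{n+1} = f(q_n) from q_0 = 0 up to ``horizon``.

    Near-critical laws may not reach q* within the horizon; that is
    reported through ``converged=False``, never as an exception.
    """
    if horizon < 1:
        raise ParameterError(f"horizon must be >= 1, got {horizon}")
    q_star = extinction_probability(dist, tol=tol)
    q = np.empty(horizon + 1)
    q[0] = 0.0
    for n in range(horizon):
        q[n + 1] = pgf_eval(dist, q[n])
    # Guard against the last float rounding a hair above the limit.
    np.minimum(q, q_star, out=q)
    return ExtinctionCurve(
        q=tuple(float(x) for x in q),
        q_star=q_star,
        horizon=horizon,
        converged=bool(abs(q[horizon] - q_star) < tol),
        source_dist_label=dist.label,
    )


def dual_subcritical(dist: OffspringDistribution) -> OffspringDistribution:
    """Subcritical dual of a supercritical law, PGF f~(s) = f(q* s)/q*.

    Conditioning a supercritical Galton-Watson process on eventual
    extinction yields this dual process; its extinction curve is
    q_n / q* of the original.
    """
    if classify_criticality(dist) != "supercritical":
        raise ParameterError("dual_subcritical requires a supercritical law")
    q_star = extinction_probability(dist)
    sup, prob = dist.as_arrays()
    dual_prob = prob * q_star ** (sup - 1)
    dual_prob = dual_prob / dual_prob.sum()
    return OffspringDistribution(
        support=tuple(int(k) for k in sup),
        probabilities=tuple(float(p) for p in dual_prob),
        label=f"dual[{dist.label}]",
    )


def mean_extinction_time(
    dist: OffspringDistribution,
    tol: float = 1e-14,
    horizon: int = 100_000,
    ratio_tol: float = 1e-9,
    ratio_run: int = 50,
) -> float:
    """Expected extinction generation E[T] = sum_{n>=0} (1 - q_n).

    Subcritical laws: the survival probabilities 1 - q_n decay
    geometrically with asymptotic ratio m, so the sum is truncated once
    either the term falls below ``tol`` or the empirical decay ratio has
    stabilized (within ``ratio_tol`` over ``ratio_run`` consecutive
    steps), at which point a geometric tail r/(1-r) correction is added.

    Critical and degenerate-unit laws: E[T] diverges; returns
    ``math.inf``.  Supercritical laws: returns the mean conditioned on
    extinction, i.e. E[T] of the subcritical dual process with PGF
    f(q* s)/q*.
    """
    cls = classify_criticality(dist)
    if cls in ("critical", "degenerate_unit"):
        return math.inf
    if cls == "supercritical":
        return mean_extinction_time(
            dual_subcritical(dist), tol=tol, horizon=horizon,
            ratio_tol=ratio_tol, ratio_run=ratio_run,
        )
    q = 0.0
    total = 0.0
    prev_term = 1.0
    prev_ratio = None
    stable = 0
    for _ in range(horizon):
        term = 1.0 - q
        total += term
        q = pgf_eval(dist, q)
        new_term = 1.0 - q
        if new_term < tol:
            return total + new_term  # tail beyond this is below float noise
        ratio = new_term / term
        if prev_ratio is not None and abs(ratio - prev_ratio) < ratio_tol:
            stable += 1
            if stable >= ratio_run:
                return total + new_term / (1.0 - ratio)
        else:
            stable = 0
        prev_ratio = ratio
        prev_term = term
    raise ConvergenceError(
        f"survival-decay ratio did not stabilize within horizon={horizon} "
        f"(last term {prev_term:.3e}, last ratio {prev_ratio})"
    )


def extinction_quantile(curve: ExtinctionCurve, p: float) -> int:
    """Smallest generation n with q[n] >= p.

    The generation at which at least a fraction p of lineages have gone
    extinct; p = 0.9 reads off the 90th percentile of T.
    """
    if not 0.0 < p <= 1.0:
        raise ParameterError(f"quantile level must be in (0, 1], got {p}")
    q = np.asarray(curve.q)
    # 1e-12 slack so closed-form ties (e.g. q_4 = 0.8 computed as
    # 0.7999999999999999) land on the mathematically correct generation.
    idx = np.searchsorted(q, p - 1e-12, side="left")
    if idx >= q.size:
        raise QuantileUnreachableError(
            f"requested p={p} exceeds attained maximum q[{curve.horizon}]="
            f"{q[-1]:.12g}"
        )
    return int(idx)
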