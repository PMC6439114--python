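"""Daughter-count offspring distributions.

The Galton-Watson model of lineage extinction is driven entirely by the
offspring law: the probability mass function (PMF) of the number of
daughters a woman has over her completed reproductive life.  This module
constructs such PMFs three ways:

* empirically, from explicit (count, weight) pairs;
* parametrically (Poisson, negative binomial, geometric);
* synthetically, as a census-like completed-fertility distribution over
  children which is then thinned to daughters.

Census and natality tables count *children*; the branching process needs
*daughters*.  Binomial thinning — independently marking each child female
with probability ``p_daughter`` — is the bridge, and is exact for the
moments: the thinned mean is ``p_daughter`` times the children mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import ParameterError, ValidationError

__all__ = [
    "OffspringDistribution",
    "make_empirical_pmf",
    "parametric_pmf",
    "thin_to_daughters",
    "synth_census_like",
    "moments",
]

#: Human secondary sex ratio of about 105 boys per 100 girls.
DEFAULT_P_DAUGHTER = 0.4878

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class OffspringDistribution:
    """A validated PMF over non-negative integer daughter counts.

    Attributes
    ----------
    support
        Strictly ascending distinct non-negative integers.
    probabilities
        Probabilities aligned with ``support``; they sum to 1 within 1e-9.
    mean, variance
        First two moments of the PMF.  The mean is the classical
        criticality parameter m of the branching process.
    label
        Free-text provenance, e.g. ``"poisson(0.95)"`` or the full
        parameter record of a synthetic census-like law.
    """

    support: tuple[int, ...]
    probabilities: tuple[float, ...]
    mean: float = field(default=None)  # type: ignore[assignment]
    variance: float = field(default=None)  # type: ignore[assignment]
    label: str = ""

    def __post_init__(self) -> None:
        sup = np.asarray(self.support)
        prob = np.asarray(self.probabilities, dtype=float)
        if sup.size == 0:
            raise ValidationError("support is empty")
        if sup.size != prob.size:
            raise ValidationError(
                f"support has {sup.size} entries but probabilities has {prob.size}"
            )
        if not np.issubdtype(sup.dtype, np.integer):
            raise ValidationError("support entries must be integers")
        if np.any(sup < 0):
            k = int(sup[sup < 0][0])
            raise ValidationError(f"negative count {k} in support")
        if np.any(np.diff(sup) <= 0):
            i = int(np.argmax(np.diff(sup) <= 0))
            raise ValidationError(
                f"support not strictly ascending at entry {self.support[i + 1]}"
            )
        if np.any(prob < 0):
            k = int(sup[prob < 0][0])
            raise ValidationError(f"negative probability for count {k}")
        total = float(prob.sum())
        if abs(total - 1.0) > _NORM_TOL:
            raise ValidationError(
                f"probabilities sum to {total!r}, not 1 within {_NORM_TOL}"
            )
        m = float(sup @ prob)
        v = float((sup.astype(float) ** 2) @ prob - m * m)
        v = max(v, 0.0)
        if self.mean is None:
            object.__setattr__(self, "mean", m)
        elif abs(self.mean - m) > _NORM_TOL:
            raise ValidationError(f"stored mean {self.mean} != computed {m}")
        if self.variance is None:
            object.__setattr__(self, "variance", v)
        elif abs(self.variance - v) > _NORM_TOL:
            raise ValidationError(f"stored variance {self.variance} != computed {v}")

    # -- convenience views -------------------------------------------------
    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.asarray(self.support, dtype=np.int64),
            np.asarray(self.probabilities, dtype=float),
        )

    def pmf_dict(self) -> dict[int, float]:
        return dict(zip(self.support, self.probabilities))

    def prob_zero(self) -> float:
        """P(X = 0): the per-generation chance a woman has no daughter."""
        return self.probabilities[0] if self.support[0] == 0 else 0.0


def make_empirical_pmf(
    support: list[int] | np.ndarray,
    weights: list[float] | np.ndarray,
    label: str = "empirical",
) -> OffspringDistribution:
    """Build a distribution from raw (count, weight) pairs.

    Weights are normalized to probabilities; pairs are sorted by count.
    Raises :class:`ValidationError` naming the offending entry for empty
    support, negative or non-integer counts, duplicate counts, negative
    weights, or all-zero weights.
    """
    sup = np.asarray(support)
    w = np.asarray(weights, dtype=float)
    if sup.size == 0:
        raise ValidationError("support is empty")
    if not np.issubdtype(sup.dtype, np.integer):
        bad = [x for x in np.atleast_1d(sup).tolist() if not float(x).is_integer()]
        raise ValidationError(f"non-integer count {bad[0] if bad else sup.dtype}")
    if sup.size != w.size:
        raise ValidationError(
            f"{sup.size} counts but {w.size} weights"
        )
    if np.any(sup < 0):
        raise ValidationError(f"negative count {int(sup[sup < 0][0])}")
    uniq, counts = np.unique(sup, return_counts=True)
    if np.any(counts > 1):
        raise ValidationError(f"duplicate count {int(uniq[counts > 1][0])}")
    if np.any(w < 0):
        raise ValidationError(
            f"negative weight {float(w[w < 0][0])} for count {int(sup[w < 0][0])}"
        )
    total = w.sum()
    if total <= 0:
        raise ValidationError("all weights are zero")
    order = np.argsort(sup)
    sup, w = sup[order], w[order]
    prob = w / total
    return OffspringDistribution(
        support=tuple(int(k) for k in sup),
        probabilities=tuple(float(p) for p in prob),
        label=label,
    )


def parametric_pmf(
    family: str,
    mean: float,
    dispersion: float | None = None,
    tail_mass_tol: float = 1e-9,
) -> OffspringDistribution:
    """Truncated-and-renormalized parametric daughter law.

    Supported families:

    ``poisson``
        P(k) = e^{-m} m^k / k!.
    ``negative_binomial``
        NB parameterized by mean m and ``dispersion`` r (number of
        failures / size parameter); variance m + m^2/r.
    ``geometric``
        P(k) = (1 - b) b^k on k = 0, 1, ...; b = m / (1 + m).

    The infinite support is truncated at the smallest K whose retained
    tail mass is below ``tail_mass_tol`` and renormalized; the realized
    mean then differs from the requested one by far less than 1e-6.
    """
    if not mean > 0:
        raise ParameterError(f"mean must be positive, got {mean}")
    if not 0 < tail_mass_tol <= 1e-6:
        raise ParameterError(
            f"tail_mass_tol must be in (0, 1e-6], got {tail_mass_tol}"
        )
    if family == "poisson":
        dist = stats.poisson(mean)
    elif family == "negative_binomial":
        if dispersion is None:
            raise ParameterError("negative_binomial requires a dispersion parameter")
        if not dispersion > 0:
            raise ParameterError(f"dispersion must be positive, got {dispersion}")
        # scipy's nbinom(n, p) has mean n(1-p)/p; match mean m, size r.
        r = dispersion
        p = r / (r + mean)
        dist = stats.nbinom(r, p)
    elif family == "geometric":
        dist = None
    else:
        raise ParameterError(f"unknown family {family!r}")

    if family == "geometric":
        # P(k) = (1-b) b^k evaluated directly; scipy's geom loses ~1e-10
        # to exp/log round trips, which matters at our tolerances.
        b = mean / (1.0 + mean)
        k_max = int(np.ceil(np.log(tail_mass_tol) / np.log(b)))
        support = np.arange(k_max + 1)
        prob = (1.0 - b) * b ** support.astype(float)
    else:
        k_max = int(dist.ppf(1.0 - tail_mass_tol)) + 1
        while dist.sf(k_max) >= tail_mass_tol:  # ppf can undershoot in the far tail
            k_max += 1
        support = np.arange(k_max + 1)
        prob = dist.pmf(support)
    prob = prob / prob.sum()
    return OffspringDistribution(
        support=tuple(int(k) for k in support),
        probabilities=tuple(float(p) for p in prob),
        label=f"{family}(mean={mean:g}"
        + (f", dispersion={dispersion:g}" if family == "negative_binomial" else "")
        + ")",
    )


def thin_to_daughters(
    children: OffspringDistribution, p_daughter: float = DEFAULT_P_DAUGHTER
) -> OffspringDistribution:
    """Binomial thinning of a children-count PMF to a daughter-count PMF.

    P(D = d) = sum_{c >= d} P(C = c) C(c, d) p^d (1-p)^{c-d}.  The mean is
    exactly scaled: E[D] = p_daughter * E[C].
    """
    if not 0.0 <= p_daughter <= 1.0:
        raise ParameterError(f"p_daughter must be in [0, 1], got {p_daughter}")
    sup, prob = children.as_arrays()
    d_max = int(sup.max())
    d = np.arange(d_max + 1)
    # thin_matrix[i, j] = P(Binomial(support[i], p) = j)
    thin_matrix = stats.binom.pmf(d[None, :], sup[:, None], p_daughter)
    daughter_prob = prob @ thin_matrix
    daughter_prob = daughter_prob / daughter_prob.sum()
    # drop structurally impossible counts (exact zeros, e.g. at p = 0 or 1)
    keep = (daughter_prob > 0.0) | (d == 0)
    d, daughter_prob = d[keep], daughter_prob[keep]
    return OffspringDistribution(
        support=tuple(int(k) for k in d),
        probabilities=tuple(float(p) for p in daughter_prob),
        label=f"thin(p={p_daughter:g})[{children.label}]",
    )


def synth_census_like(
    mean_daughters: float = 0.95,
    max_children: int = 12,
    shape: float = 3.0,
    zero_inflation: float = 0.10,
    p_daughter: float = DEFAULT_P_DAUGHTER,
    seed: int = 0,
    jitter_sd: float = 0.05,
) -> OffspringDistribution:
    """Synthetic census-like completed-fertility law, thinned to daughters.

    Emulates the qualitative shape of US completed-fertility tables:
    heavy mass at 0-3 children, over-dispersed relative to Poisson, with
    excess childlessness.  The children PMF is a zero-inflated negative
    binomial on {0..max_children} (size ``shape``, extra zero mass
    ``zero_inflation``), multiplied by a small seeded lognormal jitter so
    different seeds give distinct but similar irregular tables, then
    exponentially tilted (weights scaled by t^k, t solved by bisection)
    so the *thinned* mean equals ``mean_daughters`` within 1e-6.

    The default target mean of 0.95 daughters per woman corresponds to a
    subcritical lineage: extinction is certain and typically fast.
    """
    if not mean_daughters > 0:
        raise ParameterError(f"mean_daughters must be positive, got {mean_daughters}")
    if not 0 < p_daughter <= 1:
        raise ParameterError(f"p_daughter must be in (0, 1], got {p_daughter}")
    if not 0 <= zero_inflation < 1:
        raise ParameterError(f"zero_inflation must be in [0, 1), got {zero_inflation}")
    if not shape > 0:
        raise ParameterError(f"shape must be positive, got {shape}")
    target_children_mean = mean_daughters / p_daughter
    if target_children_mean > max_children:
        raise ParameterError(
            f"mean_daughters={mean_daughters} with p_daughter={p_daughter} needs a "
            f"children mean of {target_children_mean:.4g} > max_children={max_children}"
        )

    k = np.arange(max_children + 1)
    r = shape
    p_nb = r / (r + target_children_mean)
    base = stats.nbinom.pmf(k, r, p_nb)
    base[0] = zero_inflation + (1.0 - zero_inflation) * base[0]
    base[1:] *= 1.0 - zero_inflation

    rng = np.random.default_rng(seed)
    base = base * np.exp(rng.normal(0.0, jitter_sd, size=base.size))

    def thinned_mean(log_t: float) -> float:
        w = base * np.exp(log_t * k)
        return p_daughter * float(k @ w) / float(w.sum())

    lo, hi = -40.0, 40.0 / max(max_children, 1)
    if not thinned_mean(lo) <= mean_daughters <= thinned_mean(hi):
        raise ParameterError(
            f"mean_daughters={mean_daughters} infeasible on support 0..{max_children}"
        )
    log_t = optimize.brentq(
        lambda x: thinned_mean(x) - mean_daughters, lo, hi, xtol=1e-13
    )
    w = base * np.exp(log_t * k)
    children = make_empirical_pmf(
        k,
        w,
        label=(
            f"synthetic-census(mean_daughters={mean_daughters:g}, "
            f"max_children={max_children}, shape={shape:g}, "
            f"zero_inflation={zero_inflation:g}, p_daughter={p_daughter:g}, "
            f"seed={seed}, jitter_sd={jitter_sd:g})"
        ),
    )
    daughters = thin_to_daughters(children, p_daughter)
    return OffspringDistribution(
        support=daughters.support,
        probabilities=daughters.probabilities,
        label=children.label,
    )


def moments(dist: OffspringDistribution) -> tuple[float, float]:
    """(mean, variance) of a daughter-count law; mean is criticality m."""
    return dist.mean, dist.variance
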