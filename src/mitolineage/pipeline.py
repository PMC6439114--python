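"""End-to-end analysis pipeline and run configuration.

One call runs the whole chain the package exists for: offspring law ->
exact extinction curve (PGF iteration) -> Monte-Carlo lineage cohort ->
cross-validation of the two paths -> a single self-describing JSON
report.  Everything needed to regenerate any number in the report (seed,
replicate count, distribution provenance) is echoed back into it.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .branching import (
    classify_criticality,
    extinction_cdf,
    extinction_probability,
    extinction_quantile,
    mean_extinction_time,
)
from .errors import ParameterError, QuantileUnreachableError
from .io import read_pmf_tsv, write_json_atomic, write_pmf_tsv
from .offspring import DEFAULT_P_DAUGHTER, OffspringDistribution, synth_census_like
from .simulation import compare_to_analytic, histogram, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "build_report"]

QUANTILE_LEVELS = (0.5, 0.9, 0.95)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    pmf_path: str | None = None  # mutually exclusive with synth
    p_daughter: float | None = None  # for children-count tables / synth
    synth: bool = False
    mean_daughters: float = 0.95
    max_children: int = 12
    shape: float = 3.0
    zero_inflation: float = 0.10
    n_reps: int = 100_000
    seed: int = 1
    max_gen: int = 10_000
    horizon: int = 10_000
    tol: float = 1e-12
    hist_max_bin: int = 30
    out_report: str | None = None
    out_hist: str | None = None

    def __post_init__(self) -> None:
        if self.synth == (self.pmf_path is not None):
            raise ParameterError(
                "exactly one of pmf_path or synth must be specified"
            )
        if self.n_reps < 1 or self.max_gen < 1 or self.horizon < 1:
            raise ParameterError("n_reps, max_gen and horizon must all be >= 1")
        if not self.tol > 0:
            raise ParameterError(f"tol must be positive, got {self.tol}")

    def resolve_distribution(self) -> OffspringDistribution:
        if self.synth:
            return synth_census_like(
                mean_daughters=self.mean_daughters,
                max_children=self.max_children,
                shape=self.shape,
                zero_inflation=self.zero_inflation,
                p_daughter=(
                    self.p_daughter if self.p_daughter is not None else DEFAULT_P_DAUGHTER
                ),
                seed=self.seed,
            )
        return read_pmf_tsv(self.pmf_path, p_daughter=self.p_daughter)


def analyze_distribution(
    dist: OffspringDistribution, horizon: int = 10_000, tol: float = 1e-12
) -> dict:
    """Exact branching-process summary of one daughter law."""
    curve = extinction_cdf(dist, horizon=horizon, tol=tol)
    mean_t = mean_extinction_time(dist, horizon=max(horizon, 100_000))
    quantiles = {}
    for p in QUANTILE_LEVELS:
        try:
            quantiles[f"p{int(p * 100)}"] = extinction_quantile(curve, p)
        except QuantileUnreachableError:
            quantiles[f"p{int(p * 100)}"] = None
    return {
        "mean": dist.mean,
        "variance": dist.variance,
        "criticality": classify_criticality(dist),
        "q_star": curve.q_star,
        "mean_extinction_generations": None if math.isinf(mean_t) else mean_t,
        "mean_diverges": math.isinf(mean_t),
        "quantiles": quantiles,
        "q_curve_head": list(curve.q[:21]),
        "converged": curve.converged,
    }


def build_report(config: RunConfig) -> dict:
    """Run analytics + simulation on one distribution and assemble the report."""
    dist = config.resolve_distribution()
    curve = extinction_cdf(dist, horizon=config.horizon, tol=config.tol)
    analytic = analyze_distribution(dist, horizon=config.horizon, tol=config.tol)
    result = simulate_cohort(
        dist, n_reps=config.n_reps, seed=config.seed, max_gen=config.max_gen
    )
    hist_rows = histogram(result, max_bin=config.hist_max_bin)
    return {
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": asdict(config),
        "distribution": {
            "label": dist.label,
            "support": list(dist.support),
            "probabilities": list(dist.probabilities),
        },
        "analytic": analytic,
        "simulated": result.summaries(),
        "max_cdf_discrepancy": compare_to_analytic(result, curve),
        "histogram": hist_rows,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Build the report, then (and only then) write any requested outputs.

    Output files are written only after every stage has succeeded, so a
    failing run never leaves a partial report behind.
    """
    report = build_report(config)
    if config.out_hist is not None:
        import pandas as pd

        Path(config.out_hist).parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(report["histogram"]).to_csv(
            config.out_hist, sep="\t", index=False,
            columns=["generation", "count", "frequency"],
        )
        report["histogram_path"] = str(config.out_hist)
    if config.out_report is not None:
        write_json_atomic(report, config.out_report)
    return report
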