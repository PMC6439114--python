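"""Population burden of pathogenic-mtDNA carriers.

A chain of simple proportions: of a total population, the fraction in
fair-to-poor health is removed to get the healthy population; more than
1 in 200 healthy people carry a pathogenic mtDNA mutation; half of the
carriers are female; roughly a third of female carriers are of
reproductive age and could transmit the mutation.  Exact values are
always retained; a significant-figure rounding rule is applied only for
reporting, so the printed figures match the headline numbers customary
in this literature (e.g. "1.4 million carriers, 700,000 female").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError

__all__ = ["CarrierBurden", "estimate_burden", "round_sig"]


def round_sig(x: float, sig: int) -> float:
    """Round x to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class CarrierBurden:
    """Inputs and derived strata of the carrier-population estimate."""

    total_population: float
    fair_poor_fraction: float
    carrier_rate: float
    female_fraction: float
    reproductive_fraction: float
    # derived, exact
    healthy_population: float
    carrier_count: float
    female_carriers: float
    reproductive_age_female_carriers: float
    rounding_rule: str = "healthy: nearest 1e6; carriers: 2 sig figs; female: 1 sig fig"

    def reported(self) -> dict:
        """Rounded figures for human-readable reporting.

        Healthy population to the nearest million; carriers to 2
        significant figures; female and reproductive-age carriers to 1.
        """
        return {
            "healthy_population": round(self.healthy_population / 1e6) * 1e6,
            "carrier_count": round_sig(self.carrier_count, 2),
            "female_carriers": round_sig(self.female_carriers, 1),
            "reproductive_age_female_carriers": round_sig(
                self.reproductive_age_female_carriers, 1
            ),
        }

    def to_dict(self) -> dict:
        return {
            "inputs": {
                "total_population": self.total_population,
                "fair_poor_fraction": self.fair_poor_fraction,
                "carrier_rate": self.carrier_rate,
                "female_fraction": self.female_fraction,
                "reproductive_fraction": self.reproductive_fraction,
            },
            "exact": {
                "healthy_population": self.healthy_population,
                "carrier_count": self.carrier_count,
                "female_carriers": self.female_carriers,
                "reproductive_age_female_carriers": self.reproductive_age_female_carriers,
            },
            "reported": self.reported(),
            "rounding_rule": self.rounding_rule,
        }


def estimate_burden(
    total_population: float = 314e6,
    fair_poor_fraction: float = 0.103,
    carrier_rate: float = 1 / 200,
    female_fraction: float = 0.5,
    reproductive_fraction: float = 1 / 3,
) -> CarrierBurden:
    """Multiply the proportion chain down to reproductive-age female carriers.

    Defaults reproduce the 2012 US figures: a 314 million population with
    10.3% in fair-to-poor health leaves 282 million healthy people; a
    1-in-200 carrier rate gives 1.4 million carriers, 700,000 of them
    female, about a third of those of reproductive age.
    """
    if not total_population > 0:
        raise ParameterError(f"total_population must be positive, got {total_population}")
    for name, value in (
        ("fair_poor_fraction", fair_poor_fraction),
        ("carrier_rate", carrier_rate),
        ("female_fraction", female_fraction),
        ("reproductive_fraction", reproductive_fraction),
    ):
        if not 0.0 <= value <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {value}")
    healthy = total_population * (1.0 - fair_poor_fraction)
    carriers = healthy * carrier_rate
    female = carriers * female_fraction
    reproductive = female * reproductive_fraction
    return CarrierBurden(
        total_population=total_population,
        fair_poor_fraction=fair_poor_fraction,
        carrier_rate=carrier_rate,
        female_fraction=female_fraction,
        reproductive_fraction=reproductive_fraction,
        healthy_population=healthy,
        carrier_count=carriers,
        female_carriers=female,
        reproductive_age_female_carriers=reproductive,
    )
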