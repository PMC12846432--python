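"""Entomological summary endpoints for hut-trial arms.

Standard experimental-hut endpoints, with the conventional symbols
(u = untreated control arm, t = treated arm):

* exophily / blood-feeding / mortality proportions with 95% CI,
* blood-feeding inhibition  100 * (1 - (Bt/Tt) / (Bu/Tu)),
* personal protection       100 * (Bu - Bt) / Bu,
* insecticidal (overall killing) effect  100 * (Kt - Ku) / Tu,
* deterrence                100 * (Tu - Tt) / Tu,

where T = total caught, B = total blood-fed, K = total dead.  Ratios
can legitimately be negative (a treated arm may attract more mosquitoes
or feed more than the control) and are reported as-is, never floored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .trial_data import ArmTotals

__all__ = [
    "UndefinedEndpointError",
    "EndpointEstimate",
    "proportion_endpoint",
    "blood_feeding_inhibition",
    "personal_protection",
    "insecticidal_effect",
    "deterrence",
    "mean_per_night",
]


class UndefinedEndpointError(ZeroDivisionError):
    """The endpoint's denominator is zero, so the estimate is undefined."""


@dataclass(frozen=True)
class EndpointEstimate:
    """A percentage endpoint with its 95% confidence interval."""

    value: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.value <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")

    def __str__(self) -> str:
        return f"{self.value:.1f} ({self.ci_low:.1f}-{self.ci_high:.1f})"


def proportion_endpoint(
    numerator: int, denominator: int, method: str = "wald", level: float = 0.95
) -> EndpointEstimate:
    """Percentage ``100 * numerator / denominator`` with a CI.

    ``method='wald'`` (default) is the normal-approximation interval on
    the proportion scale, truncated to [0, 100]; ``method='wilson'`` is
    the score interval, which behaves better near the boundaries.
    """
    if denominator <= 0:
        raise UndefinedEndpointError("proportion endpoint with zero denominator")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    p = numerator / denominator
    z = stats.norm.ppf(0.5 + level / 2)
    if method == "wald":
        half = z * math.sqrt(p * (1 - p) / denominator)
        low, high = p - half, p + half
    elif method == "wilson":
        denom = 1 + z**2 / denominator
        centre = (p + z**2 / (2 * denominator)) / denom
        half = (
            z
            * math.sqrt(p * (1 - p) / denominator + z**2 / (4 * denominator**2))
            / denom
        )
        low, high = centre - half, centre + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return EndpointEstimate(
        value=100 * p,
        ci_low=max(0.0, 100 * low),
        ci_high=min(100.0, 100 * high),
        n=denominator,
    )


def blood_feeding_inhibition(treated: ArmTotals, untreated: ArmTotals) -> float:
    """Reduction in the blood-feeding *rate* relative to the control, %.

    100 * (1 - (Bt/Tt) / (Bu/Tu)).  Negative when the treated arm feeds
    at a higher rate than the control.
    """
    if treated.caught == 0 or untreated.caught == 0:
        raise UndefinedEndpointError("blood-feeding inhibition needs caught > 0 in both arms")
    if untreated.fed == 0:
        raise UndefinedEndpointError("blood-feeding inhibition undefined: no control feeding")
    rate_t = treated.fed / treated.caught
    rate_u = untreated.fed / untreated.caught
    return 100.0 * (1.0 - rate_t / rate_u)


def personal_protection(treated: ArmTotals, untreated: ArmTotals) -> float:
    """100 * (Bu - Bt) / Bu: reduction in the absolute number fed."""
    if untreated.fed == 0:
        raise UndefinedEndpointError("personal protection undefined: no control feeding")
    return 100.0 * (untreated.fed - treated.fed) / untreated.fed


def insecticidal_effect(treated: ArmTotals, untreated: ArmTotals) -> float:
    """Overall killing effect 100 * (Kt - Ku) / Tu.

    Excess kills in the treated arm normalised by control *entries* --
    the denominator is deliberately the untreated total caught, so the
    index rewards arms that kill many mosquitoes in absolute terms.
    """
    if untreated.caught == 0:
        raise UndefinedEndpointError("insecticidal effect undefined: empty control arm")
    return 100.0 * (treated.dead - untreated.dead) / untreated.caught


def deterrence(treated: ArmTotals, untreated: ArmTotals) -> float:
    """100 * (Tu - Tt) / Tu: reduction in hut entry relative to control.

    Negative when the treated arm caught more than the control (as
    observed for coated pyrethroid-only nets in some trials).
    """
    if untreated.caught == 0:
        raise UndefinedEndpointError("deterrence undefined: empty control arm")
    return 100.0 * (untreated.caught - treated.caught) / untreated.caught


def mean_per_night(
    total: int | None = None,
    nights: int | None = None,
    kind: str = "arithmetic",
    nightly_counts: Sequence[int] | None = None,
) -> float:
    """Mean catch per night.

    ``kind='arithmetic'`` is ``total / nights``.  The Williams-style
    ``kind='geometric'`` mean ``exp(mean(log(c + 1))) - 1`` needs the
    nightly counts themselves, not just the total, and must be given
    ``nightly_counts``.
    """
    if kind == "arithmetic":
        if total is None or nights is None:
            raise ValueError("arithmetic mean needs total and nights")
        if nights <= 0:
            raise UndefinedEndpointError("mean per night undefined with zero nights")
        return total / nights
    if kind == "geometric":
        if nightly_counts is None:
            raise ValueError("geometric mean requires the nightly counts, not totals")
        counts = np.asarray(nightly_counts, dtype=float)
        if counts.size == 0:
            raise UndefinedEndpointError("geometric mean of an empty night series")
        if (counts < 0).any():
            raise ValueError("nightly counts must be non-negative")
        return float(np.expm1(np.mean(np.log1p(counts))))
    raise ValueError(f"unknown mean kind {kind!r}")
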