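"""WHO tube-test susceptibility scoring and cone-bioassay efficacy.

Tube tests expose batches of mosquitoes to insecticide-impregnated
papers at a diagnostic concentration for 1 h, score knockdown over the
first hour and mortality at 24 h, and classify the population:

    >= 98% mortality  susceptible
    90-97%            possible resistance
    <  90%            resistant

Control mortality in [5%, 20%) triggers Abbott's correction; a control
at or above 20% invalidates the test.

Cone bioassays expose batches of five mosquitoes to a net piece for
3 min and score knockdown at 60 min and mortality at 24 h; a net piece
meets the WHO bio-efficacy criterion when mortality >= 80% OR
knockdown >= 95% (inclusive bounds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "InvalidAssayError",
    "SusceptibilityTest",
    "ConeAssay",
    "ConeResult",
    "abbott_correct",
    "classify_susceptibility",
    "cone_efficacy",
    "score_susceptibility_test",
    "read_tube_csv",
    "read_cone_csv",
]

KNOCKDOWN_TIMES = (10, 15, 20, 30, 40, 50, 60)

MORTALITY_CUTOFF = 80.0
KNOCKDOWN_CUTOFF = 95.0


class InvalidAssayError(ValueError):
    """The assay fails a WHO validity rule (e.g. control mortality >= 20%)."""


@dataclass(frozen=True)
class SusceptibilityTest:
    """One WHO tube test: replicates of (exposed, dead) plus control."""

    insecticide: str
    concentration: str
    replicates: tuple[tuple[int, int], ...]  # (exposed, dead) per tube
    control_exposed: int
    control_dead: int
    knockdown: dict = field(default_factory=dict)  # minute -> cumulative knocked down

    def __post_init__(self) -> None:
        for exposed, dead in self.replicates:
            if not 0 <= dead <= exposed:
                raise ValueError("dead must lie in [0, exposed] for every replicate")
        if not 0 <= self.control_dead <= self.control_exposed:
            raise ValueError("control dead must lie in [0, control exposed]")
        times = sorted(self.knockdown)
        series = [self.knockdown[t] for t in times]
        if any(b < a for a, b in zip(series, series[1:])):
            raise ValueError("knockdown series must be non-decreasing in time")

    @property
    def mortality_pct(self) -> float:
        exposed = sum(e for e, _ in self.replicates)
        dead = sum(d for _, d in self.replicates)
        if exposed == 0:
            raise InvalidAssayError("no exposed mosquitoes")
        return 100.0 * dead / exposed

    @property
    def control_mortality_pct(self) -> float:
        if self.control_exposed == 0:
            return 0.0
        return 100.0 * self.control_dead / self.control_exposed


@dataclass(frozen=True)
class ConeAssay:
    """Cone bioassay on one net piece: replicates of (exposed, kd60, dead24)."""

    product: str
    washes: int
    phase: str  # 'before' or 'after' the hut trial
    strain: str
    replicates: tuple[tuple[int, int, int], ...]
    exposure_minutes: int = 3

    def __post_init__(self) -> None:
        for exposed, kd, dead in self.replicates:
            if not (0 <= kd <= exposed and 0 <= dead <= exposed):
                raise ValueError("knockdown and dead must lie in [0, exposed]")


@dataclass(frozen=True)
class ConeResult:
    kd60_pct: float
    mortality24_pct: float
    meets_cutoff: bool
    kd60_ci: tuple[float, float]
    mortality24_ci: tuple[float, float]
    n_exposed: int
    n_replicates: int


def abbott_correct(treated_pct: float, control_pct: float) -> float:
    """Abbott's control-mortality correction.

    Returned unchanged when control mortality is below 5%; corrected as
    100*(t - c)/(100 - c) for control in [5%, 20%); invalid at >= 20%.
    """
    if control_pct >= 20.0:
        raise InvalidAssayError(
            f"control mortality {control_pct:.1f}% >= 20%: test invalid, repeat the assay"
        )
    if control_pct < 5.0:
        return treated_pct
    return 100.0 * (treated_pct - control_pct) / (100.0 - control_pct)


def classify_susceptibility(mortality_pct: float) -> str:
    """WHO susceptibility class from 24 h tube-test mortality."""
    if not 0.0 <= mortality_pct <= 100.0:
        raise ValueError("mortality must lie in [0, 100]")
    if mortality_pct >= 98.0:
        return "susceptible"
    if mortality_pct >= 90.0:
        return "possible resistance"
    return "resistant"


def score_susceptibility_test(test: SusceptibilityTest) -> dict:
    """Raw and Abbott-corrected mortality with the WHO class for each.

    Both values are reported because published summaries sometimes show
    raw mortality even when the control sits in the correction band.
    """
    raw = test.mortality_pct
    corrected = abbott_correct(raw, test.control_mortality_pct)
    return {
        "insecticide": test.insecticide,
        "concentration": test.concentration,
        "mortality_raw_pct": raw,
        "mortality_corrected_pct": corrected,
        "control_mortality_pct": test.control_mortality_pct,
        "class_raw": classify_susceptibility(min(max(raw, 0.0), 100.0)),
        "class_corrected": classify_susceptibility(min(max(corrected, 0.0), 100.0)),
    }


def _replicate_ci(fractions: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    # Wald interval across replicate-level variation; bounds may exceed
    # [0, 100] for small replicate counts and are reported untruncated.
    k = len(fractions)
    mean = sum(fractions) / k
    if k < 2:
        return (100.0 * mean, 100.0 * mean)
    var = sum((f - mean) ** 2 for f in fractions) / (k - 1)
    half = stats.norm.ppf(0.5 + level / 2) * math.sqrt(var / k)
    return (100.0 * (mean - half), 100.0 * (mean + half))


def cone_efficacy(assay: ConeAssay) -> ConeResult:
    """Pooled knockdown/mortality percentages and the WHO cut-off verdict."""
    if not assay.replicates:
        raise InvalidAssayError("cone assay needs at least one replicate")
    exposed = sum(e for e, _, _ in assay.replicates)
    if exposed == 0:
        raise InvalidAssayError("no exposed mosquitoes in cone assay")
    kd = sum(k for _, k, _ in assay.replicates)
    dead = sum(d for _, _, d in assay.replicates)
    kd_pct = 100.0 * kd / exposed
    mort_pct = 100.0 * dead / exposed
    kd_fracs = [k / e for e, k, _ in assay.replicates if e > 0]
    mort_fracs = [d / e for e, _, d in assay.replicates if e > 0]
    return ConeResult(
        kd60_pct=kd_pct,
        mortality24_pct=mort_pct,
        meets_cutoff=(mort_pct >= MORTALITY_CUTOFF) or (kd_pct >= KNOCKDOWN_CUTOFF),
        kd60_ci=_replicate_ci(kd_fracs),
        mortality24_ci=_replicate_ci(mort_fracs),
        n_exposed=exposed,
        n_replicates=len(assay.replicates),
    )


# ---------------------------------------------------------------------------
# CSV schemas: one row per replicate


def read_tube_csv(path: str | Path) -> list[SusceptibilityTest]:
    """Tube-test CSV: insecticide,concentration,exposed,dead,
    control_exposed,control_dead (control columns repeated per row)."""
    frame = pd.read_csv(path, comment="#")
    tests = []
    for (ins, conc), grp in frame.groupby(["insecticide", "concentration"], sort=False):
        tests.append(
            SusceptibilityTest(
                insecticide=str(ins),
                concentration=str(conc),
                replicates=tuple(
                    (int(r.exposed), int(r.dead)) for r in grp.itertuples()
                ),
                control_exposed=int(grp["control_exposed"].iloc[0]),
                control_dead=int(grp["control_dead"].iloc[0]),
            )
        )
    return tests


def read_cone_csv(path: str | Path) -> list[ConeAssay]:
    """Cone CSV: product,washes,phase,strain,exposed,kd60,dead24."""
    frame = pd.read_csv(path, comment="#")
    assays = []
    keys = ["product", "washes", "phase", "strain"]
    for (product, washes, phase, strain), grp in frame.groupby(keys, sort=False):
        assays.append(
            ConeAssay(
                product=str(product),
                washes=int(washes),
                phase=str(phase),
                strain=str(strain),
                replicates=tuple(
                    (int(r.exposed), int(r.kd60), int(r.dead24)) for r in grp.itertuples()
                ),
            )
        )
    return assays
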