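"""Published summary data from a seven-arm Tanzanian experimental hut
evaluation of an alpha-cypermethrin + PBO net (YAHE 4.0) against
pyrethroid-resistant *Anopheles arabiensis*.

These are the trial's printed per-arm totals, adjusted odds ratios and
chemical contents, bundled so that worked examples, the simulator's
default conditions and desk-scale reproductions run without the
(unreleased) nightly raw data.  Nightly records are *not* available;
anything that needs them (refitting the adjusted odds ratios) can only
be checked on simulated data.
"""

from __future__ import annotations

from .chemistry import ChemMeasure
from .trial_data import ArmTotals

__all__ = [
    "ARMS",
    "UNTREATED",
    "NIGHTS_PER_ARM",
    "ARM_TOTALS",
    "DELTA",
    "CHEM_MEASURES",
    "DECLARED_CONTENT",
    "PUBLISHED_COMPARISONS",
    "PUBLISHED_POOLED_COMPARISONS",
]

#: Canonical arm codes, untreated control first.
ARMS = (
    "untreated",
    "yahe_unwashed",
    "yahe_washed",
    "interceptor_unwashed",
    "interceptor_washed",
    "duranet_unwashed",
    "duranet_washed",
)
UNTREATED = "untreated"

#: Nights each arm was run (the per-night means equal caught / 112).
NIGHTS_PER_ARM = 112

#: Per-arm totals: caught, exited (veranda + window), blood-fed, dead.
ARM_TOTALS: dict[str, ArmTotals] = {
    "untreated": ArmTotals("untreated", caught=374, exited=312, fed=171, dead=17, nights=112),
    "yahe_unwashed": ArmTotals("yahe_unwashed", caught=343, exited=284, fed=110, dead=159, nights=112),
    "yahe_washed": ArmTotals("yahe_washed", caught=326, exited=268, fed=107, dead=162, nights=112),
    "interceptor_unwashed": ArmTotals("interceptor_unwashed", caught=492, exited=424, fed=188, dead=238, nights=112),
    "interceptor_washed": ArmTotals("interceptor_washed", caught=709, exited=594, fed=216, dead=313, nights=112),
    "duranet_unwashed": ArmTotals("duranet_unwashed", caught=287, exited=248, fed=101, dead=155, nights=112),
    "duranet_washed": ArmTotals("duranet_washed", caught=370, exited=304, fed=167, dead=206, nights=112),
}

#: WHO absolute non-inferiority margin (7 percentage points).
DELTA = 0.07

#: GC-FID active-ingredient contents, g/kg, by wash count and trial phase.
CHEM_MEASURES: tuple[ChemMeasure, ...] = (
    ChemMeasure("yahe", "alpha-cypermethrin", 8.70, 0, "before", 37.8),
    ChemMeasure("yahe", "alpha-cypermethrin", 8.25, 20, "before", 37.8),
    ChemMeasure("yahe", "alpha-cypermethrin", 8.33, 0, "after", 37.8),
    ChemMeasure("yahe", "alpha-cypermethrin", 7.75, 20, "after", 37.8),
    ChemMeasure("yahe", "PBO", 3.46, 0, "before", 37.8),
    ChemMeasure("yahe", "PBO", 3.08, 20, "before", 37.8),
    ChemMeasure("yahe", "PBO", 3.11, 0, "after", 37.8),
    ChemMeasure("yahe", "PBO", 2.73, 20, "after", 37.8),
    ChemMeasure("duranet", "alpha-cypermethrin", 6.11, 0, "before", 36.0),
    ChemMeasure("duranet", "alpha-cypermethrin", 5.53, 20, "before", 36.0),
    ChemMeasure("duranet", "alpha-cypermethrin", 5.91, 0, "after", 36.0),
    ChemMeasure("duranet", "alpha-cypermethrin", 5.55, 20, "after", 36.0),
    ChemMeasure("duranet", "PBO", 1.86, 0, "before", 36.0),
    ChemMeasure("duranet", "PBO", 1.66, 20, "before", 36.0),
    ChemMeasure("duranet", "PBO", 1.71, 0, "after", 36.0),
    ChemMeasure("duranet", "PBO", 1.61, 20, "after", 36.0),
    ChemMeasure("interceptor", "alpha-cypermethrin", 5.25, 0, "before", 40.0),
    ChemMeasure("interceptor", "alpha-cypermethrin", 2.09, 20, "before", 40.0),
    ChemMeasure("interceptor", "alpha-cypermethrin", 3.23, 0, "after", 40.0),
    ChemMeasure("interceptor", "alpha-cypermethrin", 1.03, 20, "after", 40.0),
)

#: Label-declared contents, g/kg (fabric weight g/m^2 alongside).
DECLARED_CONTENT = {
    ("yahe", "alpha-cypermethrin"): 6.6,
    ("yahe", "PBO"): 2.4,
    ("interceptor", "alpha-cypermethrin"): 5.0,
    ("duranet", "alpha-cypermethrin"): 6.0,
    ("duranet", "PBO"): 2.2,
}

#: The eight published single-arm comparisons: adjusted OR (candidate vs
#: reference), robust 95% CI and two-sided p, as printed.  The margins
#: and verdicts are *not* stored -- they are recomputed from ARM_TOTALS
#: and these OR quadruples.
PUBLISHED_COMPARISONS = (
    dict(endpoint="blood_feeding", reference="interceptor_unwashed",
         candidate="yahe_unwashed", oratio=0.66, ci=(0.48, 0.92), p=0.014),
    dict(endpoint="blood_feeding", reference="interceptor_washed",
         candidate="yahe_unwashed", oratio=0.93, ci=(0.68, 1.27), p=0.665),
    dict(endpoint="blood_feeding", reference="duranet_unwashed",
         candidate="yahe_unwashed", oratio=0.78, ci=(0.54, 1.13), p=0.194),
    dict(endpoint="blood_feeding", reference="duranet_washed",
         candidate="yahe_washed", oratio=0.64, ci=(0.47, 0.85), p=0.004),
    dict(endpoint="mortality", reference="interceptor_unwashed",
         candidate="yahe_unwashed", oratio=1.29, ci=(0.90, 1.84), p=0.161),
    dict(endpoint="mortality", reference="interceptor_washed",
         candidate="yahe_unwashed", oratio=1.37, ci=(0.98, 1.91), p=0.061),
    dict(endpoint="mortality", reference="duranet_unwashed",
         candidate="yahe_unwashed", oratio=0.80, ci=(0.54, 1.20), p=0.290),
    dict(endpoint="mortality", reference="duranet_washed",
         candidate="yahe_washed", oratio=1.24, ci=(0.86, 1.78), p=0.257),
)

#: Pooled unwashed + washed comparisons (YAHE vs each comparator pair).
PUBLISHED_POOLED_COMPARISONS = (
    dict(endpoint="blood_feeding",
         reference_arms=("interceptor_unwashed", "interceptor_washed"),
         candidate_arms=("yahe_unwashed", "yahe_washed"),
         oratio=0.80, ci=(0.64, 1.00), p=0.049),
    dict(endpoint="blood_feeding",
         reference_arms=("duranet_unwashed", "duranet_washed"),
         candidate_arms=("yahe_unwashed", "yahe_washed"),
         oratio=0.67, ci=(0.52, 0.86), p=0.002),
    dict(endpoint="mortality",
         reference_arms=("interceptor_unwashed", "interceptor_washed"),
         candidate_arms=("yahe_unwashed", "yahe_washed"),
         oratio=1.33, ci=(1.04, 1.69), p=0.023),
    dict(endpoint="mortality",
         reference_arms=("duranet_unwashed", "duranet_washed"),
         candidate_arms=("yahe_unwashed", "yahe_washed"),
         oratio=1.02, ci=(0.78, 1.35), p=0.867),
)
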