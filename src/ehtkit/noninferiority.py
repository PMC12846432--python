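"""WHO-style non-inferiority evaluation on the odds-ratio scale.

A candidate net is compared to an active comparator on mosquito
mortality and blood feeding with a fixed absolute margin delta
(default 7 percentage points).  The margin is converted to the
odds-ratio scale at the comparator's observed proportion pi0:

    mortality      NIM = odds(pi0 - delta) / odds(pi0)   (< 1)
    blood feeding  NIM = odds(pi0 + delta) / odds(pi0)   (> 1)

with odds(p) = p / (1 - p).  Higher mortality favours the candidate,
so non-inferiority requires the OR's lower CI bound to stay above the
mortality NIM; lower feeding favours the candidate, so the upper CI
bound must stay below the blood-feeding NIM.  Superiority additionally
requires the two-sided p < alpha with the point estimate on the
favourable side of 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .glm import GlmFit, GlmSpec, OrEstimate, fit_glm, odds_ratio_contrast
from .trial_data import TrialDataset

__all__ = [
    "ENDPOINTS",
    "VERDICTS",
    "NiDecision",
    "nim_odds_ratio",
    "classify",
    "compare",
    "pooled_comparison",
]

ENDPOINTS = ("mortality", "blood_feeding")

#: Verdict strings as printed in WHO-style decision tables.
VERDICTS = (
    "non-inferior and superior",
    "non-inferior and not superior",
    "non-inferiority not shown",
)

_OUTCOME_FOR_ENDPOINT = {"mortality": "died", "blood_feeding": "fed"}


def _odds(p: float) -> float:
    return p / (1.0 - p)


def nim_odds_ratio(pi0: float, delta: float = 0.07, endpoint: str = "mortality") -> float:
    """Convert the absolute margin ``delta`` at comparator proportion
    ``pi0`` into an odds-ratio-scale non-inferiority margin."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if not 0.0 < pi0 < 1.0:
        raise ValueError(f"comparator proportion must be in (0, 1), got {pi0}")
    if delta < 0:
        raise ValueError("margin delta must be non-negative")
    shifted = pi0 - delta if endpoint == "mortality" else pi0 + delta
    if not 0.0 < shifted < 1.0:
        raise ValueError(
            f"margin delta={delta} pushes comparator proportion {pi0} outside (0, 1)"
        )
    return _odds(shifted) / _odds(pi0)


def classify(
    or_est: OrEstimate, nim: float, endpoint: str, alpha: float = 0.05
) -> str:
    """Apply the non-inferiority / superiority decision rules.

    Boundary ties (CI bound exactly equal to the margin) are resolved
    conservatively: the strict inequality fails and non-inferiority is
    not declared.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if endpoint == "mortality":
        non_inferior = or_est.ci_low > nim
        superior = or_est.p < alpha and or_est.oratio > 1.0
    else:
        non_inferior = or_est.ci_high < nim
        superior = or_est.p < alpha and or_est.oratio < 1.0
    if not non_inferior:
        return VERDICTS[2]
    return VERDICTS[0] if superior else VERDICTS[1]


@dataclass(frozen=True)
class NiDecision:
    """Complete record of one non-inferiority comparison."""

    endpoint: str
    candidate: str
    reference: str
    pi0: float
    delta: float
    nim: float
    or_estimate: OrEstimate
    verdict: str
    alpha: float = 0.05

    def to_json_dict(self) -> dict:
        e = self.or_estimate
        return {
            "endpoint": self.endpoint,
            "candidate": self.candidate,
            "reference": self.reference,
            "pi0": self.pi0,
            "delta": self.delta,
            "nim": self.nim,
            "or": e.oratio,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "p": e.p,
            "z": e.z,
            "verdict": self.verdict,
        }


def _reference_proportion(ds: TrialDataset, arms: Sequence[str], endpoint: str) -> float:
    num = den = 0
    for arm in arms:
        tot = ds.arm_totals(arm)
        num += tot.dead if endpoint == "mortality" else tot.fed
        den += tot.caught
    if den == 0:
        raise ValueError("comparator arms caught no mosquitoes")
    return num / den


def compare(
    ds: TrialDataset,
    candidate: str,
    reference: str,
    endpoint: str = "mortality",
    delta: float = 0.07,
    alpha: float = 0.05,
    fit: GlmFit | None = None,
) -> NiDecision:
    """Single-arm non-inferiority comparison.

    Fits (or reuses) the adjusted logistic model, extracts the candidate
    vs reference odds ratio with its cluster-robust CI, converts the
    margin at the comparator's crude proportion, and classifies.
    """
    outcome = _OUTCOME_FOR_ENDPOINT[endpoint]
    if fit is None or fit.spec.outcome != outcome:
        fit = fit_glm(GlmSpec(outcome=outcome), ds)
    or_est = odds_ratio_contrast(fit, candidate, reference)
    pi0 = _reference_proportion(ds, [reference], endpoint)
    nim = nim_odds_ratio(pi0, delta, endpoint)
    verdict = classify(or_est, nim, endpoint, alpha)
    return NiDecision(endpoint, candidate, reference, pi0, delta, nim, or_est, verdict, alpha)


def pooled_comparison(
    ds: TrialDataset,
    candidate_arms: Sequence[str],
    reference_arms: Sequence[str],
    endpoint: str = "mortality",
    delta: float = 0.07,
    alpha: float = 0.05,
) -> NiDecision:
    """Pooled (e.g. unwashed + washed) non-inferiority comparison.

    The candidate arms are merged into one treatment level and the
    reference arms into another; the adjusted model is fitted on the
    records of those arms only, keeping hut and bait adjustment and
    hut-night clustering.  pi0 is the crude proportion pooled over the
    reference arms.
    """
    candidate_arms = list(candidate_arms)
    reference_arms = list(reference_arms)
    if set(candidate_arms) & set(reference_arms):
        raise ValueError("candidate and reference arm sets overlap")
    frame = ds.frame[ds.frame["arm"].isin(candidate_arms + reference_arms)].copy()
    if frame.empty:
        raise ValueError("no records in the pooled arms")
    frame["arm"] = frame["arm"].map(
        lambda a: "pooled_candidate" if a in candidate_arms else "pooled_reference"
    )
    pooled = TrialDataset(frame)

    outcome = _OUTCOME_FOR_ENDPOINT[endpoint]
    fit = fit_glm(GlmSpec(outcome=outcome), pooled)
    or_est = odds_ratio_contrast(fit, "pooled_candidate", "pooled_reference")
    pi0 = _reference_proportion(ds, reference_arms, endpoint)
    nim = nim_odds_ratio(pi0, delta, endpoint)
    verdict = classify(or_est, nim, endpoint, alpha)
    return NiDecision(
        endpoint,
        "+".join(candidate_arms),
        "+".join(reference_arms),
        pi0,
        delta,
        nim,
        or_est,
        verdict,
        alpha,
    )
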