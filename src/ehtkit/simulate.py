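"""Synthetic hut-trial generator and simulation-based power assessment.

Reproduces the statistical structure the analysis assumes: a 7-arm,
7-hut trial with weekly Latin-square treatment rotation and daily bait
rotation, overdispersed nightly hut entries (negative binomial with
variance mu + mu^2/k), and per-mosquito Bernoulli outcomes (exit, feed,
die) at arm-specific probabilities.

The default configuration is the published trial's conditions: arm
exit/feed/kill probabilities and deterrence multipliers at the
magnitudes of the published per-arm totals, a baseline entry mean of
3.3 mosquitoes per hut-night, 7-night rotation periods, and 16 rounds
(112 nights per arm).  Dispersion k = 1.0 gives the strong night-to-
night overdispersion typical of hut catches.

Power for a non-inferiority comparison is estimated by simulating the
whole pipeline (generate -> adjusted logistic fit -> margin conversion
-> verdict) and counting the replicates that conclude non-inferiority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import GlmSpec, fit_glm, odds_ratio_contrast
from .noninferiority import classify, nim_odds_ratio
from .trial_data import COUNT_COLUMNS, HutNightRecord, TrialDataset
from . import refdata

__all__ = [
    "ArmProfile",
    "SimConfig",
    "RotationDesign",
    "PowerEstimate",
    "make_latin_square",
    "build_rotation_design",
    "simulate_trial",
    "power_noninferiority",
    "default_config",
]


@dataclass(frozen=True)
class ArmProfile:
    """Behavioural parameters of one treatment arm.

    deterrence multiplies the baseline entry mean (1 = no deterrence,
    < 1 = fewer entries than control); p_exit / p_feed / p_die are
    per-mosquito Bernoulli probabilities.  ``joint_fed_dead``, if set,
    is a 2x2 matrix of joint (fed, dead) probabilities replacing the
    independent product -- a sensitivity option, since the analysis
    only ever uses the margins.
    """

    name: str
    p_exit: float
    p_feed: float
    p_die: float
    deterrence: float = 1.0
    joint_fed_dead: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        for p in (self.p_exit, self.p_feed, self.p_die):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.deterrence <= 0:
            raise ValueError("deterrence multiplier must be positive")
        if self.joint_fed_dead is not None:
            flat = [p for row in self.joint_fed_dead for p in row]
            if any(p < 0 for p in flat) or abs(sum(flat) - 1.0) > 1e-9:
                raise ValueError("joint fed x dead probabilities must sum to 1")

    def cell_probabilities(self) -> np.ndarray:
        """12-cell probabilities [location, fed, dead]; exited mosquitoes
        split 50:50 between veranda and window traps."""
        loc = np.array([1.0 - self.p_exit, self.p_exit / 2.0, self.p_exit / 2.0])
        if self.joint_fed_dead is not None:
            fd = np.asarray(self.joint_fed_dead, dtype=float)
        else:
            fed = np.array([1.0 - self.p_feed, self.p_feed])
            dead = np.array([1.0 - self.p_die, self.p_die])
            fd = np.outer(fed, dead)
        return loc[:, None, None] * fd[None, :, :]


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration (see module docstring for defaults)."""

    arms: tuple[ArmProfile, ...]
    mu: float = 3.3
    hut_effects: tuple[float, ...] | None = None
    bait_effects: tuple[float, ...] | None = None
    dispersion_k: float = 1.0
    rotation_length: int = 7
    rounds: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.arms)
        if n < 1:
            raise ValueError("need at least one arm")
        if self.mu <= 0 or self.dispersion_k <= 0:
            raise ValueError("mu and dispersion k must be positive")
        for effects, label in ((self.hut_effects, "hut"), (self.bait_effects, "bait")):
            if effects is not None:
                if len(effects) != n:
                    raise ValueError(f"{label} effects must have one entry per hut")
                if any(e <= 0 for e in effects):
                    raise ValueError(f"{label} effects must be positive")

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    @property
    def n_nights(self) -> int:
        return self.rotation_length * self.rounds


@dataclass(frozen=True)
class RotationDesign:
    """arm_of[hut, night] and bait_of[hut, night] index arrays."""

    arm_of: np.ndarray
    bait_of: np.ndarray


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    ci_low: float
    ci_high: float
    replicates: int
    n_non_inferior: int


def make_latin_square(n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Random n x n Latin square.

    A cyclic square has its rows, columns and symbols independently
    permuted under the seed; every row and column remains a permutation
    of 0..n-1, and the same seed always yields the same square.
    """
    if n < 1:
        raise ValueError("order must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = (np.arange(n)[:, None] + np.arange(n)[None, :]) % n
    rows, cols, symbols = rng.permutation(n), rng.permutation(n), rng.permutation(n)
    return symbols[base[np.ix_(rows, cols)]]


def build_rotation_design(cfg: SimConfig, rng: np.random.Generator) -> RotationDesign:
    """Weekly treatment rotation and daily bait rotation.

    The treatment square assigns arm_of[hut, period]; with more rounds
    than arms the square's columns are tiled cyclically, so every
    complete block of n_arms periods is Latin.  Baits follow an
    independent daily cyclic shift of a seeded permutation -- a Latin
    structure at the nightly scale, without claiming orthogonality to
    the treatment square.
    """
    n = cfg.n_arms
    square = make_latin_square(n, rng)
    arm_of = np.empty((n, cfg.n_nights), dtype=np.int64)
    for night in range(cfg.n_nights):
        period = night // cfg.rotation_length
        arm_of[:, night] = square[:, period % n]
    bait_perm = rng.permutation(n)
    bait_of = np.empty_like(arm_of)
    for night in range(cfg.n_nights):
        bait_of[:, night] = bait_perm[(np.arange(n) + night) % n]
    return RotationDesign(arm_of=arm_of, bait_of=bait_of)


def simulate_trial(cfg: SimConfig, rng: np.random.Generator | None = None) -> TrialDataset:
    """Generate one full trial dataset under the configuration.

    Nightly entries per hut are negative binomial with mean
    mu * hut_effect * bait_effect * deterrence and dispersion k; each
    entering mosquito is allocated to one of the 12 cells by a single
    multinomial draw over the arm's cell probabilities.  Fully
    reproducible from ``cfg.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    design = build_rotation_design(cfg, rng)
    hut_eff = np.asarray(cfg.hut_effects or [1.0] * cfg.n_arms, dtype=float)
    bait_eff = np.asarray(cfg.bait_effects or [1.0] * cfg.n_arms, dtype=float)
    cell_p = {i: arm.cell_probabilities().ravel() for i, arm in enumerate(cfg.arms)}

    records = []
    k = cfg.dispersion_k
    for night in range(1, cfg.n_nights + 1):
        for hut in range(cfg.n_arms):
            arm_idx = int(design.arm_of[hut, night - 1])
            bait_idx = int(design.bait_of[hut, night - 1])
            arm = cfg.arms[arm_idx]
            mean = cfg.mu * hut_eff[hut] * bait_eff[bait_idx] * arm.deterrence
            entries = int(rng.negative_binomial(k, k / (k + mean)))
            counts = rng.multinomial(entries, cell_p[arm_idx]).reshape(3, 2, 2)
            records.append(
                HutNightRecord(
                    night=night,
                    hut=f"hut{hut + 1}",
                    bait=f"bait{bait_idx + 1}",
                    arm=arm.name,
                    counts=counts,
                )
            )
    return TrialDataset.from_records(records)


def default_config(seed: int = 0, rounds: int = 16, **overrides) -> SimConfig:
    """The published trial's conditions as a simulator configuration.

    Exit/feed/kill probabilities and deterrence multipliers are the
    published per-arm proportions; the untreated arm anchors deterrence
    at 1 and the baseline mean at caught/nights = 3.3 per night.
    """
    totals = refdata.ARM_TOTALS
    t_u = totals[refdata.UNTREATED].caught
    arms = tuple(
        ArmProfile(
            name=arm,
            p_exit=t.exited / t.caught,
            p_feed=t.fed / t.caught,
            p_die=t.dead / t.caught,
            deterrence=t.caught / t_u,
        )
        for arm, t in totals.items()
    )
    mu = t_u / refdata.NIGHTS_PER_ARM
    return SimConfig(arms=arms, mu=mu, rounds=rounds, seed=seed, **overrides)


def power_noninferiority(
    cfg: SimConfig,
    candidate: str,
    reference: str,
    endpoint: str = "mortality",
    delta: float = 0.07,
    alpha: float = 0.05,
    replicates: int = 500,
    seed: int | None = None,
) -> PowerEstimate:
    """Fraction of simulated trials concluding non-inferiority (or better).

    Each replicate draws an independent stream from the master seed
    (``seed`` if given, else ``cfg.seed``), simulates a trial, fits the
    adjusted logistic model, converts the margin at the simulated
    comparator proportion, and classifies.  The binomial 95% CI on the
    power is Wilson's.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    master = cfg.seed if seed is None else seed
    streams = np.random.SeedSequence(master).spawn(replicates)
    outcome = "died" if endpoint == "mortality" else "fed"
    wins = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        ds = simulate_trial(cfg, rng=rng)
        fit = fit_glm(GlmSpec(outcome=outcome), ds)
        or_est = odds_ratio_contrast(fit, candidate, reference)
        tot = ds.arm_totals(reference)
        pi0 = (tot.dead if endpoint == "mortality" else tot.fed) / tot.caught
        nim = nim_odds_ratio(pi0, delta, endpoint)
        if classify(or_est, nim, endpoint, alpha) != "non-inferiority not shown":
            wins += 1
    p = wins / replicates
    z = 1.959963984540054
    denom = 1 + z**2 / replicates
    centre = (p + z**2 / (2 * replicates)) / denom
    half = z * np.sqrt(p * (1 - p) / replicates + z**2 / (4 * replicates**2)) / denom
    return PowerEstimate(
        power=p,
        ci_low=max(0.0, centre - half),
        ci_high=min(1.0, centre + half),
        replicates=replicates,
        n_non_inferior=wins,
    )
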