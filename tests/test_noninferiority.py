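"""Margin conversion and decision rules against the published tables."""

import pytest
from hypothesis import given, strategies as st

import ehtkit as ek
from ehtkit.glm import OrEstimate
from ehtkit.noninferiority import VERDICTS, classify, nim_odds_ratio
from ehtkit.refdata import ARM_TOTALS, DELTA


def _pi0(arm, endpoint):
    t = ARM_TOTALS[arm]
    return (t.dead if endpoint == "mortality" else t.fed) / t.caught


@pytest.mark.parametrize(
    "arm, endpoint, expected",
    [
        ("interceptor_unwashed", "blood_feeding", 1.33),
        ("interceptor_washed", "blood_feeding", 1.37),
        ("duranet_unwashed", "blood_feeding", 1.34),
        ("duranet_washed", "blood_feeding", 1.32),
        ("interceptor_unwashed", "mortality", 0.75),
        ("interceptor_washed", "mortality", 0.75),
        ("duranet_unwashed", "mortality", 0.76),
        ("duranet_washed", "mortality", 0.76),
    ],
)
def test_single_arm_margins_reproduce_published_tables(arm, endpoint, expected):
    assert round(nim_odds_ratio(_pi0(arm, endpoint), DELTA, endpoint), 2) == expected


@pytest.mark.parametrize(
    "arms, expected",
    [
        (("interceptor_unwashed", "interceptor_washed"), 1.35),
        (("duranet_unwashed", "duranet_washed"), 1.33),
    ],
)
def test_pooled_blood_feeding_margins_reproduce_published(arms, expected):
    fed = sum(ARM_TOTALS[a].fed for a in arms)
    caught = sum(ARM_TOTALS[a].caught for a in arms)
    assert round(nim_odds_ratio(fed / caught, DELTA, "blood_feeding"), 2) == expected


def test_zero_margin_gives_unit_odds_ratio():
    assert nim_odds_ratio(0.4, 0.0, "mortality") == pytest.approx(1.0)
    assert nim_odds_ratio(0.4, 0.0, "blood_feeding") == pytest.approx(1.0)


def test_margin_outside_unit_interval_errors():
    with pytest.raises(ValueError):
        nim_odds_ratio(0.05, 0.07, "mortality")
    with pytest.raises(ValueError):
        nim_odds_ratio(0.96, 0.07, "blood_feeding")


@given(st.floats(min_value=0.08, max_value=0.92))
def test_margin_direction_bands(pi0):
    """For delta = 0.07 the mortality margin always sits in (0, 1) and
    the blood-feeding margin in (1, inf)."""
    assert 0.0 < nim_odds_ratio(pi0, 0.07, "mortality") < 1.0
    assert nim_odds_ratio(pi0, 0.07, "blood_feeding") > 1.0


@given(
    st.floats(min_value=0.08, max_value=0.92),
    st.floats(min_value=0.001, max_value=0.07),
)
def test_margin_round_trip_recovers_shifted_odds(pi0, delta):
    odds = lambda p: p / (1 - p)
    nim_m = nim_odds_ratio(pi0, delta, "mortality")
    assert nim_m * odds(pi0) == pytest.approx(odds(pi0 - delta), rel=1e-12)
    nim_b = nim_odds_ratio(pi0, delta, "blood_feeding")
    assert nim_b * odds(pi0) == pytest.approx(odds(pi0 + delta), rel=1e-12)


def _or(oratio, lo, hi, p):
    import math

    se = (math.log(hi) - math.log(lo)) / (2 * 1.96) or 1e-6
    z = math.log(oratio) / se
    return OrEstimate(oratio=oratio, ci_low=lo, ci_high=hi, p=p, z=z, se_log=se)


#: the eight published decision rows: OR, CI, p, margin, endpoint, verdict
PUBLISHED_ROWS = [
    (0.66, 0.48, 0.92, 0.014, 1.33, "blood_feeding", VERDICTS[0]),
    (0.93, 0.68, 1.27, 0.665, 1.37, "blood_feeding", VERDICTS[1]),
    (0.78, 0.54, 1.13, 0.194, 1.34, "blood_feeding", VERDICTS[1]),
    (0.64, 0.47, 0.85, 0.004, 1.32, "blood_feeding", VERDICTS[0]),
    (1.29, 0.90, 1.84, 0.161, 0.75, "mortality", VERDICTS[1]),
    (1.37, 0.98, 1.91, 0.061, 0.75, "mortality", VERDICTS[1]),
    (0.80, 0.54, 1.20, 0.290, 0.76, "mortality", VERDICTS[2]),
    (1.24, 0.86, 1.78, 0.257, 0.76, "mortality", VERDICTS[1]),
]


@pytest.mark.parametrize("oratio, lo, hi, p, nim, endpoint, expected", PUBLISHED_ROWS)
def test_published_decision_rows_classify_identically(oratio, lo, hi, p, nim, endpoint, expected):
    assert classify(_or(oratio, lo, hi, p), nim, endpoint) == expected


def test_pooled_published_quadruples_classify_as_printed():
    # pooled blood feeding: superiority forced by p < 0.05 even though
    # the rounded CI touches 1.00
    assert classify(_or(0.80, 0.64, 1.00, 0.049), 1.35, "blood_feeding") == VERDICTS[0]
    assert classify(_or(0.67, 0.52, 0.86, 0.002), 1.33, "blood_feeding") == VERDICTS[0]
    assert classify(_or(1.02, 0.78, 1.35, 0.867), 0.72, "mortality") == VERDICTS[1]


def test_boundary_tie_is_not_non_inferior():
    est = _or(1.0, 0.76, 1.3, 0.9)
    assert classify(est, 0.76, "mortality") == VERDICTS[2]
    est = _or(1.0, 0.8, 1.33, 0.9)
    assert classify(est, 1.33, "blood_feeding") == VERDICTS[2]


@given(
    st.floats(min_value=0.1, max_value=3.0),
    st.floats(min_value=0.01, max_value=1.0),
    st.floats(min_value=0.01, max_value=1.0),
)
def test_widening_the_interval_never_creates_non_inferiority(oratio, half1, half2):
    """Monotonicity: if the narrow CI fails to show non-inferiority, any
    wider CI fails too."""
    import math

    lo_n, hi_n = oratio * math.exp(-half1), oratio * math.exp(half1)
    widen = half1 + half2
    lo_w, hi_w = oratio * math.exp(-widen), oratio * math.exp(widen)
    for endpoint, nim in (("mortality", 0.75), ("blood_feeding", 1.33)):
        narrow = classify(_or(oratio, lo_n, hi_n, 0.5), nim, endpoint)
        wide = classify(_or(oratio, lo_w, hi_w, 0.5), nim, endpoint)
        if narrow == VERDICTS[2]:
            assert wide == VERDICTS[2]


def test_pooling_two_identical_arms_preserves_the_margin(small_trial):
    """Pooled pi0 over two copies of the same arm equals the single-arm
    pi0, so the margin is unchanged."""
    t = ARM_TOTALS["duranet_unwashed"]
    single = nim_odds_ratio(t.dead / t.caught, DELTA, "mortality")
    pooled_pi0 = (t.dead + t.dead) / (t.caught + t.caught)
    assert nim_odds_ratio(pooled_pi0, DELTA, "mortality") == pytest.approx(single)


def test_full_comparison_on_simulated_trial(small_trial):
    decision = ek.compare(small_trial, "yahe_unwashed", "duranet_unwashed", "mortality")
    assert decision.verdict in VERDICTS
    assert 0 < decision.nim < 1
    tot = small_trial.arm_totals("duranet_unwashed")
    assert decision.pi0 == pytest.approx(tot.dead / tot.caught)


def test_pooled_comparison_runs_and_uses_crude_pooled_pi0(small_trial):
    decision = ek.pooled_comparison(
        small_trial,
        ["yahe_unwashed", "yahe_washed"],
        ["interceptor_unwashed", "interceptor_washed"],
        "blood_feeding",
    )
    a = small_trial.arm_totals("interceptor_unwashed")
    b = small_trial.arm_totals("interceptor_washed")
    assert decision.pi0 == pytest.approx((a.fed + b.fed) / (a.caught + b.caught))
    assert decision.nim > 1
    assert decision.verdict in VERDICTS
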