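"""Evidence-to-probability conversions and duration calibration."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mcrpcsim import (
    CalibrationError,
    TrialEvidence,
    builtin_model,
    calibrate_state,
    fit_progression_to_mean,
    prob_from_fraction,
    prob_from_rate,
    rate_from_median,
    simulate_cohort,
    survival_calibration,
)
from mcrpcsim.transitions import (
    occupancy_mean,
    occupancy_median,
    occupancy_survival,
    progression_fraction,
)

# ---------------------------------------------------------------------------
# independent oracle: explicit enumeration of the occupancy distribution
# ---------------------------------------------------------------------------


def occupancy_pmf(p_death, p_progress, min_cycles, tmax=20_000):
    """P(D = t) by direct per-cycle enumeration of the pay-then-draw law."""
    m = max(min_cycles, 1)
    pmf = {}
    alive = 1.0
    for t in range(1, tmax + 1):
        # after paying month t the patient draws: death first, then (if past
        # the minimum) progression
        exit_p = p_death if t < m else p_death + (1 - p_death) * p_progress
        pmf[t] = alive * exit_p
        alive *= 1 - exit_p
        if alive < 1e-15:
            break
    return pmf


def pmf_median(pmf):
    cum = 0.0
    for t in sorted(pmf):
        cum += pmf[t]
        if cum >= 0.5:
            return t
    raise AssertionError("pmf mass below 0.5")


def pmf_mean(pmf):
    return sum(t * p for t, p in pmf.items()) / sum(pmf.values())


# ---------------------------------------------------------------------------
# elementary conversions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "median,expected",
    [(18.9, 0.036674), (math.log(2), 1.0)],
)
def test_rate_from_median(median, expected):
    assert rate_from_median(median) == pytest.approx(expected, abs=1e-5)


def test_rate_vanishes_for_long_medians():
    assert rate_from_median(1e9) == pytest.approx(0.0, abs=1e-8)
    with pytest.raises(ValueError):
        rate_from_median(0.0)


@pytest.mark.parametrize(
    "rate,t,expected",
    [(0.0, 1.0, 0.0), (math.log(2), 1.0, 0.5),
     (rate_from_median(16.7), 1.0, 0.040657)],
)
def test_prob_from_rate(rate, t, expected):
    assert prob_from_rate(rate, t) == pytest.approx(expected, abs=1e-5)
    with pytest.raises(ValueError):
        prob_from_rate(-0.1)


@pytest.mark.parametrize(
    "P,T,expected",
    [(0.5, 1.0, 0.5), (0.5, 24.0, 0.028466), (0.42, 12.8, 0.041664)],
)
def test_prob_from_fraction(P, T, expected):
    assert prob_from_fraction(P, T) == pytest.approx(expected, abs=1e-5)


@given(P=st.floats(min_value=1e-6, max_value=1 - 1e-6))
def test_prob_from_fraction_one_month_identity(P):
    assert prob_from_fraction(P, 1.0) == pytest.approx(P, rel=1e-9)


@given(m=st.floats(min_value=0.5, max_value=120))
def test_median_conversion_accumulates_to_half(m):
    """1 - (1-p)^m = 1/2 when p is the monthly conversion of median m."""
    p = prob_from_rate(rate_from_median(m))
    assert 1 - (1 - p) ** m == pytest.approx(0.5, abs=1e-12)


def test_prob_from_fraction_domain():
    for bad in (0.0, 1.0, -0.2):
        with pytest.raises(ValueError):
            prob_from_fraction(bad, 12.0)
    with pytest.raises(ValueError):
        prob_from_fraction(0.5, 0.0)


# ---------------------------------------------------------------------------
# occupancy closed forms vs enumeration oracle
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pd_,pp,m",
    [(0.0, 0.2, 0), (0.04, 0.3, 3), (0.036, 0.49, 7), (0.1, 0.05, 1),
     (0.0140, 0.1607, 4)],
)
def test_occupancy_closed_forms_match_enumeration(pd_, pp, m):
    pmf = occupancy_pmf(pd_, pp, m)
    assert occupancy_mean(pd_, pp, m) == pytest.approx(pmf_mean(pmf), abs=1e-6)
    assert occupancy_median(pd_, pp, m) == pmf_median(pmf)
    surv = sum(p for t, p in pmf.items() if t >= 5)
    assert float(occupancy_survival(5, pd_, pp, m)) == pytest.approx(surv, abs=1e-9)


@given(
    pd_=st.floats(min_value=0.0, max_value=0.2),
    m=st.integers(min_value=0, max_value=12),
    mean=st.floats(min_value=1.5, max_value=40),
)
def test_fit_progression_round_trip(pd_, m, mean):
    """Solving p_progress for a target mean then re-evaluating recovers it."""
    head = m if pd_ == 0 else (1 - (1 - pd_) ** max(m, 1)) / pd_
    try:
        pp = fit_progression_to_mean(pd_, mean, m)
    except CalibrationError:
        assert mean < head + 1e-9 or pd_ > 0  # infeasible targets only
        return
    assert occupancy_mean(pd_, pp, m) == pytest.approx(mean, rel=1e-9)


def test_progression_fraction_equals_death_complement():
    """P(die in state) = p_death * E[D] under pay-then-draw, so the
    progression fraction is its complement."""
    for pd_, pp, m in [(0.04, 0.3, 3), (0.014, 0.16, 4)]:
        assert progression_fraction(pd_, pp, m) == pytest.approx(
            1 - pd_ * occupancy_mean(pd_, pp, m), rel=1e-9
        )


# ---------------------------------------------------------------------------
# calibrate_state
# ---------------------------------------------------------------------------


def test_calibrate_pure_geometric_median():
    """With no mortality the recipe reduces to the pure geometric law."""
    params = calibrate_state(TrialEvidence("x", median_duration=4.0), p_death=0.0)
    assert params.min_cycles == 0
    assert pmf_median(occupancy_pmf(0.0, params.p_progress, 0)) == 4


def test_calibrate_docetaxel_median():
    """The chemotherapy state calibrated to its 7.13-month trial median
    has occupancy median 7."""
    p_death = prob_from_rate(rate_from_median(18.9))
    params = calibrate_state(TrialEvidence("Docetaxel", median_duration=7.13), p_death)
    pmf = occupancy_pmf(p_death, params.p_progress, params.min_cycles)
    assert pmf_median(pmf) == 7


@pytest.mark.parametrize("median", [2, 5, 9, 14, 20, 24])
def test_calibrate_recovers_enumerated_median(median):
    p_death = prob_from_fraction(0.5, 36.0)
    params = calibrate_state(TrialEvidence("x", median_duration=float(median)), p_death)
    assert abs(pmf_median(occupancy_pmf(p_death, params.p_progress,
                                        params.min_cycles)) - median) <= 0.5


def test_calibrate_degenerate_minimum_is_deterministic():
    """p_progress = 1 past the minimum gives a deterministic duration."""
    pmf = occupancy_pmf(0.0, 1.0, 5)
    assert pmf[5] == pytest.approx(1.0)
    assert pmf_median(pmf) == 5


def test_calibrate_infeasible_reports_nearest():
    p_death = 0.9  # near-certain monthly death: long medians unreachable
    with pytest.raises(CalibrationError, match="nearest achievable"):
        calibrate_state(TrialEvidence("x", median_duration=20.0), p_death)


def test_calibrate_requires_duration():
    with pytest.raises(ValueError):
        calibrate_state(TrialEvidence("x", median_survival=12.0), 0.02)


# ---------------------------------------------------------------------------
# monotonicity and whole-model survival calibration
# ---------------------------------------------------------------------------


def test_mortality_never_lengthens_occupancy():
    """Raising p_death (p_progress held) cannot increase mean duration."""
    for pp, m in [(0.1, 0), (0.3, 4)]:
        means = [occupancy_mean(pd_, pp, m) for pd_ in (0.0, 0.02, 0.05, 0.2)]
        assert all(a >= b for a, b in zip(means, means[1:]))


def test_survival_calibration_hits_target(current_spec):
    """The built-in pathway already sits at the 25-month median overall
    survival target, and the calibration keeps it there."""
    calibrated = survival_calibration(current_spec, 25.0, sim_budget=30_000, seed=7)
    summ = simulate_cohort(calibrated, 30_000, 8)
    assert abs(summ.os_median - 25.0) <= 1.0


def test_survival_calibration_rejects_immortal_model(current_spec):
    import dataclasses

    states = tuple(dataclasses.replace(s, p_death=0.0) for s in current_spec.states)
    immortal = current_spec.replace(states=states)
    with pytest.raises(CalibrationError):
        survival_calibration(immortal, 25.0, sim_budget=1000)


def test_doubling_mortality_roughly_halves_survival():
    """In a single-line model survival is governed by p_death alone."""
    import dataclasses

    spec = builtin_model("current")
    # isolate mortality: forbid progression, lift the cap far away
    states = []
    for s in spec.states:
        states.append(dataclasses.replace(s, p_progress=0.0, min_cycles=0,
                                          cap_cycles=3000 if s.is_last_line else None))
    base = spec.replace(states=tuple(states), otherx_cap=3000)
    doubled = base.replace(
        states=tuple(dataclasses.replace(s, p_death=2 * s.p_death) for s in base.states)
    )
    s1 = simulate_cohort(base, 50_000, 11)
    s2 = simulate_cohort(doubled, 50_000, 12)
    assert s2.os_median == pytest.approx(s1.os_median / 2, rel=0.12)
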