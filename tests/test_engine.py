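"""Microsimulation engine: cycle law, tracker accounting, replicate CIs."""

import dataclasses
import math

import numpy as np
import pytest

from mcrpcsim import (
    ModelSpec,
    TreatmentState,
    builtin_model,
    replicate_ci,
    simulate_cohort,
    simulate_patient,
    step,
)
from mcrpcsim.costing import supportive_monthly_rates


def _single_state_spec(p_death, p_progress=0.0, min_cycles=0, cost=100.0,
                       cap=3000):
    """One active line feeding a far-capped terminal state."""
    return ModelSpec(
        variant="custom",
        states=(
            TreatmentState("S0", cost, min_cycles, p_progress, p_death),
            TreatmentState("OtherTx", 0.0, 0, 0.0, p_death or 0.5,
                           is_last_line=True, cap_cycles=cap),
        ),
        castration_monthly_cost=0.0,
        bone_monthly_cost=0.0,
        otherx_cap=cap,
    )


# ---------------------------------------------------------------------------
# step
# ---------------------------------------------------------------------------


def test_step_degenerate_probabilities():
    never = TreatmentState("x", 0.0, 0, 0.0, 0.0)
    always = TreatmentState("x", 0.0, 0, 0.0, 1.0)
    for u in (0.0, 0.3, 0.999):
        assert step(never, 5, u) == "stay"
        assert step(always, 5, u) == "die"


def test_step_threshold_partition():
    """With p_death 0.1 and p_progress 0.5 the draw space splits exactly
    into die 0.10, advance 0.45, stay 0.45 (death evaluated first)."""
    st_ = TreatmentState("x", 0.0, 0, 0.5, 0.1)
    u = (np.arange(1_000_000) + 0.5) / 1_000_000  # uniform grid, exact fractions
    die = (u < 0.1).mean()
    adv = ((u >= 0.1) & (u < 0.1 + 0.9 * 0.5)).mean()
    # cross-check the scalar step on the boundary neighbourhoods
    assert step(st_, 1, 0.0999999) == "die"
    assert step(st_, 1, 0.1000001) == "advance"
    assert step(st_, 1, 0.5499999) == "advance"
    assert step(st_, 1, 0.5500001) == "stay"
    assert die == pytest.approx(0.10, abs=1e-6)
    assert adv == pytest.approx(0.45, abs=1e-6)


def test_step_minimum_blocks_progression_not_death():
    st_ = TreatmentState("x", 0.0, 6, 0.9, 0.05)
    assert step(st_, 3, 0.04) == "die"
    assert step(st_, 3, 0.5) == "stay"  # would advance if past the minimum
    assert step(st_, 6, 0.5) == "advance"


def test_step_rejects_bad_draw():
    with pytest.raises(ValueError):
        step(TreatmentState("x", 0.0, 0, 0.1, 0.1), 0, 1.5)


# ---------------------------------------------------------------------------
# single-patient path
# ---------------------------------------------------------------------------


def test_patient_zero_cost_spec(current_spec):
    free = current_spec.replace(
        states=tuple(dataclasses.replace(s, primary_monthly_cost=0.0)
                     for s in current_spec.states),
        castration_monthly_cost=0.0,
        bone_monthly_cost=0.0,
    )
    rec = simulate_patient(free, np.random.default_rng(0))
    assert rec.total_cost == 0.0


def test_patient_conservation_identity(current_spec):
    """Total cost is exactly paid cycles x monthly rates per state, plus
    the death-month supportive accrual."""
    cast, bone = supportive_monthly_rates(current_spec)
    rng = np.random.default_rng(42)
    for _ in range(200):
        rec = simulate_patient(current_spec, rng)
        expected = sum(
            rec.cycles_in_state[s.name] * s.primary_monthly_cost
            for s in current_spec.states
        ) + rec.mcrpc_months * (cast + bone)
        assert rec.total_cost == pytest.approx(expected, abs=1e-9)
        assert rec.mcrpc_months == rec.months_on_treatment + (1 if rec.died else 0)


def test_patient_geometric_death():
    """A single state with p_death 1/2 gives geometric survival, mean 2."""
    spec = _single_state_spec(p_death=0.5)
    rng = np.random.default_rng(3)
    months = [simulate_patient(spec, rng).months_on_treatment for _ in range(4000)]
    assert np.mean(months) == pytest.approx(2.0, rel=0.05)


def test_patient_surviving_all_lines_ends_in_othertx(current_spec):
    rng = np.random.default_rng(7)
    seen = set()
    for _ in range(500):
        rec = simulate_patient(current_spec, rng)
        seen.add(rec.last_line_received)
        if rec.censored:
            assert rec.last_line_received == "OtherTx"
            assert rec.cycles_in_state["OtherTx"] == current_spec.otherx_cap
    assert "OtherTx" in seen


# ---------------------------------------------------------------------------
# cohort path
# ---------------------------------------------------------------------------


def test_cohort_determinism(current_spec):
    s1 = simulate_cohort(current_spec, 5000, 123)
    s2 = simulate_cohort(current_spec, 5000, 123)
    assert s1.totals.equals(s2.totals)
    assert s1.states.equals(s2.states)
    s3 = simulate_cohort(current_spec, 5000, 124)
    assert not s1.totals.equals(s3.totals)


def test_cohort_conservation_exact(current_spec):
    """Per-patient cost identity holds exactly in the vectorised path."""
    _, rec = simulate_cohort(current_spec, 20_000, 5, return_records=True)
    cast, bone = supportive_monthly_rates(current_spec)
    prim = rec.cycles @ np.array(
        [s.primary_monthly_cost for s in current_spec.states]
    )
    costs = rec.category_costs()
    supp = rec.mcrpc_months * (cast + bone)
    np.testing.assert_allclose(costs["total"], prim + supp, rtol=0, atol=1e-9)
    np.testing.assert_allclose(
        costs["total"], costs["primary"] + costs["castration"] + costs["bone"],
        rtol=0, atol=1e-9,
    )


def test_utilization_monotone_along_chain(current_spec, alternate_spec):
    for spec in (current_spec, alternate_spec):
        for seed in (0, 1, 2):
            util = simulate_cohort(spec, 20_000, seed).states["utilization"]
            assert (np.diff(util.to_numpy()) <= 0).all()


def test_minimum_cycles_enforced(current_spec):
    """No one progresses out of a line before its protocol minimum."""
    _, rec = simulate_cohort(current_spec, 20_000, 9, return_records=True)
    names = current_spec.state_names
    for i, s in enumerate(current_spec.states[:-1]):
        entered_next = rec.cycles[:, i + 1] > 0
        assert (rec.cycles[entered_next, i] >= s.min_cycles).all(), names[i]


def test_geometric_oracle_min_cycles_zero():
    """With no protocol minimum the occupancy is exactly geometric on the
    combined exit probability: Kolmogorov-Smirnov at alpha = 0.001."""
    p_death, p_progress = 0.05, 0.15
    spec = _single_state_spec(p_death, p_progress, min_cycles=0)
    n = 100_000
    _, rec = simulate_cohort(spec, n, 17, return_records=True)
    d = rec.cycles[:, 0]
    e = p_death + (1 - p_death) * p_progress
    t = np.arange(1, d.max() + 1)
    cdf = 1 - (1 - e) ** t
    emp = np.searchsorted(np.sort(d), t, side="right") / n
    ks = np.abs(emp - cdf).max()
    assert ks < 1.949 / math.sqrt(n)  # critical value at alpha = 0.001


def test_mean_survival_decomposition(current_spec):
    """Mean mCRPC months = sum over states of utilization x mean paid
    duration among entrants, plus the death-month fraction."""
    summ = simulate_cohort(current_spec, 30_000, 21)
    parts = (summ.states["utilization"] * summ.states["dur_mean"]).sum()
    assert summ.mcrpc_months_mean == pytest.approx(
        parts + summ.death_fraction, abs=1e-9
    )


def test_bone_coverage_zero_removes_exactly_bone_component(current_spec):
    base = simulate_cohort(current_spec, 20_000, 31)
    nobone = simulate_cohort(
        current_spec.replace(bone_coverage=0.0), 20_000, 31
    )
    assert nobone.totals.loc["bone", "mean"] == 0.0
    assert nobone.totals.loc["total", "mean"] == pytest.approx(
        base.totals.loc["total", "mean"] - base.totals.loc["bone", "mean"], abs=1e-9
    )


def test_othertx_cap_censors_at_two_years(current_spec):
    _, rec = simulate_cohort(current_spec, 20_000, 37, return_records=True)
    otx = rec.cycles[:, -1]
    assert otx.max() <= current_spec.otherx_cap
    assert (otx[rec.censored] == current_spec.otherx_cap).all()
    assert not (rec.died & rec.censored).any()
    assert (rec.died | rec.censored).all()


# ---------------------------------------------------------------------------
# replicate-sample confidence intervals
# ---------------------------------------------------------------------------


def test_replicate_ci_zero_cost():
    spec = _single_state_spec(0.3, 0.1, cost=0.0)
    rep = replicate_ci(spec, sample_size=200, n_samples=20, seed=1)
    assert rep.point == 0.0 and rep.ci95 == (0.0, 0.0)


def test_replicate_ci_brackets_point(current_spec):
    rep = replicate_ci(current_spec, sample_size=500, n_samples=40, seed=2)
    assert rep.ci95[0] <= rep.point <= rep.ci95[1]


def test_replicate_ci_determinism(current_spec):
    a = replicate_ci(current_spec, 300, 20, seed=5)
    b = replicate_ci(current_spec, 300, 20, seed=5)
    assert np.array_equal(a.sample_means, b.sample_means)
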