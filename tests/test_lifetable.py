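import math

import numpy as np
import pytest

from aphidcascade.lifetable import (
    CohortSchedule,
    IndividualRecord,
    LifeTableError,
    NoReproductionError,
    bootstrap_lifetable,
    build_schedule,
    cohort_summary,
    finite_rate,
    intrinsic_rate,
    mean_generation_time,
    net_reproductive_rate,
)
from aphidcascade.simulate import gen_cohort


def _schedule(l_m_pairs, stage="adult"):
    """Single-stage schedule with given (l_x, m_x) rows."""
    s = np.array([[l] for l, _ in l_m_pairs], dtype=float)
    f = np.array([[m] for _, m in l_m_pairs], dtype=float)
    return CohortSchedule(n=1, stages=(stage,), s_xj=s, f_xj=f)


def _individual(id, stages, offspring, treatment="T"):
    return IndividualRecord(id=id, treatment=treatment, stages=tuple(stages), offspring=tuple(offspring))


# ---------------------------------------------------------------------------
# record / schedule construction


def test_record_invariants_enforced():
    with pytest.raises(LifeTableError):
        _individual("a", ["nymph", "adult", "nymph"], [0, 1, 0])  # stage reversal
    with pytest.raises(LifeTableError):
        _individual("b", ["nymph", "nymph"], [0, 2])  # nymph reproduction
    with pytest.raises(LifeTableError):
        _individual("c", [], [])


def test_build_schedule_simple_counts():
    recs = [
        _individual("a", ["nymph", "adult"], [0, 1]),
        _individual("b", ["nymph"], [0]),
    ]
    sched = build_schedule(recs)
    assert sched.s_xj[0, 0] == 1.0  # both nymphs at age 0
    assert sched.l_x[0] == 1.0
    assert sched.l_x[1] == 0.5


def test_build_schedule_half_survival_at_age_two():
    recs = [
        _individual("a", ["nymph", "nymph"], [0, 0]),
        _individual("b", ["nymph", "nymph"], [0, 0]),
        _individual("c", ["nymph", "nymph", "adult", "adult"], [0, 0, 1, 0]),
        _individual("d", ["nymph", "nymph", "adult"], [0, 0, 2]),
    ]
    sched = build_schedule(recs)
    assert sched.l_x[2] == 0.5


def test_build_schedule_matches_hand_tally():
    """Three individuals with staggered adult molts vs a spreadsheet tally."""
    recs = [
        _individual("a", ["nymph", "adult", "adult"], [0, 2, 1]),
        _individual("b", ["nymph", "nymph", "adult"], [0, 0, 3]),
        _individual("c", ["nymph"], [0]),
    ]
    sched = build_schedule(recs)
    # age 1: a adult, b nymph, c dead
    assert sched.s_xj[1].tolist() == [1 / 3, 1 / 3]  # (nymph, adult)
    # f at age 1: adults laid 2 over 1 adult
    assert sched.f_xj[1, 1] == 2.0
    # m_x by hand: age1 total offspring 2 over 2/3 alive
    assert sched.m_x[1] == pytest.approx((2 / 3) / (2 / 3) * 1.0)  # = 2 * (1/3) / (2/3)
    assert sched.net_fecundity.tolist() == pytest.approx([0.0, 2 / 3, 4 / 3])
    assert net_reproductive_rate(sched) == pytest.approx(2.0)  # 6 offspring / 3


def test_empty_cohort_rejected():
    with pytest.raises(LifeTableError):
        build_schedule([])


# ---------------------------------------------------------------------------
# growth parameters


def test_r0_hand_sum():
    sched = _schedule([(1.0, 1.0), (0.5, 2.0)])
    assert net_reproductive_rate(sched) == pytest.approx(2.0)


def test_r0_zero_when_no_reproduction():
    sched = _schedule([(1.0, 0.0), (0.5, 0.0)])
    assert net_reproductive_rate(sched) == 0.0
    with pytest.raises(NoReproductionError):
        intrinsic_rate(sched)
    with pytest.raises(NoReproductionError):
        mean_generation_time(0.0, 0.1)


def test_intrinsic_rate_replacement_reproduction():
    # one offspring at age 0: exp(-r) = 1 -> r = 0
    sched = _schedule([(1.0, 1.0)])
    assert intrinsic_rate(sched) == pytest.approx(0.0, abs=1e-9)
    assert finite_rate(sched) == pytest.approx(1.0, abs=1e-9)


def test_intrinsic_rate_closed_form():
    # 2 offspring at age 1: 2 exp(-2r) = 1 -> r = ln(2)/2
    sched = _schedule([(1.0, 0.0), (1.0, 2.0)])
    assert intrinsic_rate(sched) == pytest.approx(math.log(2) / 2, abs=1e-9)
    assert finite_rate(sched) == pytest.approx(math.sqrt(2), abs=1e-9)


def test_generation_time_closed_forms():
    assert mean_generation_time(math.e, 1.0) == pytest.approx(1.0)
    assert mean_generation_time(20.0, 0.3) == pytest.approx(math.log(20.0) / 0.3)
    assert mean_generation_time(2.0, math.log(2) / 2) == pytest.approx(2.0)


def test_sign_of_r_follows_r0_on_random_schedules():
    rng = np.random.default_rng(99)
    for _ in range(50):
        ages = rng.integers(3, 12)
        l = np.minimum.accumulate(rng.uniform(0.2, 1.0, ages))
        l[0] = 1.0
        m = rng.uniform(0, 1.2, ages) * (rng.random(ages) < 0.7)
        if (l * m).sum() <= 0 or abs(np.log((l * m).sum())) < 1e-3:
            continue
        sched = _schedule(list(zip(l, m)))
        r = intrinsic_rate(sched)
        assert np.sign(r) == np.sign(np.log(net_reproductive_rate(sched)))


def test_scaling_offspring_increases_r():
    rng = np.random.default_rng(5)
    l = np.minimum.accumulate(rng.uniform(0.3, 1.0, 8))
    l[0] = 1.0
    m = rng.uniform(0.1, 2.0, 8)
    base = intrinsic_rate(_schedule(list(zip(l, m))))
    for c in (1.5, 2.0, 4.0):
        scaled = intrinsic_rate(_schedule(list(zip(l, c * m))))
        assert scaled > base
        base = scaled


def test_two_solvers_agree_on_simulated_cohort(control_cohort):
    sched = build_schedule(control_cohort)
    r = intrinsic_rate(sched)
    lam = finite_rate(sched)
    assert abs(lam - math.exp(r)) < 1e-9


def test_r0_identity_on_simulated_cohort(control_cohort):
    sched = build_schedule(control_cohort)
    total = sum(sum(rec.offspring) for rec in control_cohort)
    assert abs(net_reproductive_rate(sched) - total / len(control_cohort)) < 1e-12


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_deterministic_and_consistent(control_cohort):
    small = control_cohort[:60]
    p1 = bootstrap_lifetable(small, B=200, seed=4)
    p2 = bootstrap_lifetable(small, B=200, seed=4)
    assert p1 == p2
    assert p1.se_r > 0 and p1.se_R0 > 0
    assert p1.lam == pytest.approx(math.exp(p1.r), abs=1e-9)
    assert p1.T * p1.r == pytest.approx(math.log(p1.R0), abs=1e-8)


def test_bootstrap_identical_individuals_zero_se():
    rec = _individual("a", ["nymph", "adult", "adult"], [0, 3, 2])
    cohort = [_individual(f"a{i}", rec.stages, rec.offspring) for i in range(20)]
    p = bootstrap_lifetable(cohort, B=100, seed=1)
    # no resampling variance beyond root-solver noise
    assert p.se_r < 1e-12 and p.se_lambda < 1e-12 and p.se_R0 == 0.0 and p.se_T < 1e-12


def test_bootstrap_rejects_sterile_cohort():
    cohort = [_individual(f"a{i}", ["nymph", "adult"], [0, 0]) for i in range(5)]
    with pytest.raises(NoReproductionError):
        bootstrap_lifetable(cohort, B=10, seed=0)


# ---------------------------------------------------------------------------
# cohort summaries


def test_cohort_summary_by_definition():
    rec = _individual("a", ["nymph", "nymph", "adult", "adult", "adult", "adult", "adult"],
                      [0, 0, 0, 0, 3, 0, 2])
    summary = cohort_summary([rec])
    row = summary.loc["T"]
    assert row["reproductive_days_mean"] == 2
    assert row["fecundity_mean"] == 5
    assert row["nymph_period_mean"] == 2
    assert row["adult_longevity_mean"] == 5


def test_cohort_summary_no_adults_flagged():
    recs = [_individual(f"a{i}", ["nymph", "nymph"], [0, 0]) for i in range(4)]
    summary = cohort_summary(recs)
    row = summary.loc["T"]
    assert row["n_adult"] == 0
    assert np.isnan(row["adult_longevity_mean"])
    assert np.isnan(row["fecundity_mean"])


def test_cohort_summary_recovers_calibration(control):
    records = gen_cohort(control, n=10_000, seed=21)
    row = cohort_summary(records).loc["Control"]
    assert row["nymph_period_mean"] == pytest.approx(control.nymph_mean, rel=0.02)
    assert row["adult_longevity_mean"] == pytest.approx(control.adult_longevity_mean, rel=0.02)
    assert row["reproductive_days_mean"] == pytest.approx(control.repro_days_mean, rel=0.02)
    assert row["fecundity_mean"] == pytest.approx(control.fecundity_mean, rel=0.02)
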