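"""Cohort statistics against hand-computed textbook oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from depotflow import cohort, synth
from depotflow.cohort import (
    AnimalRecord,
    DoseSpec,
    EventTable,
    SurvivalRecord,
    anova_tukey,
    chisq_2x2,
    dose_to_volume,
    grubbs_test,
    km_curve,
    logrank_test,
    time_to_threshold,
    tumor_volume,
)
from depotflow.errors import InvalidArgumentError


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("w,l,expected", [(10, 10, 500), (5, 8, 100)])
def test_tumor_volume_formula(w, l, expected):
    assert tumor_volume(w, l) == pytest.approx(expected)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(w=st.floats(1, 20), l=st.floats(1, 20), dw=st.floats(0.1, 5), dl=st.floats(0.1, 5))
def test_tumor_volume_monotone(w, l, dw, dl):
    assert tumor_volume(w + dw, l) > tumor_volume(w, l)
    assert tumor_volume(w, l + dl) > tumor_volume(w, l)


@pytest.mark.parametrize(
    "dose,mass,expected", [(6, 25, 150), (2, 25, 50), (0, 30, 0)]
)
def test_dose_to_volume(dose, mass, expected):
    assert dose_to_volume(DoseSpec(dose, mass)) == pytest.approx(expected)


def test_dose_spec_validation():
    with pytest.raises(InvalidArgumentError):
        DoseSpec(-1, 25)
    with pytest.raises(InvalidArgumentError):
        DoseSpec(6, 0)


# ---------------------------------------------------------------------------
# surrogate survival
# ---------------------------------------------------------------------------


def _record(days_vols, **kw):
    # build (day, W, L) with W = L from the target volume: V = W^3 / 2
    meas = [(d, (2 * v) ** (1 / 3), (2 * v) ** (1 / 3)) for d, v in days_vols]
    return AnimalRecord(animal_id="a", arm="x", measurements=meas, **kw)


def test_threshold_crossing_interpolates_linearly():
    r = _record([(10, 1000.0), (12, 2000.0)])
    s = time_to_threshold(r, threshold=1500.0)
    assert s.event_observed
    assert s.time == pytest.approx(11.0, abs=1e-9)


def test_censoring_and_boundary_conventions():
    never = _record([(0, 100.0), (35, 1200.0)])
    s = time_to_threshold(never, threshold=1500.0)
    assert not s.event_observed and s.time == 35.0
    already = _record([(3, 1600.0), (5, 1800.0)])
    s2 = time_to_threshold(already, threshold=1500.0)
    assert s2.event_observed and s2.time == 3.0


def test_death_censors_by_default_and_events_on_flag():
    r = _record([(0, 100.0), (10, 800.0), (20, 3000.0)], death_day=12.0)
    s = time_to_threshold(r, threshold=1500.0)
    assert not s.event_observed and s.time == 12.0
    s2 = time_to_threshold(r, threshold=1500.0, death_is_event=True)
    assert s2.event_observed and s2.time == 12.0


def test_redundant_measurements_do_not_move_the_crossing():
    r1 = _record([(10, 1000.0), (12, 2000.0)])
    r2 = _record([(10, 1000.0), (11, 1500.0), (12, 2000.0)])
    t1 = time_to_threshold(r1, threshold=1500.0).time
    t2 = time_to_threshold(r2, threshold=1500.0).time
    assert t1 == pytest.approx(t2, abs=1e-9)


def test_width_length_swap_is_transparent():
    a = AnimalRecord("a", "x", [(0, 8.0, 5.0)])
    assert a.measurements[0][1] <= a.measurements[0][2]
    assert tumor_volume(*a.measurements[0][1:]) == pytest.approx(100.0)


def test_km_hand_product_limit():
    """Five-record mixed example against a hand-computed product-limit table:
    events at 2, 4, 5; censoring at 3 and 5."""
    recs = [
        SurvivalRecord(2, True), SurvivalRecord(3, False), SurvivalRecord(4, True),
        SurvivalRecord(5, True), SurvivalRecord(5, False),
    ]
    km = km_curve(recs)
    surv = dict(zip(km["time"], km["survival"]))
    assert surv[2.0] == pytest.approx(0.8, abs=1e-12)          # 1 * 4/5
    assert surv[4.0] == pytest.approx(0.8 * 2 / 3, abs=1e-12)  # one at risk dropped by censor
    assert surv[5.0] == pytest.approx(0.8 * 2 / 3 * 0.5, abs=1e-12)


def test_km_no_censoring_equals_empirical_survival():
    times = [2.0, 4.0, 7.0, 9.0]
    recs = [SurvivalRecord(t, True) for t in times]
    km = km_curve(recs)
    surv = dict(zip(km["time"], km["survival"]))
    for i, t in enumerate(times):
        assert surv[t] == pytest.approx(1 - (i + 1) / 4, abs=1e-12)


def test_km_all_censored_stays_at_one():
    recs = [SurvivalRecord(t, False) for t in (3.0, 6.0, 9.0)]
    km = km_curve(recs)
    assert np.all(km["survival"].to_numpy() == 1.0)


def _logrank_oracle(g1, g2):
    """Textbook two-group log-rank: sum of (O - E) over risk sets."""
    all_events = sorted({r.time for r in g1 + g2 if r.event_observed})
    o_minus_e = 0.0
    var = 0.0
    for t in all_events:
        n1 = sum(r.time >= t for r in g1)
        n2 = sum(r.time >= t for r in g2)
        d1 = sum(r.time == t and r.event_observed for r in g1)
        d2 = sum(r.time == t and r.event_observed for r in g2)
        n, d = n1 + n2, d1 + d2
        if n == 0:
            continue
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    stat = o_minus_e**2 / var
    return stat, stats.chi2.sf(stat, df=1)


def test_logrank_matches_hand_oracle_to_1e10():
    g1 = [SurvivalRecord(t, e) for t, e in [(2, True), (5, True), (7, False), (9, True)]]
    g2 = [SurvivalRecord(t, e) for t, e in [(3, True), (4, True), (6, True), (8, False), (10, True)]]
    stat, p = logrank_test(g1, g2)
    stat_o, p_o = _logrank_oracle(g1, g2)
    assert stat == pytest.approx(stat_o, abs=1e-10)
    assert p == pytest.approx(p_o, abs=1e-10)


def test_logrank_identical_groups_is_null():
    g = [SurvivalRecord(t, True) for t in (2.0, 4.0, 6.0)]
    stat, p = logrank_test(g, list(g))
    assert stat == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0, abs=1e-10)


def test_logrank_separated_synthetic_cohorts_reject():
    df = synth.gen_cohort(
        {"ctrl": 10, "treat": 10},
        growth_rates={"ctrl": 0.16, "treat": 0.06},
        meas_noise_cv=0.1,
        seed=11,
    )
    recs = cohort.records_from_frame(df)
    groups = {
        arm: [time_to_threshold(r, max_day=35) for r in recs if r.arm == arm]
        for arm in ("ctrl", "treat")
    }
    stat, p = logrank_test(groups["ctrl"], groups["treat"])
    assert p < 0.05


# ---------------------------------------------------------------------------
# chi-squared / ANOVA / Grubbs
# ---------------------------------------------------------------------------


def _chisq_oracle(table):
    t = table.as_2x2()
    e = np.outer(t.sum(1), t.sum(0)) / t.sum()
    stat = ((t - e) ** 2 / e).sum()
    return stat, stats.chi2.sf(stat, df=1)


def test_chisq_balanced_table_is_null():
    t = EventTable(("a", "b"), (10, 10), (20, 20))
    stat, p = chisq_2x2(t)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_chisq_fully_separated_table():
    t = EventTable(("a", "b"), (20, 0), (20, 20))
    stat, _ = chisq_2x2(t)
    assert stat == pytest.approx(40.0, abs=1e-10)  # sum (O-E)^2/E with E = 10


@pytest.mark.parametrize("events,totals", [((3, 9), (12, 15)), ((1, 7), (10, 8))])
def test_chisq_matches_formula_oracle(events, totals):
    t = EventTable(("a", "b"), events, totals)
    stat, p = chisq_2x2(t)
    stat_o, p_o = _chisq_oracle(t)
    assert stat == pytest.approx(stat_o, abs=1e-10)
    assert p == pytest.approx(p_o, abs=1e-10)


def test_chisq_rejects_zero_margin():
    t = EventTable(("a", "b"), (0, 0), (10, 10))
    with pytest.raises(InvalidArgumentError):
        chisq_2x2(t)


def test_welch_anova_two_groups_equals_welch_t():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 12)
    b = rng.normal(1, 2, 9)
    res = anova_tukey({"a": a, "b": b}, welch=True)
    t_p = stats.ttest_ind(a, b, equal_var=False).pvalue
    assert res.p_overall == pytest.approx(t_p, rel=1e-8)


def test_tukey_flags_only_the_shifted_pair():
    rng = np.random.default_rng(5)
    groups = {
        "a": rng.normal(0, 1, 60),
        "b": rng.normal(0, 1, 60),
        "c": rng.normal(1.5, 1, 60),
    }
    res = anova_tukey(groups)
    assert res.p_overall < 0.05
    pw = res.pairwise.set_index(["group1", "group2"])["p_adj"]
    assert pw.loc[("a", "b")] > 0.05
    assert pw.loc[("a", "c")] < 0.05
    assert pw.loc[("b", "c")] < 0.05


def test_anova_degenerate_constant_groups_flagged():
    res = anova_tukey({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0]})
    assert res.degenerate
    assert res.p_overall == 1.0


def test_grubbs_flags_gross_outlier_and_not_clean_data():
    clean = grubbs_test([1.0, 2.0, 3.0])
    assert not clean.is_outlier
    dirty = grubbs_test([1.0, 1.1, 0.9, 50.0])
    assert dirty.is_outlier and dirty.index == 3
    # statistic vs the tabulated n=4, alpha=0.05 two-sided critical value 1.481
    assert dirty.statistic > 1.481
    flat = grubbs_test([2.0, 2.0, 2.0, 2.0])
    assert flat.degenerate and not flat.is_outlier
    with pytest.raises(InvalidArgumentError):
        grubbs_test([1.0, 2.0])


def test_mean_growth_curve_drops_deceased():
    recs = [
        _record([(0, 100.0), (7, 200.0), (14, 400.0)]),
        _record([(0, 100.0), (7, 300.0), (14, 900.0)], death_day=8.0),
    ]
    df = cohort.mean_growth_curve(recs)
    at14 = df[df["day"] == 14.0]
    assert int(at14["count"].iloc[0]) == 1
    assert at14["mean"].iloc[0] == pytest.approx(400.0, rel=1e-9)
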