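"""Cohort-level preclinical statistics.

Caliper tumor volumes ``V = W^2 * L / 2``, dose arithmetic (mL/kg to uL),
time-to-1500-mm^3 surrogate survival, Kaplan-Meier / log-rank, adverse-event
chi-squared (df = 1), Welch ANOVA with Tukey HSD post-hoc comparisons, and
Grubbs outlier screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.oneway import anova_oneway

from .errors import DegenerateTestError, InvalidArgumentError

log = logging.getLogger(__name__)

SURVIVAL_SURROGATE_MM3 = 1500.0  # surrogate-survival threshold
EUTHANASIA_MM3 = 2000.0          # humane tumor-burden limit


# ---------------------------------------------------------------------------
# records and arithmetic
# ---------------------------------------------------------------------------


@dataclass
class AnimalRecord:
    """Longitudinal caliper measurements for one animal.

    ``measurements`` is a list of ``(day, width_mm, length_mm)``; width and
    length are swapped (with a logged note) if given in the wrong order, so
    W <= L always holds.
    """

    animal_id: str
    arm: str
    measurements: list
    death_day: float | None = None
    humane_endpoint_flag: bool = False

    def __post_init__(self):
        fixed = []
        last_day = -np.inf
        for day, w, l in self.measurements:
            if day < last_day:
                raise InvalidArgumentError("measurement days must be non-decreasing")
            last_day = day
            if w > l:
                log.info("animal %s day %s: width %.3g > length %.3g, swapping",
                         self.animal_id, day, w, l)
                w, l = l, w
            fixed.append((float(day), float(w), float(l)))
        self.measurements = fixed

    def volumes(self) -> tuple[np.ndarray, np.ndarray]:
        days = np.array([m[0] for m in self.measurements])
        vols = np.array([tumor_volume(m[1], m[2]) for m in self.measurements])
        return days, vols


@dataclass(frozen=True)
class SurvivalRecord:
    """Time to the surrogate event (threshold crossing) or censoring."""

    time: float
    event_observed: bool
    animal_id: str = ""
    arm: str = ""

    def __post_init__(self):
        if self.time <= 0:
            raise InvalidArgumentError("survival time must be positive")


@dataclass(frozen=True)
class EventTable:
    """Per-group (event, no-event) counts for one adverse-event category."""

    groups: tuple
    events: tuple
    totals: tuple

    def __post_init__(self):
        if len(self.groups) != len(self.events) or len(self.groups) != len(self.totals):
            raise InvalidArgumentError("groups, events and totals must align")
        for e, n in zip(self.events, self.totals):
            if not (0 <= e <= n) or int(e) != e or int(n) != n:
                raise InvalidArgumentError("counts must be non-negative integers with e <= n")
            if n <= 0:
                raise InvalidArgumentError("group totals must be positive")

    def as_2x2(self) -> np.ndarray:
        if len(self.groups) != 2:
            raise InvalidArgumentError("a 2x2 table needs exactly 2 groups")
        return np.array(
            [[self.events[0], self.totals[0] - self.events[0]],
             [self.events[1], self.totals[1] - self.events[1]]],
            dtype=float,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.groups, "event": self.events,
             "no_event": [n - e for e, n in zip(self.events, self.totals)]}
        )


@dataclass(frozen=True)
class DoseSpec:
    """An injection dose quoted per body mass."""

    dose_ml_per_kg: float
    body_mass_g: float

    def __post_init__(self):
        if self.dose_ml_per_kg < 0:
            raise InvalidArgumentError("dose must be non-negative")
        if self.body_mass_g <= 0:
            raise InvalidArgumentError("body mass must be positive")


def tumor_volume(width_mm: float, length_mm: float) -> float:
    """Caliper tumor volume ``V = W^2 * L / 2`` (mm^3)."""
    if width_mm <= 0 or length_mm <= 0:
        raise InvalidArgumentError("caliper dimensions must be positive")
    return float(width_mm**2 * length_mm / 2.0)


def dose_to_volume(spec: DoseSpec) -> float:
    """Injected volume in uL: dose (mL/kg) x mass (kg) x 1000."""
    return spec.dose_ml_per_kg * (spec.body_mass_g / 1000.0) * 1000.0


# ---------------------------------------------------------------------------
# surrogate survival
# ---------------------------------------------------------------------------


def time_to_threshold(
    record: AnimalRecord,
    threshold: float = SURVIVAL_SURROGATE_MM3,
    max_day: float | None = None,
    interpolate: bool = True,
    death_is_event: bool = False,
) -> SurvivalRecord:
    """Surrogate survival time: first crossing of the volume threshold.

    The crossing day is linearly interpolated in volume between the
    bracketing measurements (``interpolate=False`` uses the first day the
    measured volume exceeds the threshold).  Animals that die before
    crossing are censored at death by default -- the humane endpoint is an
    adverse event, not a tumor event -- unless ``death_is_event``.  A first
    measurement already above threshold counts as an event on that day.
    """
    if len(record.measurements) < 2:
        raise InvalidArgumentError("need at least 2 measurements")
    days, vols = record.volumes()
    if record.death_day is not None:
        keep = days <= record.death_day
        days, vols = days[keep], vols[keep]
        if days.size == 0:
            raise InvalidArgumentError("no measurements before death")
    above = np.nonzero(vols >= threshold)[0]
    if above.size > 0:
        i = int(above[0])
        if i == 0 or not interpolate:
            t = days[i]
        else:
            frac = (threshold - vols[i - 1]) / (vols[i] - vols[i - 1])
            t = days[i - 1] + frac * (days[i] - days[i - 1])
        return SurvivalRecord(time=float(t), event_observed=True,
                              animal_id=record.animal_id, arm=record.arm)
    if record.death_day is not None:
        return SurvivalRecord(time=float(record.death_day), event_observed=death_is_event,
                              animal_id=record.animal_id, arm=record.arm)
    t_cens = float(days[-1]) if max_day is None else float(min(days[-1], max_day))
    return SurvivalRecord(time=t_cens, event_observed=False,
                          animal_id=record.animal_id, arm=record.arm)


def km_curve(records) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival curve with right censoring.

    Returns a DataFrame with columns ``time`` and ``survival`` (the step
    function evaluated at each event/censoring time, starting from S=1 at
    time 0).
    """
    records = list(records)
    if not records:
        raise InvalidArgumentError("need at least one survival record")
    kmf = KaplanMeierFitter()
    kmf.fit(
        durations=[r.time for r in records],
        event_observed=[r.event_observed for r in records],
    )
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(*groups) -> tuple[float, float]:
    """Log-rank chi-squared test across >= 2 groups (df = n_groups - 1)."""
    if len(groups) == 1 and isinstance(groups[0], dict):
        groups = tuple(groups[0].values())
    if len(groups) < 2:
        raise InvalidArgumentError("need at least two groups")
    durations, events, labels = [], [], []
    for gi, grp in enumerate(groups):
        grp = list(grp)
        if not grp:
            raise InvalidArgumentError("each group must be non-empty")
        for r in grp:
            durations.append(r.time)
            events.append(bool(r.event_observed))
            labels.append(gi)
    if not any(events):
        raise DegenerateTestError("no events observed in any group")
    res = multivariate_logrank_test(durations, labels, events)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------


def chisq_2x2(table: EventTable, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 adverse-event table, df = 1.

    No continuity correction by default; ``correction=True`` applies Yates.
    """
    t = table.as_2x2()
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise InvalidArgumentError("chi-squared needs positive table margins")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=correction)
    assert dof == 1
    return float(stat), float(p)


@dataclass(frozen=True)
class AnovaTukeyResult:
    F: float
    p_overall: float
    pairwise: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject
    welch: bool
    degenerate: bool = False


def anova_tukey(groups: dict, welch: bool = True, alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA across groups plus Tukey HSD pairwise comparisons.

    ``groups`` maps label -> 1-D sample.  The default is the Welch
    (unequal-variance) ANOVA; ``welch=False`` gives the classical equal-
    variance F test.  Tukey HSD is computed on untransformed group means
    with the studentized-range distribution.  All-constant input is
    degenerate and flagged rather than raised.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(samples) < 2:
        raise InvalidArgumentError("need at least two groups")
    for s in samples:
        if s.size < 2:
            raise InvalidArgumentError("each group needs at least two observations")
    values = np.concatenate(samples)
    if np.ptp(values) == 0:
        empty = pd.DataFrame(columns=["group1", "group2", "meandiff", "p_adj", "reject"])
        return AnovaTukeyResult(F=0.0, p_overall=1.0, pairwise=empty, welch=welch,
                                degenerate=True)
    use_var = "unequal" if welch else "equal"
    res = anova_oneway(samples, use_var=use_var, welch_correction=welch)
    tags = np.concatenate([[lab] * s.size for lab, s in zip(labels, samples)])
    tk = pairwise_tukeyhsd(values, tags, alpha=alpha)
    pairwise = pd.DataFrame(
        {
            "group1": tk.groupsunique[tk._multicomp.pairindices[0]],
            "group2": tk.groupsunique[tk._multicomp.pairindices[1]],
            "meandiff": tk.meandiffs,
            "p_adj": tk.pvalues,
            "reject": tk.reject,
        }
    )
    return AnovaTukeyResult(F=float(res.statistic), p_overall=float(res.pvalue),
                            pairwise=pairwise, welch=welch)


@dataclass(frozen=True)
class GrubbsResult:
    is_outlier: bool
    index: int | None
    statistic: float
    critical: float
    degenerate: bool = False


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided Grubbs test for a single outlier.

    ``G = max |x - mean| / sd`` compared with the critical value
    ``((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2))`` where ``t`` is the
    upper ``alpha/(2n)`` Student-t quantile with ``n - 2`` df.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise InvalidArgumentError("Grubbs test needs a 1-D sample with n >= 3")
    s = x.std(ddof=1)
    n = x.size
    tcrit = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    gcrit = (n - 1) / np.sqrt(n) * np.sqrt(tcrit**2 / (n - 2 + tcrit**2))
    if s == 0:
        return GrubbsResult(False, None, 0.0, float(gcrit), degenerate=True)
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = float(dev[i] / s)
    out = g > gcrit
    return GrubbsResult(bool(out), i if out else None, g, float(gcrit))


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------


def records_from_frame(df: pd.DataFrame) -> list[AnimalRecord]:
    """Build AnimalRecords from a long cohort table.

    Expected columns: ``animal_id, arm, day, width_mm, length_mm`` and
    optionally ``dead_flag`` (death recorded on the flagged day).
    """
    records = []
    for (aid, arm), grp in df.groupby(["animal_id", "arm"], sort=True):
        grp = grp.sort_values("day")
        meas = list(zip(grp["day"], grp["width_mm"], grp["length_mm"]))
        death = None
        if "dead_flag" in grp and grp["dead_flag"].any():
            death = float(grp.loc[grp["dead_flag"].astype(bool), "day"].iloc[0])
        records.append(AnimalRecord(animal_id=str(aid), arm=str(arm),
                                    measurements=meas, death_day=death))
    return records


def mean_growth_curve(records, drop_after_death: bool = True) -> pd.DataFrame:
    """Arm-level mean tumor volume by day.

    Deceased animals stop contributing after their death day (the group
    average excludes deceased mice), unless ``drop_after_death=False``.
    """
    rows = []
    for r in records:
        days, vols = r.volumes()
        for d, v in zip(days, vols):
            if drop_after_death and r.death_day is not None and d > r.death_day:
                continue
            rows.append({"arm": r.arm, "day": d, "volume_mm3": v})
    df = pd.DataFrame(rows)
    return df.groupby(["arm", "day"], as_index=False)["volume_mm3"].agg(["mean", "count"])
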