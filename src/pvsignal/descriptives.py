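"""Descriptive profile of the case/exposure group.

Produces the categorical breakdown of a report cohort (age bands, gender,
tracked medical history, exposure-drug distribution, reporter
qualification, EU vs non-EU origin) with explicit "unspecified" buckets,
and the three clinical interval statistics: latency (first drug
administration to event onset), onset-to-withdrawal, and
withdrawal-to-resolution.

Intervals are computed only for reports where both endpoints are known to
at least month precision (a missing day is imputed as the 15th); negative
intervals are excluded from the statistics and counted separately as a
data-quality flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, median, stdev

from .cohort import ClassifiedReport
from .model import GLIPTINS, PartialDate, Role, StudyDesign

__all__ = [
    "CohortSummary",
    "IntervalStats",
    "TRACKED_CONDITIONS",
    "summarize_cohort",
    "compute_intervals",
    "withdrawal_timing_bands",
    "DAYS_PER_MONTH",
]

DAYS_PER_MONTH = 30.4375  # mean Gregorian month

AGE_BANDS = ("<65", "65-85", ">85", "unspecified")

# Tracked history conditions with literal synonyms (case-insensitive).
TRACKED_CONDITIONS: dict[str, frozenset[str]] = {
    "T2DM": frozenset(
        {"t2dm", "type 2 diabetes mellitus", "type ii diabetes mellitus",
         "diabetes mellitus type 2"}
    ),
    "stroke": frozenset({"stroke", "cerebrovascular accident"}),
    "dementia": frozenset({"dementia"}),
    "Parkinson": frozenset({"parkinson", "parkinson's disease", "parkinson disease"}),
    "epilepsy": frozenset({"epilepsy"}),
    "multiple sclerosis": frozenset({"multiple sclerosis"}),
}


def _round1(x: float) -> float:
    import decimal

    return float(
        decimal.Decimal(repr(x)).quantize(
            decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class CohortSummary:
    """Categorical counts over one report group, percentages on demand.

    Percentages use the full group size as denominator, including the
    unspecified rows, rounded half-away-from-zero to one decimal.
    """

    group_size: int
    age_bands: dict[str, int]
    gender: dict[str, int]
    history: dict[str, int]
    drug_distribution: dict[str, int]
    reporter: dict[str, int]
    eu_split: dict[str, int]

    def percentage(self, count: int) -> float:
        if self.group_size == 0:
            return 0.0
        return _round1(100.0 * count / self.group_size)

    def percentages(self) -> dict[str, dict[str, float]]:
        return {
            var: {level: self.percentage(n) for level, n in table.items()}
            for var, table in {
                "age_bands": self.age_bands,
                "gender": self.gender,
                "history": self.history,
                "drug_distribution": self.drug_distribution,
                "reporter": self.reporter,
                "eu_split": self.eu_split,
            }.items()
        }

    def to_frame(self):
        """Long-format table: variable, level, count, percentage."""
        import pandas as pd

        rows = []
        for var, table in [
            ("age", self.age_bands),
            ("gender", self.gender),
            ("medical_history", self.history),
            ("drug", self.drug_distribution),
            ("reporter", self.reporter),
            ("region", self.eu_split),
        ]:
            for level, n in table.items():
                rows.append(
                    {
                        "variable": var,
                        "level": level,
                        "count": n,
                        "percentage": self.percentage(n),
                    }
                )
        return pd.DataFrame(rows)


def _age_band(age: float | None) -> str:
    if age is None:
        return "unspecified"
    if age < 65:
        return "<65"
    if age <= 85:  # "between 65 and 85" is inclusive on both ends
        return "65-85"
    return ">85"


def _history_condition_hits(cr: ClassifiedReport) -> set[str]:
    hits: set[str] = set()
    conditions = {h.condition.lower() for h in cr.report.history}
    for label, synonyms in TRACKED_CONDITIONS.items():
        if conditions & synonyms:
            hits.add(label)
    return hits


def summarize_cohort(
    case_exposed: list[ClassifiedReport],
    drug_names: tuple[str, ...] = GLIPTINS,
) -> CohortSummary:
    """Categorical profile of a (typically case-and-exposed) report group.

    ``drug_names`` are the exposure substances given their own bucket in
    the drug distribution; any other exposure drug counts as unspecified.
    An empty input yields an all-zero summary.
    """
    age_bands = {band: 0 for band in AGE_BANDS}
    gender = {"male": 0, "female": 0, "unspecified": 0}
    history = {label: 0 for label in TRACKED_CONDITIONS}
    drugs = {name: 0 for name in drug_names}
    drugs["unspecified"] = 0
    reporter = {
        "physician": 0, "other_hcp": 0, "pharmacist": 0, "consumer": 0, "unknown": 0,
    }
    eu_split = {"EU": 0, "non-EU": 0}

    for cr in case_exposed:
        r = cr.report
        age_bands[_age_band(r.age_years)] += 1
        gender[r.gender.value] += 1
        for label in _history_condition_hits(cr):
            history[label] += 1
        bucket = cr.exposure_drug if cr.exposure_drug in drugs else "unspecified"
        drugs[bucket] += 1
        reporter[r.reporter.value] += 1
        eu_split["EU" if r.eu_member else "non-EU"] += 1

    return CohortSummary(
        group_size=len(case_exposed),
        age_bands=age_bands,
        gender=gender,
        history=history,
        drug_distribution=drugs,
        reporter=reporter,
        eu_split=eu_split,
    )


@dataclass(frozen=True)
class IntervalStats:
    """Median/mean/SD of one clinical interval over its evaluable reports.

    ``n_negative`` counts reports whose endpoints were both known but in
    reverse order (excluded from the statistics).
    """

    name: str
    n_evaluable: int
    median: float
    mean: float
    sd: float
    unit: str = "days"
    n_negative: int = 0

    def in_months(self) -> "IntervalStats":
        if self.unit == "months":
            return self
        f = 1.0 / DAYS_PER_MONTH
        return IntervalStats(
            name=self.name,
            n_evaluable=self.n_evaluable,
            median=self.median * f,
            mean=self.mean * f,
            sd=self.sd * f,
            unit="months",
            n_negative=self.n_negative,
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_evaluable": self.n_evaluable,
            "median": self.median,
            "mean": self.mean,
            "sd": self.sd,
            "unit": self.unit,
            "n_negative": self.n_negative,
        }


def _month_precise(d: PartialDate | None):
    return d.to_date() if d is not None and d.has_month else None


def _endpoints(cr: ClassifiedReport, design: StudyDesign):
    """(drug start, event onset, drug end, event resolution) as dates or None."""
    r = cr.report
    term = design.event_term_norm
    gliptin_entries = [
        d
        for d in r.drugs
        if d.role is Role.suspect and d.substance in design.exposure_drugs
    ]
    starts = [x for d in gliptin_entries if (x := _month_precise(d.start))]
    ends = [x for d in gliptin_entries if (x := _month_precise(d.end))]
    event_rx = [rx for rx in r.reactions if rx.term.lower() == term]
    onsets = [x for rx in event_rx if (x := _month_precise(rx.onset))]
    resolutions = [x for rx in event_rx if (x := _month_precise(rx.resolution))]
    return (
        min(starts) if starts else None,
        min(onsets) if onsets else None,
        min(ends) if ends else None,
        min(resolutions) if resolutions else None,
    )


def _interval_days(cr: ClassifiedReport, design: StudyDesign) -> dict[str, int | None]:
    start, onset, end, resolution = _endpoints(cr, design)
    return {
        "latency": (onset - start).days if start and onset else None,
        "onset_to_withdrawal": (end - onset).days if onset and end else None,
        "withdrawal_to_resolution": (resolution - end).days
        if end and resolution
        else None,
    }


def compute_intervals(
    case_exposed: list[ClassifiedReport], design: StudyDesign
) -> list[IntervalStats]:
    """Latency, onset-to-withdrawal and withdrawal-to-resolution statistics.

    Results are in days; use :meth:`IntervalStats.in_months` for the
    months view (days / 30.4375).  Order-invariant over the input.
    """
    values: dict[str, list[int]] = {
        "latency": [],
        "onset_to_withdrawal": [],
        "withdrawal_to_resolution": [],
    }
    negatives: dict[str, int] = {k: 0 for k in values}
    for cr in case_exposed:
        for name, days in _interval_days(cr, design).items():
            if days is None:
                continue
            if days < 0:
                negatives[name] += 1
            else:
                values[name].append(days)
    out = []
    for name, xs in values.items():
        if xs:
            out.append(
                IntervalStats(
                    name=name,
                    n_evaluable=len(xs),
                    median=float(median(xs)),
                    mean=float(mean(xs)),
                    sd=float(stdev(xs)) if len(xs) > 1 else 0.0,
                    n_negative=negatives[name],
                )
            )
        else:
            out.append(
                IntervalStats(
                    name=name, n_evaluable=0, median=math.nan, mean=math.nan,
                    sd=math.nan, n_negative=negatives[name],
                )
            )
    return out


def withdrawal_timing_bands(
    case_exposed: list[ClassifiedReport], design: StudyDesign = StudyDesign()
) -> dict[str, int]:
    """How soon after event onset the exposure drug was withdrawn.

    Disjoint bands over the onset-to-withdrawal interval: the same day
    (0 days), within a month ((0, 30] days, boundary inclusive), more than
    a year (> 365 days), the remainder, plus reports where the interval is
    not evaluable.
    """
    bands = {"same_day": 0, "within_month": 0, "over_year": 0, "other": 0,
             "unevaluable": 0}
    for cr in case_exposed:
        days = _interval_days(cr, design)["onset_to_withdrawal"]
        if days is None or days < 0:
            bands["unevaluable"] += 1
        elif days == 0:
            bands["same_day"] += 1
        elif days <= 30:
            bands["within_month"] += 1
        elif days > 365:
            bands["over_year"] += 1
        else:
            bands["other"] += 1
    return bands
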