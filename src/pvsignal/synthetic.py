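"""Synthetic ICSR cohort generator.

Spontaneous-report extracts from the big pharmacovigilance databases are
not redistributable, so every stage of the pipeline is exercised on
generated cohorts with the same statistical structure: per-drug exposure
frequencies, a rare baseline event rate, per-drug target reporting odds
ratios, realistic missingness in age/gender/country, a reporter-
qualification mix dominated by physicians, a right-skewed (lognormal)
latency distribution, and injected contaminants (duplicates, multi-drug
exposures, confounder co-medication, prior event history) that give the
cohort-building exclusions work to do.

The event indicator is drawn by *odds* multiplication: a report exposed to
drug D is a case with odds = baseline_odds * target_ror[D] (times the
confounder odds multiplier when a confounder drug is co-reported).  With
everything else at odds ratio 1, the generating parameter is exactly the
reporting odds ratio the analysis estimates, so parameter recovery is
unbiased in expectation.

:func:`generate_frame` produces the cohort as a flat pandas DataFrame
(vectorized, fast, with full bookkeeping columns for oracle tests);
:func:`generate_cohort` materializes the same cohort as
:class:`~pvsignal.model.ICSRReport` objects.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MarginRecord, MarginTable
from .model import (
    BP_ASSOCIATED_DRUGS,
    DrugEntry,
    Gender,
    GLIPTINS,
    ICSRReport,
    MedicalHistoryEntry,
    PartialDate,
    ReactionEntry,
    Reporter,
    Role,
)

__all__ = ["GeneratorConfig", "generate_frame", "generate_cohort",
           "generate_margins_fixture", "TABLE1_MARGINS"]

# Reports mentioning each drug per database report (drug_total/grand_total
# of the published margins), the exposure frequencies the generator
# emulates by default.
_DEFAULT_EXPOSURE = {
    "vildagliptin": 2722 / 11_451_738,
    "sitagliptin": 19_464 / 11_451_738,
    "linagliptin": 3525 / 11_451_738,
    "alogliptin": 554 / 11_451_738,
    "saxagliptin": 885 / 11_451_738,
    "teneligliptin": 46 / 11_451_738,
    "furosemide": 5e-3,
    "paracetamol": 1e-2,
}

# Published per-drug reporting odds ratios the generator targets by default.
_DEFAULT_TARGET_ROR = {
    "vildagliptin": 692.9,
    "sitagliptin": 37.7,
    "linagliptin": 279.7,
    "alogliptin": 144.4,
    "saxagliptin": 66.8,
    "teneligliptin": 394.5,
    "furosemide": 11.3,
    "paracetamol": 0.5,
}

_BACKGROUND_DRUGS = (
    "amoxicillin", "atorvastatin", "omeprazole", "ramipril", "simvastatin",
    "levothyroxine", "warfarin", "amlodipine", "bisoprolol", "sertraline",
)

_OTHER_REACTIONS = (
    "Nausea", "Headache", "Rash", "Dizziness", "Diarrhoea", "Fatigue",
    "Pruritus", "Vomiting", "Hepatotoxicity", "Anaphylactic reaction",
)

_COUNTRY_MIX = {
    "JP": 0.35, "US": 0.20, "DE": 0.10, "FR": 0.09, "ES": 0.08,
    "IT": 0.07, "GB": 0.06, "NL": 0.05,
}


def _lognormal_params(median_months: float = 11.0, mean_months: float = 19.0):
    """(mu, sigma) of a lognormal latency in days with the given median/mean."""
    mu = math.log(median_months * 30.4375)
    sigma = math.sqrt(2.0 * math.log(mean_months / median_months))
    return mu, sigma


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the real database: exposure frequencies and target
    reporting odds ratios from the published margins, a baseline event
    probability of 5215/11,451,738, missingness of 31% (age), 7.3%
    (gender) and 5% (country), a 64%-physician reporter mix, and a
    lognormal latency with median 11 months and mean 19 months.
    Contaminant probabilities inject the report types the eligibility
    exclusions are designed to remove.
    """

    n_reports: int = 20_000
    seed: int = 0
    drug_exposure_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EXPOSURE)
    )
    baseline_event_prob: float = 5215 / 11_451_738
    target_ror: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TARGET_ROR)
    )
    missingness: dict[str, float] = field(
        default_factory=lambda: {"age": 0.31, "gender": 0.073, "country": 0.05}
    )
    reporter_mix: dict[str, float] = field(
        default_factory=lambda: {
            "physician": 0.64, "other_hcp": 0.21, "pharmacist": 0.05,
            "consumer": 0.05, "unknown": 0.05,
        }
    )
    country_mix: dict[str, float] = field(default_factory=lambda: dict(_COUNTRY_MIX))
    gender_male_frac: float = 0.632  # male share among reports with known gender
    age_mean: float = 77.0
    age_sd: float = 10.6
    latency_lognormal: tuple[float, float] = field(
        default_factory=_lognormal_params
    )
    withdrawal_median_days: float = 36.0
    same_day_withdrawal_prob: float = 0.118  # point mass: drug stopped at diagnosis
    resolution_median_days: float = 33.0
    confounder_contamination: float = 0.05
    confounder_or: float = 10.0
    confounder_drugs: tuple[str, ...] = BP_ASSOCIATED_DRUGS
    t2dm_given_gliptin: float = 0.304
    multi_gliptin_prob: float = 0.01
    antihyperglycemic_combo_prob: float = 0.05
    prior_bp_history_prob: float = 0.002
    duplicate_prob: float = 0.005
    start_day_missing: float = 0.25
    start_month_missing: float = 0.05

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        for name, p in [
            ("baseline_event_prob", self.baseline_event_prob),
            ("confounder_contamination", self.confounder_contamination),
            ("multi_gliptin_prob", self.multi_gliptin_prob),
            ("antihyperglycemic_combo_prob", self.antihyperglycemic_combo_prob),
            ("prior_bp_history_prob", self.prior_bp_history_prob),
            ("duplicate_prob", self.duplicate_prob),
            ("same_day_withdrawal_prob", self.same_day_withdrawal_prob),
            *self.missingness.items(),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {name} out of [0,1]: {p}")
        s = sum(self.drug_exposure_probs.values())
        if s > 1.0 + 1e-12 or any(p < 0 for p in self.drug_exposure_probs.values()):
            raise ValueError("drug exposure probabilities invalid or exceed 1")
        for mix_name, mix in [("reporter_mix", self.reporter_mix),
                              ("country_mix", self.country_mix)]:
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{mix_name} must sum to 1")
        if any(r < 0 for r in self.target_ror.values()):
            raise ValueError("target RORs must be nonnegative")


_WINDOW_START = datetime.date(2008, 1, 1).toordinal()
_WINDOW_END = datetime.date(2022, 12, 31).toordinal()


def generate_frame(cfg: GeneratorConfig) -> pd.DataFrame:
    """Generate the cohort as a flat DataFrame with bookkeeping columns.

    One row per report (duplicate injections appear as extra rows sharing
    a registration id, flagged ``is_duplicate``).  Bookkeeping columns
    (``is_case``, ``primary_drug``, ``is_gliptin``, ``confounder``, ...)
    let tests compare pipeline output against the generating process.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports

    drugs = list(cfg.drug_exposure_probs)
    probs = np.array([cfg.drug_exposure_probs[d] for d in drugs])
    p_bg = 1.0 - probs.sum()
    choice = rng.choice(len(drugs) + 1, size=n, p=np.append(probs, p_bg))
    bg_pick = rng.choice(len(_BACKGROUND_DRUGS), size=n)
    primary = np.where(
        choice < len(drugs),
        np.array(drugs + ["?"], dtype=object)[choice],
        np.array(_BACKGROUND_DRUGS, dtype=object)[bg_pick],
    ).astype(object)
    is_gliptin = np.isin(primary.astype(str), GLIPTINS)

    ror = np.array(
        [cfg.target_ror.get(d, 1.0) for d in primary], dtype=float
    )
    confounded = rng.random(n) < cfg.confounder_contamination
    conf_pick = rng.choice(len(cfg.confounder_drugs), size=n)
    confounder = np.where(
        confounded, np.array(cfg.confounder_drugs, dtype=object)[conf_pick], ""
    ).astype(object)

    p0 = cfg.baseline_event_prob
    odds = (p0 / (1.0 - p0)) * ror * np.where(confounded, cfg.confounder_or, 1.0)
    is_case = rng.random(n) < odds / (1.0 + odds)

    # contaminants the exclusions are meant to catch
    second = np.full(n, "", dtype=object)
    multi = is_gliptin & (rng.random(n) < cfg.multi_gliptin_prob)
    others = rng.choice(len(GLIPTINS), size=n)
    for i in np.nonzero(multi)[0]:
        alt = GLIPTINS[others[i]]
        second[i] = alt if alt != primary[i] else GLIPTINS[(others[i] + 1) % len(GLIPTINS)]
    combo = is_gliptin & (rng.random(n) < cfg.antihyperglycemic_combo_prob)
    prior_bp = rng.random(n) < cfg.prior_bp_history_prob

    # demographics
    age = rng.normal(cfg.age_mean, cfg.age_sd, size=n).clip(18, 105)
    age = np.where(rng.random(n) < cfg.missingness["age"], np.nan, np.round(age))
    male = rng.random(n) < cfg.gender_male_frac
    gender = np.where(male, "male", "female").astype(object)
    gender[rng.random(n) < cfg.missingness["gender"]] = "unspecified"
    countries = list(cfg.country_mix)
    country = np.array(countries, dtype=object)[
        rng.choice(len(countries), size=n, p=np.array(list(cfg.country_mix.values())))
    ]
    country[rng.random(n) < cfg.missingness["country"]] = "unknown"
    reporters = list(cfg.reporter_mix)
    reporter = np.array(reporters, dtype=object)[
        rng.choice(len(reporters), size=n, p=np.array(list(cfg.reporter_mix.values())))
    ]

    # dates (ordinals); latency applies to cases, a short delay otherwise
    start = rng.integers(_WINDOW_START, _WINDOW_END - 400, size=n)
    mu, sigma = cfg.latency_lognormal
    latency = np.where(
        is_case,
        rng.lognormal(mu, sigma, size=n),
        rng.exponential(90.0, size=n),
    ).astype(int) + 1
    onset = start + latency
    ln2 = math.log(2.0)
    withdraw_delay = rng.exponential(cfg.withdrawal_median_days / ln2, size=n).astype(int)
    withdraw_delay[rng.random(n) < cfg.same_day_withdrawal_prob] = 0
    withdraw = onset + withdraw_delay
    resolve = withdraw + rng.exponential(cfg.resolution_median_days / ln2, size=n).astype(int) + 1
    receipt = onset + rng.integers(7, 90, size=n)
    start_day_miss = rng.random(n) < cfg.start_day_missing
    start_month_miss = rng.random(n) < cfg.start_month_missing

    # medical history
    t2dm_p = np.where(is_gliptin, cfg.t2dm_given_gliptin, 0.05)
    t2dm = rng.random(n) < t2dm_p
    stroke = rng.random(n) < np.where(is_gliptin, 0.062, 0.01)
    dementia = rng.random(n) < 0.005
    parkinson = rng.random(n) < 0.005
    epilepsy = rng.random(n) < 0.003

    reaction = np.where(
        is_case, "Pemphigoid",
        np.array(_OTHER_REACTIONS, dtype=object)[
            rng.choice(len(_OTHER_REACTIONS), size=n)
        ],
    ).astype(object)

    rid = np.array([f"R{cfg.seed:05d}-{i:07d}" for i in range(n)], dtype=object)

    frame = pd.DataFrame(
        {
            "registration_id": rid,
            "primary_drug": primary,
            "is_gliptin": is_gliptin,
            "second_gliptin": second,
            "combo_antihyperglycemic": combo,
            "confounder": confounder,
            "is_case": is_case,
            "reaction_term": reaction,
            "age_years": age,
            "gender": gender,
            "country": country,
            "reporter": reporter,
            "start_ord": start,
            "onset_ord": onset,
            "withdraw_ord": withdraw,
            "resolve_ord": resolve,
            "receipt_ord": receipt,
            "start_day_missing": start_day_miss,
            "start_month_missing": start_month_miss,
            "t2dm": t2dm,
            "stroke": stroke,
            "dementia": dementia,
            "parkinson": parkinson,
            "epilepsy": epilepsy,
            "prior_bp_history": prior_bp,
            "is_duplicate": np.zeros(n, dtype=bool),
        }
    )

    dup = rng.random(n) < cfg.duplicate_prob
    if dup.any():
        copies = frame.loc[dup].copy()
        copies["receipt_ord"] = copies["receipt_ord"] + 30
        copies["is_duplicate"] = True
        frame = pd.concat([frame, copies], ignore_index=True)
    return frame


def _ordinal_to_partial(ordinal: int, day_missing: bool = False,
                        month_missing: bool = False) -> PartialDate:
    d = datetime.date.fromordinal(int(ordinal))
    if month_missing:
        return PartialDate(d.year)
    if day_missing:
        return PartialDate(d.year, d.month)
    return PartialDate(d.year, d.month, d.day)


def _materialize_row(row) -> ICSRReport:
    start = _ordinal_to_partial(
        row.start_ord, row.start_day_missing, row.start_month_missing
    )
    onset = _ordinal_to_partial(row.onset_ord)
    drugs = [
        DrugEntry(
            substance=row.primary_drug,
            role=Role.suspect,
            start=start,
            end=_ordinal_to_partial(row.withdraw_ord) if row.is_case else None,
        )
    ]
    if row.second_gliptin:
        drugs.append(DrugEntry(substance=row.second_gliptin, role=Role.suspect,
                               start=start))
    if row.combo_antihyperglycemic:
        drugs.append(DrugEntry(substance="metformin", role=Role.concomitant))
    if row.confounder:
        drugs.append(DrugEntry(substance=row.confounder, role=Role.concomitant))
    reactions = [
        ReactionEntry(
            term=row.reaction_term,
            onset=onset,
            resolution=_ordinal_to_partial(row.resolve_ord) if row.is_case else None,
        )
    ]
    history = []
    start_year = datetime.date.fromordinal(int(row.start_ord)).year
    if row.t2dm:
        history.append(
            MedicalHistoryEntry("type 2 diabetes mellitus", start_year - 5)
        )
    for flag, cond in [
        (row.stroke, "stroke"), (row.dementia, "dementia"),
        (row.parkinson, "parkinson"), (row.epilepsy, "epilepsy"),
    ]:
        if flag:
            history.append(MedicalHistoryEntry(cond, start_year - 2))
    if row.prior_bp_history:
        history.append(MedicalHistoryEntry("pemphigoid", start_year - 3))
    return ICSRReport(
        registration_id=row.registration_id,
        receipt_date=_ordinal_to_partial(row.receipt_ord),
        country=row.country,
        reporter=Reporter(row.reporter),
        age_years=None if np.isnan(row.age_years) else float(row.age_years),
        gender=Gender(row.gender),
        drugs=drugs,
        reactions=reactions,
        history=history,
    )


def generate_cohort(cfg: GeneratorConfig) -> list[ICSRReport]:
    """Generate the cohort as a list of ICSR reports (see generate_frame)."""
    frame = generate_frame(cfg)
    return [_materialize_row(row) for row in frame.itertuples(index=False)]


# Published per-drug margins: (event reports a, total reports mentioning the
# drug) for each DPP-4 inhibitor, with the database-wide totals.  These
# printed aggregates are the study's margin-level input.
TABLE1_MARGINS: tuple[tuple[str, int, int], ...] = (
    ("vildagliptin", 595, 2722),
    ("teneligliptin", 7, 46),
    ("linagliptin", 373, 3525),
    ("alogliptin", 34, 554),
    ("saxagliptin", 26, 885),
    ("sitagliptin", 310, 19464),
    ("gemigliptin", 0, 2),
    ("anagliptin", 0, 4),
    ("trelagliptin", 0, 0),
)
EVENT_TOTAL = 5215
GRAND_TOTAL = 11_451_738


def generate_margins_fixture() -> MarginTable:
    """The published aggregated margins as a byte-stable MarginTable."""
    return MarginTable(
        records=tuple(MarginRecord(d, a, t) for d, a, t in TABLE1_MARGINS),
        event_total=EVENT_TOTAL,
        grand_total=GRAND_TOTAL,
    )
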