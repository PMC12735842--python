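"""Shared fixtures: handcrafted reports, oracle implementations, cohorts."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest

from pvsignal import (
    ClassifiedReport,
    DrugEntry,
    Gender,
    ICSRReport,
    MedicalHistoryEntry,
    PartialDate,
    ReactionEntry,
    Reporter,
    Role,
    StudyDesign,
)


def fisher_p_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by rational-arithmetic enumeration of the support.

    Sums the central hypergeometric probabilities of every table (with the
    observed margins) whose probability does not exceed the observed
    table's.  Exact in Fraction arithmetic; independent of the log-space
    implementation under test.
    """
    m1, n1, N = a + b, a + c, a + b + c + d
    m2 = N - m1
    lo, hi = max(0, n1 - m2), min(m1, n1)
    denom = comb(N, n1)
    pmf = {k: Fraction(comb(m1, k) * comb(m2, n1 - k), denom) for k in range(lo, hi + 1)}
    obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= obs))


def make_report(
    rid: str,
    drug: str = "vildagliptin",
    reaction: str = "Pemphigoid",
    receipt: str = "2020-06-15",
    role: Role = Role.suspect,
    extra_drugs: list[DrugEntry] | None = None,
    history: list[MedicalHistoryEntry] | None = None,
    **kwargs,
) -> ICSRReport:
    onset = kwargs.pop("onset", None)
    drugs = [
        DrugEntry(
            substance=drug,
            role=role,
            start=kwargs.pop("drug_start", None),
            end=kwargs.pop("drug_end", None),
        )
    ]
    if extra_drugs:
        drugs += extra_drugs
    return ICSRReport(
        registration_id=rid,
        receipt_date=PartialDate.parse(receipt),
        drugs=drugs,
        reactions=[
            ReactionEntry(
                term=reaction,
                onset=onset,
                resolution=kwargs.pop("resolution", None),
            )
        ],
        history=history or [],
        **kwargs,
    )


@pytest.fixture
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture
def small_reports() -> list[ICSRReport]:
    """One report per 2x2 stratum."""
    return [
        make_report("A1", drug="vildagliptin", reaction="Pemphigoid"),
        make_report("A2", drug="vildagliptin", reaction="Nausea"),
        make_report("A3", drug="omeprazole", reaction="Pemphigoid"),
        make_report("A4", drug="omeprazole", reaction="Headache"),
    ]


def table3_cohort() -> list[ClassifiedReport]:
    """Case/exposure group rebuilt from the published categorical counts.

    1345 case-and-exposed reports with the exact printed marginal counts
    for gender (788/459/98), age bands (103/582/238/422), gliptin
    distribution (594/372/309/34/26/7/3) and T2DM history (409).  The
    attributes are assigned independently, which preserves every marginal
    count.
    """
    n = 1345
    genders = (
        [Gender.male] * 788 + [Gender.female] * 459 + [Gender.unspecified] * 98
    )
    ages: list[float | None] = [50.0] * 103 + [75.0] * 582 + [90.0] * 238 + [None] * 422
    drugs = (
        ["vildagliptin"] * 594
        + ["linagliptin"] * 372
        + ["sitagliptin"] * 309
        + ["alogliptin"] * 34
        + ["saxagliptin"] * 26
        + ["teneligliptin"] * 7
        + ["dpp-4 inhibitor"] * 3  # gliptin type not recorded
    )
    out = []
    for i in range(n):
        history = (
            [MedicalHistoryEntry("type 2 diabetes mellitus", 2010)] if i < 409 else []
        )
        report = ICSRReport(
            registration_id=f"T3-{i:04d}",
            receipt_date=PartialDate(2020, 6, 15),
            drugs=[DrugEntry(substance=drugs[i], role=Role.suspect)],
            reactions=[ReactionEntry(term="Pemphigoid")],
            gender=genders[i],
            age_years=ages[i],
            reporter=Reporter.physician,
            history=history,
        )
        out.append(
            ClassifiedReport(
                report=report, is_case=True, exposed=True, exposure_drug=drugs[i]
            )
        )
    return out


@pytest.fixture(scope="session")
def case_exposure_group() -> list[ClassifiedReport]:
    return table3_cohort()
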