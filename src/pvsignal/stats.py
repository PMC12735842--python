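"""Disproportionality statistics on 2x2 drug-event contingency tables.

The table cells follow the pharmacovigilance convention

    a = event reports mentioning the drug        (case, exposed)
    b = other-event reports mentioning the drug  (control, exposed)
    c = event reports without the drug           (case, unexposed)
    d = other-event reports without the drug     (control, unexposed)

Two inferential columns are computed:

* the reporting odds ratio ROR = (a/c)/(b/d) = ad/(bc) with a Wald 95% CI
  on the log scale, exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d));
* Fisher's exact framework conditional on both margins: the two-sided
  p-value by the probability-mass method, the conditional maximum-likelihood
  odds ratio (the noncentral-hypergeometric odds parameter whose
  conditional mean equals the observed a), and the exact confidence
  interval obtained by inverting the one-sided tail probabilities.

All tail sums, pmfs and conditional means are evaluated in log space over
the hypergeometric support, so tables with margins in the millions are
handled exactly as small ones.

Conditional-MLE solver modes
----------------------------
``solver="reference"`` (default) reproduces the estimates printed by the
de-facto standard implementation, R's ``stats::fisher.test``: the root is
bracketed on the direct odds scale when the estimate is below 1 and on the
reciprocal scale otherwise, and Brent's method is stopped at the tolerance
that implementation uses by default (machine epsilon ** 0.25, an absolute
tolerance on the solving scale).  For strong signals on very large tables
that tolerance is visible in the first decimal of the estimate, so the
published values of standard software can only be matched in this mode.
``solver="precise"`` solves the same equations to relative tolerance 1e-10.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .cohort import ClassifiedReport
from .io import MarginTable
from .model import StudyDesign

__all__ = [
    "ContingencyTable",
    "StatsConfig",
    "DisproResult",
    "build_contingency",
    "build_contingency_for_substance",
    "contingency_from_margins",
    "contingency_from_flags",
    "hypergeom_logpmf",
    "ror_wald",
    "fisher_exact",
    "analyze_table",
    "analyze_drug_set",
    "analyze_margins",
    "analyze_classified",
    "results_to_frame",
    "round_half_away",
]

_EPS = float(np.finfo(float).eps)
_REFERENCE_XTOL = _EPS**0.25  # uniroot's default convergence tolerance


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention for report tables)."""
    if not math.isfinite(x):
        return x
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d cells of a drug-event 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")
        if self.grand == 0:
            raise ValueError("empty contingency table")

    @property
    def exposed_total(self) -> int:
        return self.a + self.b

    @property
    def case_total(self) -> int:
        return self.a + self.c

    @property
    def grand(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class StatsConfig:
    """Inference and display settings.

    ``z`` defaults to the exact 97.5% normal quantile; using 1.96 instead
    changes no one-decimal result on the study's tables.  Under the default
    ``report_zero`` policy a table with a = 0 is reported as ROR 0 with no
    CI; ``haldane_half`` adds 0.5 to every cell before estimation instead.
    """

    alpha: float = 0.05
    z: float = 1.959964
    p_tie_tolerance: float = 1e-7
    report_decimals: int = 1
    zero_cell_policy: str = "report_zero"
    cmle_solver: str = "reference"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha out of (0,1): {self.alpha}")
        if self.z <= 0:
            raise ValueError(f"z must be positive: {self.z}")
        if self.zero_cell_policy not in ("report_zero", "haldane_half"):
            raise ValueError(f"unknown zero_cell_policy {self.zero_cell_policy!r}")
        if self.cmle_solver not in ("reference", "precise"):
            raise ValueError(f"unknown cmle_solver {self.cmle_solver!r}")


@dataclass(frozen=True)
class DisproResult:
    """One analysis row: point estimates, intervals and degeneracy flags.

    ``ror`` is None (undefined/infinite, flagged by ``ror_infinite``) when a
    zero cell other than a makes the ratio diverge under the report_zero
    policy; Wald bounds are None whenever any cell is zero under that
    policy.  ``exact_low``/``exact_high`` may be 0 / inf at the support
    boundaries.
    """

    drug: str | None = None
    table: ContingencyTable | None = None
    ror: float | None = None
    wald_low: float | None = None
    wald_high: float | None = None
    fisher_p: float | None = None
    cmle_or: float | None = None
    exact_low: float | None = None
    exact_high: float | None = None
    zero_cell: bool = False
    ror_infinite: bool = False


# ---------------------------------------------------------------------------
# table construction


def build_contingency(
    classified: Sequence[ClassifiedReport], drug_subset: set[str] | frozenset[str]
) -> ContingencyTable:
    """Report-level 2x2 table for the given exposure-drug subset.

    a/b count reports whose ``exposure_drug`` is in ``drug_subset``; c/d
    count all other reports (including reports exposed to other drugs of
    the class, mirroring the per-drug rows of a margin table).
    """
    if not classified:
        raise ValueError("empty classified input")
    a = b = c = d = 0
    for cr in classified:
        in_subset = cr.exposure_drug is not None and cr.exposure_drug in drug_subset
        if in_subset:
            if cr.is_case:
                a += 1
            else:
                b += 1
        elif cr.is_case:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def build_contingency_for_substance(
    classified: Sequence[ClassifiedReport],
    substance: str,
    any_role: bool = True,
) -> ContingencyTable:
    """2x2 table for a single substance at report level (control drugs).

    Exposure here is mention of the substance among the report's drugs
    (any role by default, suspect-only otherwise), independent of the
    study's exposure-class classification.
    """
    if not classified:
        raise ValueError("empty classified input")
    a = b = c = d = 0
    for cr in classified:
        subs = (
            cr.report.all_substances() if any_role else cr.report.suspect_substances()
        )
        if substance in subs:
            if cr.is_case:
                a += 1
            else:
                b += 1
        elif cr.is_case:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def contingency_from_flags(
    is_case: np.ndarray, in_subset: np.ndarray
) -> ContingencyTable:
    """Vectorized table construction from boolean report-level flags."""
    is_case = np.asarray(is_case, dtype=bool)
    in_subset = np.asarray(in_subset, dtype=bool)
    if is_case.shape != in_subset.shape or is_case.size == 0:
        raise ValueError("flag arrays must be nonempty and congruent")
    a = int(np.sum(is_case & in_subset))
    b = int(np.sum(~is_case & in_subset))
    c = int(np.sum(is_case & ~in_subset))
    d = int(np.sum(~is_case & ~in_subset))
    return ContingencyTable(a, b, c, d)


def contingency_from_margins(
    a: int,
    drug_total: int,
    event_total: int,
    grand_total: int,
    drug_total_includes_cases: bool = True,
) -> ContingencyTable:
    """Reconstruct the 2x2 cells from aggregated margins.

    With ``drug_total_includes_cases`` (the default, and the reading that
    reproduces the study's published ratios) the per-drug count is the
    TOTAL number of reports mentioning the drug, so b = drug_total - a;
    otherwise the column is taken as b directly.  c = event_total - a and
    d completes the grand total.
    """
    if drug_total_includes_cases:
        if a > drug_total:
            raise ValueError(f"a={a} > drug_total={drug_total}")
        b = drug_total - a
    else:
        b = drug_total
    if a > event_total:
        raise ValueError(f"a={a} > event_total={event_total}")
    c = event_total - a
    if a + b + c > grand_total:
        raise ValueError(
            f"a+b+c={a + b + c} > grand_total={grand_total} (margins inconsistent)"
        )
    d = grand_total - a - b - c
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# Wald inference


def ror_wald(table: ContingencyTable, cfg: StatsConfig = StatsConfig()) -> DisproResult:
    """Reporting odds ratio with Wald 95% (1-alpha) confidence interval."""
    a, b, c, d = table.cells()
    if table.has_zero_cell and cfg.zero_cell_policy == "haldane_half":
        af, bf, cf, df = (x + 0.5 for x in (a, b, c, d))
        ror = (af * df) / (bf * cf)
        se = math.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df)
        return DisproResult(
            table=table,
            ror=ror,
            wald_low=ror * math.exp(-cfg.z * se),
            wald_high=ror * math.exp(cfg.z * se),
            zero_cell=True,
        )
    if table.has_zero_cell:
        # report_zero policy: a=0 rows print as ROR 0 with no CI; a zero in
        # the denominator cells makes the ratio diverge instead.
        if a == 0 or d == 0:
            return DisproResult(table=table, ror=0.0, zero_cell=True)
        return DisproResult(table=table, ror=None, zero_cell=True, ror_infinite=True)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return DisproResult(
        table=table,
        ror=ror,
        wald_low=ror * math.exp(-cfg.z * se),
        wald_high=ror * math.exp(cfg.z * se),
    )


# ---------------------------------------------------------------------------
# exact conditional inference


def hypergeom_logpmf(k: int, m1: int, n1: int, N: int) -> float:
    """Log pmf of the central hypergeometric distribution.

    ``m1`` is the exposed margin (a+b), ``n1`` the case margin (a+c) and
    ``N`` the grand total; ``k`` counts exposed cases.  Returns -inf
    outside the support.
    """
    lo = max(0, n1 + m1 - N)
    hi = min(m1, n1)
    if not (lo <= k <= hi):
        return -math.inf
    return float(
        gammaln(m1 + 1)
        - gammaln(k + 1)
        - gammaln(m1 - k + 1)
        + gammaln(N - m1 + 1)
        - gammaln(n1 - k + 1)
        - gammaln(N - m1 - n1 + k + 1)
        - (gammaln(N + 1) - gammaln(n1 + 1) - gammaln(N - n1 + 1))
    )


class _ConditionalDist:
    """Noncentral hypergeometric machinery on the support of one table.

    Holds the central log-pmf over the support; pmfs at odds psi are
    obtained by exponential tilting, normalized in log space.
    """

    def __init__(self, table: ContingencyTable) -> None:
        a, b, c, d = table.cells()
        self.x = a
        m1, n1, N = a + b, a + c, table.grand
        self.lo = max(0, n1 + m1 - N)
        self.hi = min(m1, n1)
        k = np.arange(self.lo, self.hi + 1)
        self.support = k
        self.logdc = (
            gammaln(m1 + 1)
            - gammaln(k + 1)
            - gammaln(m1 - k + 1)
            + gammaln(N - m1 + 1)
            - gammaln(n1 - k + 1)
            - gammaln(N - m1 - n1 + k + 1)
        )
        self.logdc -= self.logdc.max()  # common scale; normalized per psi

    def pmf(self, psi: float) -> np.ndarray:
        t = self.logdc + np.log(psi) * self.support
        t -= t.max()
        p = np.exp(t)
        return p / p.sum()

    def mean(self, psi: float) -> float:
        if psi == 0:
            return float(self.lo)
        if math.isinf(psi):
            return float(self.hi)
        return float((self.support * self.pmf(psi)).sum())

    def cdf_upper(self, q: int, psi: float) -> float:
        """P(X >= q | psi)."""
        if psi == 0:
            return float(q <= self.lo)
        if math.isinf(psi):
            return float(q <= self.hi)
        return float(self.pmf(psi)[self.support >= q].sum())

    def cdf_lower(self, q: int, psi: float) -> float:
        """P(X <= q | psi)."""
        if psi == 0:
            return float(q >= self.lo)
        if math.isinf(psi):
            return float(q >= self.hi)
        return float(self.pmf(psi)[self.support <= q].sum())


def _solve(f, reference: bool) -> float:
    """Root of f on (0, 1] or its reciprocal branch, the way the reference
    implementation brackets it: f is evaluated at psi = 1 first and the
    root is solved on whichever side of 1 it lies, on the direct scale for
    psi < 1 and on the reciprocal scale for psi > 1."""
    xtol = _REFERENCE_XTOL if reference else 1e-12
    at_one = f(1.0)
    if at_one > 0:
        return float(brentq(f, 0.0, 1.0, xtol=xtol, rtol=8 * _EPS))
    if at_one < 0:
        return 1.0 / float(
            brentq(lambda t: f(1.0 / t), _EPS, 1.0, xtol=xtol, rtol=8 * _EPS)
        )
    return 1.0


def fisher_exact(
    table: ContingencyTable, cfg: StatsConfig = StatsConfig()
) -> DisproResult:
    """Exact conditional inference: two-sided p, CMLE odds ratio, exact CI.

    The two-sided p-value sums the probabilities of all support points
    whose central-hypergeometric pmf does not exceed the observed one by
    more than the relative tie tolerance.  The CMLE solves
    E[X | psi] = a; the CI bounds invert P(X >= a | psi) = alpha/2 (lower)
    and P(X <= a | psi) = alpha/2 (upper), with 0 / inf at the support
    boundaries.  See the module docstring for the two solver modes.
    """
    dist = _ConditionalDist(table)
    x = dist.x
    reference = cfg.cmle_solver == "reference"

    # two-sided probability-mass p-value
    p1 = dist.pmf(1.0)
    obs = p1[x - dist.lo]
    fisher_p = min(1.0, float(p1[p1 <= obs * (1.0 + cfg.p_tie_tolerance)].sum()))

    # conditional MLE
    if x == dist.lo:
        cmle = 0.0
    elif x == dist.hi:
        cmle = math.inf
    else:
        cmle = _solve(lambda psi_or_t: dist.mean(psi_or_t) - x, reference)

    # exact CI by tail inversion
    half = cfg.alpha / 2
    if x == dist.lo:
        low = 0.0
    else:
        # P(X >= x | psi) increases in psi; root where it equals alpha/2
        low = _solve(lambda psi: dist.cdf_upper(x, psi) - half, reference)
    if x == dist.hi:
        high = math.inf
    else:
        high = _solve(lambda psi: half - dist.cdf_lower(x, psi), reference)

    return DisproResult(
        table=table,
        fisher_p=fisher_p,
        cmle_or=cmle,
        exact_low=low,
        exact_high=high,
        zero_cell=table.has_zero_cell,
    )


# ---------------------------------------------------------------------------
# composition


def analyze_table(
    table: ContingencyTable,
    cfg: StatsConfig = StatsConfig(),
    drug: str | None = None,
) -> DisproResult:
    """ROR/Wald plus exact conditional inference in one result row."""
    w = ror_wald(table, cfg)
    f = fisher_exact(table, cfg)
    return replace(
        w,
        drug=drug,
        fisher_p=f.fisher_p,
        cmle_or=f.cmle_or,
        exact_low=f.exact_low,
        exact_high=f.exact_high,
    )


def analyze_margins(
    margins: MarginTable,
    cfg: StatsConfig = StatsConfig(),
    class_label: str = "all gliptins",
    class_drugs: Sequence[str] | None = None,
    drug_total_includes_cases: bool = True,
) -> list[DisproResult]:
    """One result row per margin record, preceded by a summed class row.

    ``class_drugs`` restricts which records sum into the class row (all of
    them by default); the class row is omitted when fewer than two records
    contribute.
    """
    results: list[DisproResult] = []
    pool = [
        r
        for r in margins.records
        if class_drugs is None or r.drug in set(class_drugs)
    ]
    if len(pool) >= 2:
        a = sum(r.a for r in pool)
        tot = sum(r.drug_total for r in pool)
        table = contingency_from_margins(
            a, tot, margins.event_total, margins.grand_total, drug_total_includes_cases
        )
        results.append(analyze_table(table, cfg, drug=class_label))
    for rec in margins.records:
        table = contingency_from_margins(
            rec.a,
            rec.drug_total,
            margins.event_total,
            margins.grand_total,
            drug_total_includes_cases,
        )
        results.append(analyze_table(table, cfg, drug=rec.drug))
    return results


def analyze_drug_set(
    source: MarginTable | Sequence[ClassifiedReport],
    drug_subset: set[str] | frozenset[str] | None = None,
    cfg: StatsConfig = StatsConfig(),
    label: str | None = None,
) -> list[DisproResult]:
    """Analyze one drug set from either margin-level or report-level input.

    For a MarginTable, rows whose drug is in ``drug_subset`` are summed
    into a single table (all rows when None).  For classified reports the
    table is built per report from ``exposure_drug``.
    """
    if isinstance(source, MarginTable):
        pool = [
            r
            for r in source.records
            if drug_subset is None or r.drug in drug_subset
        ]
        if not pool:
            raise ValueError("no margin records match the requested drug subset")
        a = sum(r.a for r in pool)
        tot = sum(r.drug_total for r in pool)
        table = contingency_from_margins(a, tot, source.event_total, source.grand_total)
    else:
        classified = list(source)
        if drug_subset is None:
            drug_subset = {
                cr.exposure_drug for cr in classified if cr.exposure_drug is not None
            }
        table = build_contingency(classified, drug_subset)
    return [analyze_table(table, cfg, drug=label)]


def analyze_classified(
    classified: Sequence[ClassifiedReport],
    design: StudyDesign,
    cfg: StatsConfig = StatsConfig(),
    include_controls: bool = True,
    class_label: str = "all gliptins",
) -> list[DisproResult]:
    """Per-drug + class-level (+ control drug) rows from report-level input.

    Control drugs are analyzed at the substance-mention level (any role),
    contextualizing the exposure-class signal against a drug with a known
    association and one with none.
    """
    classified = list(classified)
    results = [
        analyze_table(
            build_contingency(classified, design.exposure_drugs), cfg, drug=class_label
        )
    ]
    present = {cr.exposure_drug for cr in classified if cr.exposure_drug}
    for drug in sorted(design.exposure_drugs):
        if drug in present:
            results.append(
                analyze_table(build_contingency(classified, {drug}), cfg, drug=drug)
            )
    if include_controls:
        for ctrl in (design.positive_control, design.negative_control):
            table = build_contingency_for_substance(classified, ctrl, any_role=True)
            if table.exposed_total > 0:
                results.append(analyze_table(table, cfg, drug=f"{ctrl} (control)"))
    return results


def results_to_frame(results: Sequence[DisproResult], cfg: StatsConfig = StatsConfig()):
    """Results as a pandas DataFrame, estimates rounded for display."""
    import pandas as pd

    nd = cfg.report_decimals

    def rr(x: float | None) -> float | None:
        if x is None or not math.isfinite(x):
            return None if x is None else x
        return round_half_away(x, nd)

    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "drug": r.drug,
                "a": t.a if t else None,
                "drug_total": t.exposed_total if t else None,
                "ror": rr(r.ror),
                "wald_low": rr(r.wald_low),
                "wald_high": rr(r.wald_high),
                "fisher_p": r.fisher_p,
                "cmle_or": rr(r.cmle_or),
                "exact_low": rr(r.exact_low),
                "exact_high": rr(r.exact_high),
                "zero_cell": r.zero_cell,
            }
        )
    return pd.DataFrame(rows)
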