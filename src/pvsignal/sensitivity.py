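"""Drug-exclusion sensitivity analysis.

Re-runs the disproportionality analysis after removing every report that
mentions any drug independently associated with the event in the
literature (for bullous pemphigoid: loop diuretics, DPP-4-unrelated
immunomodulators, some antibiotics and NSAIDs, ...).  If the association
survives this stricter cohort, the signal is less likely to be an artifact
of co-reported confounder drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import ClassifiedReport
from .model import BP_ASSOCIATED_DRUGS, StudyDesign, normalize_substance
from .stats import DisproResult, StatsConfig, analyze_classified

__all__ = ["SensitivityConfig", "sensitivity_filter", "run_sensitivity"]

# Entries matched as substance prefixes rather than full strings
# ("psoralens" covers psoralen, psoralens, psoralen with UVA, ...).
_PREFIX_ENTRIES = {"psoralen"}


@dataclass(frozen=True)
class SensitivityConfig:
    """Exclusion list and the roles it matches.

    ``match_roles="any_role"`` (default) removes a report whatever the
    excluded drug's role in it; ``"suspect_only"`` restricts matching to
    suspect drugs.  ``synonyms`` maps normalized brand names to substances
    before matching.
    """

    exclusion_substances: frozenset[str] = frozenset(BP_ASSOCIATED_DRUGS)
    match_roles: str = "any_role"
    synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exclusion_substances:
            raise ValueError("empty exclusion list")
        if self.match_roles not in ("any_role", "suspect_only"):
            raise ValueError(f"unknown match_roles {self.match_roles!r}")
        object.__setattr__(
            self,
            "exclusion_substances",
            frozenset(normalize_substance(s) for s in self.exclusion_substances),
        )

    def matches(self, substance: str) -> bool:
        s = normalize_substance(substance, self.synonyms)
        if s in self.exclusion_substances:
            return True
        for prefix in _PREFIX_ENTRIES:
            if s.startswith(prefix) and any(
                e.startswith(prefix) for e in self.exclusion_substances
            ):
                return True
        return False

    @classmethod
    def from_file(cls, path, **kwargs) -> "SensitivityConfig":
        """Exclusion list from a plain-text file, one substance per line."""
        lines = [
            ln.strip()
            for ln in open(path, encoding="utf-8")
            if ln.strip() and not ln.startswith("#")
        ]
        return cls(exclusion_substances=frozenset(lines), **kwargs)


def sensitivity_filter(
    classified: list[ClassifiedReport], cfg: SensitivityConfig = SensitivityConfig()
) -> list[ClassifiedReport]:
    """Remove every report containing an excluded substance; keep the rest."""
    out: list[ClassifiedReport] = []
    for cr in classified:
        subs = (
            cr.report.all_substances()
            if cfg.match_roles == "any_role"
            else cr.report.suspect_substances()
        )
        if not any(cfg.matches(s) for s in subs):
            out.append(cr)
    return out


def run_sensitivity(
    classified: list[ClassifiedReport],
    design: StudyDesign,
    stats_cfg: StatsConfig = StatsConfig(),
    sens_cfg: SensitivityConfig = SensitivityConfig(),
    include_controls: bool = True,
) -> list[DisproResult]:
    """The primary analysis pipeline on the sensitivity-filtered cohort.

    Emits the same row layout as the primary analysis: a class-level row,
    one row per exposure drug, and (optionally) the control drugs.
    """
    survivors = sensitivity_filter(classified, sens_cfg)
    if not survivors:
        raise ValueError("exclusion list removed every report")
    return analyze_classified(
        survivors, design, stats_cfg, include_controls=include_controls
    )
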