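"""Drug-exclusion sensitivity analysis on a confounded synthetic cohort.

One fifth of the generated reports carry a co-medication independently
associated with the event (odds multiplier 10).  Removing every report
that mentions such a drug and re-running the analysis shows the class
signal strengthening - the direction expected when the exclusion removes
event reports that the confounders, not the exposure class, produced.
"""

from pvsignal import (
    GeneratorConfig,
    StudyDesign,
    analyze_classified,
    build_cohort,
    generate_cohort,
    round_half_away,
    run_sensitivity,
)

design = StudyDesign()
cfg = GeneratorConfig(
    n_reports=50_000,
    seed=2,
    drug_exposure_probs={"vildagliptin": 0.01, "sitagliptin": 0.01},
    target_ror={"vildagliptin": 150.0, "sitagliptin": 40.0},
    baseline_event_prob=1e-3,
    confounder_contamination=0.2,
    confounder_or=10.0,
)

classified, _ = build_cohort(generate_cohort(cfg), design)
before = analyze_classified(classified, design, include_controls=False)[0]
after = run_sensitivity(classified, design, include_controls=False)[0]

print(f"class-level ROR, primary analysis:     {round_half_away(before.ror)}")
print(f"class-level ROR, after drug exclusion: {round_half_away(after.ror)}")
print(
    "\nThe post-exclusion ROR is higher: confounder-driven event reports"
    "\nwere diluting the comparison group, so the signal is robust to this"
    "\nstricter cohort rather than explained away by it."
)
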