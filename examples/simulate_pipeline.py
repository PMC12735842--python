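"""End-to-end run on a synthetic report-level cohort.

Generates individual case safety reports with known structure (exposure
frequencies, target reporting odds ratios, injected duplicates and
multi-drug contaminants), then runs the full pipeline: deduplication,
eligibility exclusions, case/exposure classification, and per-drug
disproportionality statistics alongside the positive (furosemide) and
negative (paracetamol) control drugs.
"""

from pvsignal import (
    GeneratorConfig,
    StudyDesign,
    analyze_classified,
    build_cohort,
    generate_cohort,
    results_to_frame,
)

cfg = GeneratorConfig(
    n_reports=40_000,
    seed=1,
    drug_exposure_probs={
        "vildagliptin": 0.01, "sitagliptin": 0.02,
        "furosemide": 0.02, "paracetamol": 0.02,
    },
    target_ror={
        "vildagliptin": 150.0, "sitagliptin": 40.0,
        "furosemide": 11.3, "paracetamol": 0.5,
    },
    baseline_event_prob=2e-3,
)
design = StudyDesign()

reports = generate_cohort(cfg)
classified, log = build_cohort(reports, design)
print(f"generated {len(reports)} reports; {len(classified)} kept after exclusions")
print("exclusions:", log.counts)

results = analyze_classified(classified, design)
print(results_to_frame(results).to_string(index=False))
print(
    "\nEvery exposure drug shows a strong signal, the positive control sits"
    "\nwell above 1 and the negative control below 1.  The estimates are"
    "\nsmaller than the generating odds multipliers because the comparison"
    "\ngroup (cells c and d) itself contains reports of other elevated-risk"
    "\ndrugs - the same comparator dilution a real all-database analysis has."
)
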