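"""Margin-level disproportionality analysis of DPP-4 inhibitors.

Reconstructs each drug's 2x2 contingency table from the published
aggregated margins (event reports a, total reports mentioning the drug,
database totals) and computes the reporting odds ratio with its Wald 95%
CI plus the Fisher exact column (conditional-MLE odds ratio, exact CI).
"""

from pvsignal import analyze_margins, generate_margins_fixture, results_to_frame

margins = generate_margins_fixture()
results = analyze_margins(margins)

print(results_to_frame(results).to_string(index=False))
print(
    "\nROR >> 1 with a CI excluding 1 means the drug-event pair is reported"
    "\ndisproportionately often relative to the rest of the database - a"
    "\npharmacovigilance signal, not a causal risk estimate.  Rows with a = 0"
    "\nprint as ROR 0 with no interval."
)
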