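"""Score interferon-response gene signatures per cell.

The score is mean gene-set expression minus the mean of expression-bin
matched control genes, so it is centred at zero for an uninformative set.
Inflamed-region cells score higher because the generator shifts the
interferon genes upward there.
"""

import bcrpipe as bp

cohort = bp.simulate_cohort(seed=0)
scores = bp.score_signatures(cohort.expression, cohort.gene_sets, seed=0)
merged = scores.merge(cohort.metadata[["cell_id", "inflammation"]], on="cell_id")
print(
    merged.groupby(["signature_name", "inflammation"])["score"]
    .mean().round(3).to_string()
)
# A positive inflamed-vs-non-inflamed gap on both IFN signatures reads out
# the interferon imprint of inflamed terminal-ileum B cells.
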