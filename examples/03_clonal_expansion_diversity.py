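"""Clonotype the repertoire, then measure clonal expansion and diversity.

Cells sharing donor, V gene, J gene and the exact CDR3 amino-acid junction
form one clonotype.  Expansion is the fraction of cells in clones of size
>= 2; diversity is Shannon entropy over clone sizes, rarefied to a common
depth so groups with different cell counts stay comparable.
"""

import bcrpipe as bp

cohort = bp.simulate_cohort(seed=0)
analysis = bp.analyze_cohort(cohort.airr, cohort.metadata)

ti_mbc = analysis.cells[
    (analysis.cells["tissue"] == "TI") & (analysis.cells["cell_type"] == "MBC")
]
stats = bp.clonal_stats(
    ti_mbc, analysis.assignment, by=["disease_group"],
    rarefy_depth=100, n_resamples=100, seed=0,
)
print(stats.round(4).to_string(index=False))
# CD memory B cells carry a higher expanded fraction (smaller geometric
# clone-size parameter in the generator), while entropy at matched depth
# shows how evenly cells spread across clones.

usage = bp.vgene_usage(ti_mbc.dropna(subset=["v_call"]), by=["disease_group"])
top = usage.sort_values("frequency", ascending=False).groupby("disease_group").head(3)
print(top.round(4).to_string(index=False))
# IGHV3-23 usage is boosted in CD MBCs, echoing microbiota-reactive skew.
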