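# bcrpipe

Single-cell B-cell-receptor (BCR) repertoire analysis for multi-tissue
cohort studies of intestinal inflammation, built around the question of how
chronic gut inflammation (Crohn's-disease-like) rewires memory B-cell (MBC)
responses: impaired somatic hypermutation, shifted isotype usage, clonal
expansion of mucosal MBCs, and increased direct MBC → plasma-cell (PC)
differentiation read out as clonotype sharing.

It is a library for computational immunologists working with paired
single-cell V(D)J + transcriptome data: AIRR Rearrangement tables in,
per-cell mutation profiles, in-silico cell-type calls, clonal statistics
and donor-level tests out. A ground-truthed synthetic cohort generator
makes every stage testable by parameter recovery.

## What it computes

- **Somatic hypermutation (SHM)** per chain against the germline-gapped V
  alignment: mutation count `m` = mismatches over positions where both
  sequences have unambiguous bases; rate = `m / L` with `L` the comparable
  length. Gap and `N` columns count in neither numerator nor denominator.
- **Naive-calibrated mutation threshold**: the nearest-rank quantile
  (default `q = 0.99`, rank `⌈qn⌉`) of mutation counts in flow-sorted naive
  (IgD⁺CD27⁻) B cells; a chain is "mutated" iff `m > threshold`.
- **In-silico MBC calling**: within naive/memory clusters, a cell is MBC
  iff its heavy chain is mutated above threshold **and/or** its isotype is
  class-switched (IgG/IgA/IgE from the constant-region call).
- **Clonotypes**: donor-scoped groups sharing allele-stripped IGHV and IGHJ
  genes plus the exact CDR3 amino-acid junction. Expansion = fraction of
  cells in clones of size ≥ 2. Diversity = Shannon entropy
  `H = −Σ pᵢ ln pᵢ` over clone sizes, with depth-matched rarefaction.
- **Repertoire similarity** between subsets of one donor: overlap
  coefficient `|A∩B| / min(|A|,|B|)` on clonotype sets (Jaccard optional),
  with a within-donor permutation null.
- **Signature scores**: mean gene-set expression minus expression-bin
  matched control genes (25 bins, 100 controls/gene), seed-deterministic.
- **Statistics**: two-tailed/paired t, Mann–Whitney, one-way ANOVA + Tukey
  HSD, and Pearson correlation of per-donor subset proportions against
  disease-severity (SES-CD-like) scores — donor as the unit of replication.

## Worked example

```python
import bcrpipe as bp

cohort = bp.simulate_cohort(bp.default_cd_scenario(), seed=0)
analysis = bp.analyze_cohort(cohort.airr, cohort.metadata)

t = analysis.threshold
print(t.threshold_count, t.n_naive_chains)   # 2 1257
```

The threshold means: in 1257 sorted naive heavy chains, the 99th-percentile
mutation count is 2, so only chains with ≥ 3 mutations count as
antigen-experienced by mutation alone. Summarising SHM by group:

```python
mbc = analysis.cells[analysis.cells.cell_type.isin(["MBC", "GCBC", "PC"])]
print(bp.shm_summary(mbc, analysis.chains, by=["disease_group", "cell_type"]))
```

```
disease_group cell_type  mean_rate  median_rate  mean_count    n
           CD       MBC     0.0132       0.0133      3.9698 3443
       nonIBD       MBC     0.0204       0.0200      6.1214 1779
           CD        PC     0.0295       0.0300      8.8457 2625
       nonIBD        PC     0.0405       0.0400     12.1485 1657
...
```

CD memory and plasma cells carry fewer mutations than controls — the
impaired-affinity-maturation readout. The MBC–PC sharing contrast
(`examples/04_similarity_and_severity.py`) prints

```
CD        0.261
nonIBD    0.049
two-tailed t-test p = 8.54e-11
resident-like MBC proportion vs severity: r = 0.857, p = 0.00654 (n = 8 donors)
```

i.e. CD donors share five-fold more clonotypes between MBCs and PCs
(increased direct differentiation), and donors with more resident-like
MBCs in the terminal ileum have higher severity scores.

The `examples/` directory holds one short script per capability:
simulation, SHM + MBC calling, expansion/diversity, similarity +
severity association, and signature scoring.

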