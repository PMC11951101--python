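# Methods

## Scope and data model

The package analyses paired single-cell V(D)J + transcriptome data from
multi-tissue B-cell cohorts. Its unit records are the immunoglobulin chain
(AIRR Rearrangement row with a germline-gapped V alignment) and the cell
(donor, tissue, inflammation state, sort gate, optional cluster label and
cell type). Tabular stages operate on pandas DataFrames with the same
column names, so AIRR TSV, metadata TSV and the in-memory API stay
interchangeable. One heavy chain is retained per cell; when several IGH
rows exist, the one with the highest UMI count (if present) or the
lexicographically smallest `sequence_id` is kept and the rest are logged —
single-cell V(D)J callers differ here, and a deterministic rule keeps runs
reproducible.

## Somatic hypermutation

A chain's mutation count is the number of aligned positions where the
observed and germline symbols are both unambiguous bases (`A/C/G/T`) and
differ; positions with `N`, `.` or `-` in either sequence are excluded from
both the numerator and the comparable length. Insertions and deletions are
therefore not counted as mutations: the mutation unit is the nucleotide
mismatch in the gapped V alignment. Rates (`count / comparable length`)
are used for distribution summaries because they normalise read-length
differences; integer counts are used for thresholding and for the MBC→PC
increment, whose semantics are count-based.

**Naive threshold.** Sorted naive (IgD⁺CD27⁻) B cells carry near-germline
sequences; the antigen-driven-mutation threshold is the nearest-rank
quantile (rank `⌈qn⌉`, default `q = 0.99`) of their heavy-chain mutation
counts. By construction at most `1 − q` of calibration chains strictly
exceed the threshold, which bounds the false-positive rate of the
mutation-based MBC call on fresh naive cells near `1 − q` plus sampling
error. The quantile, the calibration floor (50 chains) and the chain scope
(heavy-only by default; light chains are profiled but not used for
calling) are configuration, since reasonable alternatives exist
(e.g. mean + k·SD) and the choice should be visible, not buried.

**MBC calling.** Within naive/memory clusters a cell is MBC iff its heavy
chain exceeds the threshold and/or its isotype is class-switched
(IgG/IgA/IgE by constant-gene prefix match). IgD counts as unswitched, so
an IgD⁺ cell below threshold is naive-like. Upstream GCBC/PC labels pass
through untouched. Cells without a heavy chain are reported
unclassifiable and excluded from MBC analyses; cells with an empty
constant call keep their SHM profile but drop out of isotype-frequency
denominators.

## Clonotypes, expansion, diversity

Clonotypes are donor-scoped: allele-stripped IGHV gene + IGHJ gene + exact
CDR3 amino-acid junction. Exact-junction matching is deterministic and
conservative; with the synthetic generator it coincides with true clonal
lineages by construction, so recovery tests are exact. Clonotype ids are
ordinals in sorted key order, making the partition and the ids invariant
to input row order.

Expansion in a compartment uses compartment-restricted clone sizes (a
clone counts as expanded only if ≥ 2 of its members fall inside the
compartment), matching per-tissue, per-subset presentation. Diversity is
Shannon entropy over clone sizes with the natural log, unnormalised.
Because entropy grows with cell count, cross-group comparisons use
rarefaction: subsample to a common depth without replacement (default 100
resamples) and report the mean ± SD; the resampler is seeded and
bit-reproducible.

## Repertoire similarity

Sharing between two compartments of one donor is the overlap coefficient
`|A∩B| / min(|A|,|B|)` on clonotype identity sets, unweighted by clone
size. The overlap coefficient is symmetric, bounded, and robust to the
large size asymmetry between MBC and PC compartments; Jaccard is available
as a sensitivity option. Entries with fewer than 10 clonotypes on either
side are missing, not zero, so sparse donors cannot drag group means to
zero. Group-level matrices average per-donor matrices (donor = unit of
replication) rather than pooling clonotypes. Cross-donor comparisons are
a domain error. A within-donor permutation null (shuffling compartment
membership over pooled cells, clone labels riding along) provides the
no-sharing reference distribution.

## Signature scores and statistics

The per-cell signature score is mean gene-set expression minus the mean
over expression-bin-matched controls: genes are ranked by mean expression
(ties broken by name so column order is irrelevant), cut into 25
equal-size bins, and each gene-set gene draws 100 controls from its bin
excluding the set itself (with replacement when the pool is small; seeded
RNG). Under exchangeability of set and control genes the score's
expectation is zero, which is the tested null. Note one scorer property
visible in tests: a shift applied to a large fraction of cells moves gene
means, hence bin assignments, so per-group absolute scores shrink toward
the contrast while the shifted-vs-unshifted difference still recovers the
designed shift.

Group comparisons wrap scipy: two-tailed Student t (pooled variance;
Welch optional), paired t keyed by donor with explicit unmatched-donor
errors, Mann–Whitney, and one-way ANOVA with Tukey HSD family-wise
adjustment. Proportion–severity association is Pearson r with the
two-sided p and the least-squares line; it requires ≥ 3 donors and nonzero
variance, and raw p-values are reported by default (a Benjamini–Hochberg
helper exists for dot-plot-style families of tests).

## Synthetic cohort generator

The generator emulates the study design the analysis targets, with every
effect a tunable parameter and defaults encoding the disease contrasts:

| parameter | default | meaning |
|---|---|---|
| donors | 8 CD + 7 non-IBD | CD donors add an inflamed-TI region |
| clone sizes | geometric; p = 0.55 MBC (0.45 in CD), 0.6 PC, 0.5 GCBC, 0.95 naive | smaller p ⇒ more expansion |
| SHM means λ | MBC 6→4, GCBC 5→3.5, PC 12→10 (non-IBD→CD); PC 6 in inflamed TI; naive 0.3 | Poisson per cell; i.i.d. uniform substitutions, no hotspot model |
| isotype vectors | PC IgA-dominant, shifted IgA→IgG1 in CD inflamed TI; MBC shifted toward IgM there | per-stratum categorical draws |
| MBC–PC sharing s | 0.30 CD, 0.05 non-IBD | each PC clone adopts a random same-donor MBC clone identity with probability s |
| V-gene usage | geometric-decay weights; +0.08 IGHV3-23 mass in CD MBCs | clone-level draws |
| severity score | 2 + 30·(resident-like TI MBC proportion) + N(0, 1.5) | CD donors only; resident target per donor ~ U(0.05, 0.45) |
| expression | ≤ 1500 TI MBC/PC cells × 300 genes; +0.8 on two 30-gene IFN sets in inflamed cells | log-normalised-like values |

Sharing is implemented at the clone level, which preserves the geometric
clone-size law and yields an expected PC-cell shared fraction equal to s;
at s = 1 every PC clonotype is contained in the MBC set, forcing overlap
similarity 1. Sample sizes (~50 clones per intestinal compartment, ~13 000
cells across 15 donors) were chosen as the smallest cohort at which every
designed contrast is comfortably detectable at donor-level α = 0.05;
replicate-heavy tests use a scaled-down TI-only configuration.

What the generator does **not** emulate: V(D)J junction machinery and
convergent recombination, SHM hotspot targeting and selection, doublets,
ambient RNA, isotype–mutation dependence within cells, and transcriptional
cluster structure beyond one resident-like MBC label and an IFN shift.
Passing recovery tests therefore demonstrate that the pipeline's
estimators are unbiased and its tests calibrated under a clean clonal
model — not that real-data artefacts are handled.

## Numerical and degenerate-input choices

- Alignment with zero comparable positions → per-sequence error, never a
  silent zero-length rate.
- Similarity of an empty clonotype set is 0 and flagged; below-floor
  entries are missing (NaN) and excluded from means.
- Nearest-rank quantiles (no interpolation) keep the threshold an
  attainable integer count.
- Rarefaction SD uses the population formula (ddof = 0) so the degenerate
  depth = n case reports exactly 0.
- All RNG flows through `numpy.random.default_rng` seeds; generator
  outputs and signature scores are byte-stable across reruns.

## Known limitations

Light chains are profiled but not used for clonotyping or MBC calling;
clonotype identity ignores junction length-tolerant matching (a nucleotide
identity-threshold option is a natural extension); the similarity measure
is unweighted by clone size; and the expression model is intentionally too
simple for benchmarking expression methods — it exists to exercise the
scoring contract.
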