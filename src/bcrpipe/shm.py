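"""Somatic hypermutation quantification and in-silico memory B-cell calling.

SHM is measured as nucleotide mismatches between the observed V-region
alignment and its germline, over positions where both symbols are unambiguous
bases (``A/C/G/T``); positions carrying ``N`` or a gap in either sequence are
excluded from numerator and denominator alike, so insertions/deletions are
not counted as mutations.

The antigen-driven-mutation threshold is calibrated on flow-sorted naive B
cells (IgD+CD27-), which carry essentially germline sequences: the threshold
is the nearest-rank quantile (default 0.99) of their heavy-chain mutation
counts, and a chain is called "mutated" only when its count strictly exceeds
it.  A cell in the naive/memory compartment is then classified as a memory B
cell (MBC) when its heavy chain is mutated above threshold and/or its isotype
is class-switched (IgG/IgA/IgE); otherwise it is naive-like.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    CalibrationError,
    DegenerateAlignmentError,
    InsufficientDataError,
)
from .records import ChainRecord

log = logging.getLogger(__name__)

_BASES = b"ACGT"


@dataclass(frozen=True)
class MutationProfile:
    """Per-chain SHM measurement.

    ``comparable_length`` counts aligned positions where both observed and
    germline symbols are unambiguous bases; ``mutation_rate`` is
    ``n_mutations / comparable_length``.
    """

    sequence_id: str
    n_mutations: int
    comparable_length: int

    @property
    def mutation_rate(self) -> float:
        return self.n_mutations / self.comparable_length


@dataclass(frozen=True)
class NaiveThreshold:
    """Mutation-count threshold calibrated on sorted naive B cells.

    By the nearest-rank construction, at most ``1 - quantile`` of the
    calibration chains strictly exceed ``threshold_count``.
    """

    threshold_count: int
    quantile: float
    n_naive_chains: int
    chain_scope: str = "heavy_only"


_ISOTYPE_PREFIXES = (
    # longest prefixes first so IGHG1 wins over any bare-IGHG fallback
    ("IGHG1", "IgG1", "IgG"),
    ("IGHG2", "IgG2", "IgG"),
    ("IGHG3", "IgG3", "IgG"),
    ("IGHG4", "IgG4", "IgG"),
    ("IGHA1", "IgA1", "IgA"),
    ("IGHA2", "IgA2", "IgA"),
    ("IGHM", "IgM", "IgM"),
    ("IGHD", "IgD", "IgD"),
    ("IGHE", "IgE", "IgE"),
)

_SWITCHED_CLASSES = frozenset({"IgG", "IgA", "IgE"})


@dataclass(frozen=True)
class IsotypeCall:
    sequence_id: str
    isotype: str
    isotype_class: str

    @property
    def class_switched(self) -> bool:
        return self.isotype_class in _SWITCHED_CLASSES


def count_mutations(chain: ChainRecord) -> MutationProfile:
    """Count nucleotide mismatches between observed and germline alignments.

    Raises :class:`DegenerateAlignmentError` when no aligned position has an
    unambiguous base on both strands.
    """
    obs = chain.sequence_alignment.upper().encode()
    germ = chain.germline_alignment.upper().encode()
    if len(obs) != len(germ):
        raise ValueError(
            f"{chain.sequence_id}: alignment lengths differ "
            f"({len(obs)} vs {len(germ)})"
        )
    a = np.frombuffer(obs, dtype=np.uint8)
    b = np.frombuffer(germ, dtype=np.uint8)
    bases = np.frombuffer(_BASES, dtype=np.uint8)
    comparable = np.isin(a, bases) & np.isin(b, bases)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise DegenerateAlignmentError(
            f"{chain.sequence_id}: no comparable positions in alignment"
        )
    n_mut = int((a[comparable] != b[comparable]).sum())
    return MutationProfile(chain.sequence_id, n_mut, n_comp)


def profile_chains(records, cells=None) -> pd.DataFrame:
    """Profile every chain; returns a tidy frame with one row per chain.

    Columns: sequence_id, cell_id, locus, n_mutations, comparable_length,
    mutation_rate.  Chains with degenerate alignments are skipped and logged.
    """
    rows = []
    for r in records:
        try:
            p = count_mutations(r)
        except DegenerateAlignmentError as exc:
            log.warning("skipping chain: %s", exc)
            continue
        rows.append(
            {
                "sequence_id": r.sequence_id,
                "cell_id": r.cell_id,
                "locus": r.locus,
                "n_mutations": p.n_mutations,
                "comparable_length": p.comparable_length,
                "mutation_rate": p.mutation_rate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_id", "cell_id", "locus",
            "n_mutations", "comparable_length", "mutation_rate",
        ],
    )


def calibrate_naive_threshold(
    naive_counts,
    quantile: float = 0.99,
    *,
    min_calibration_n: int = 50,
    chain_scope: str = "heavy_only",
) -> NaiveThreshold:
    """Nearest-rank quantile of the naive mutation-count distribution.

    ``naive_counts`` may be an iterable of integers or of
    :class:`MutationProfile`.  rank = ceil(quantile * n) over the sorted
    counts; a chain is later called mutated iff count > threshold_count.
    """
    counts = np.asarray(
        [c.n_mutations if isinstance(c, MutationProfile) else int(c) for c in naive_counts],
        dtype=int,
    )
    if not 0 < quantile <= 1:
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    n = counts.size
    if n < min_calibration_n:
        raise CalibrationError(
            f"only {n} naive calibration chains (< {min_calibration_n}); "
            "either lower min_calibration_n or supply a fallback threshold "
            "constant from prior data"
        )
    rank = math.ceil(quantile * n)  # 1-based nearest rank
    threshold = int(np.sort(counts)[rank - 1])
    return NaiveThreshold(
        threshold_count=threshold,
        quantile=quantile,
        n_naive_chains=n,
        chain_scope=chain_scope,
    )


def call_isotype(chain) -> IsotypeCall:
    """Isotype from the constant-region call (prefix match, case-folded).

    Accepts a :class:`ChainRecord` or a bare ``c_call`` string.  An empty or
    unrecognised call yields ``unknown`` — a value, not an error; such cells
    drop out of isotype-frequency denominators but keep their SHM profile.
    """
    if isinstance(chain, str):
        c_call, seq_id = chain, ""
    else:
        c_call, seq_id = chain.c_call, chain.sequence_id
    c = (c_call or "").strip().upper()
    for prefix, isotype, iso_class in _ISOTYPE_PREFIXES:
        if c.startswith(prefix):
            return IsotypeCall(seq_id, isotype, iso_class)
    return IsotypeCall(seq_id, "unknown", "unknown")


def classify_mbc(
    profile: MutationProfile | None,
    isotype: IsotypeCall,
    threshold: NaiveThreshold,
) -> str:
    """Classify a naive/memory-compartment cell: ``"MBC"`` or ``"naive_like"``.

    MBC iff the heavy-chain mutation count strictly exceeds the naive
    threshold and/or the isotype is class-switched.  A class-switched cell is
    MBC regardless of the threshold.
    """
    if isotype.class_switched:
        return "MBC"
    if profile is not None and profile.n_mutations > threshold.threshold_count:
        return "MBC"
    return "naive_like"


def classify_naive_memory(cells: pd.DataFrame, chains: pd.DataFrame,
                          threshold: NaiveThreshold) -> pd.DataFrame:
    """Apply the in-silico MBC call across a cohort table.

    ``cells`` needs cell_id and cell_type (upstream GCBC/PC labels pass
    through unchanged; everything else is treated as the naive/memory
    compartment).  ``chains`` is a heavy-chain table with cell_id,
    n_mutations and c_call.  Returns ``cells`` with an ``inferred_type``
    column; cells without a heavy chain are marked ``unclassifiable``.
    """
    heavy = chains.set_index("cell_id")
    out = cells.copy()
    labels = []
    for row in out.itertuples(index=False):
        upstream = getattr(row, "cell_type", None)
        if upstream in {"GCBC", "PC"}:
            labels.append(upstream)
            continue
        if row.cell_id not in heavy.index:
            labels.append("unclassifiable")
            continue
        h = heavy.loc[row.cell_id]
        profile = MutationProfile(
            sequence_id=str(h.get("sequence_id", "")),
            n_mutations=int(h["n_mutations"]),
            comparable_length=int(h.get("comparable_length", 1)),
        )
        iso = call_isotype(str(h.get("c_call", "")))
        labels.append(classify_mbc(profile, iso, threshold))
    out["inferred_type"] = labels
    n_un = labels.count("unclassifiable")
    if n_un:
        log.info("%d cell(s) lacked a heavy chain and were not classified", n_un)
    return out


def shm_summary(
    cells: pd.DataFrame,
    profiles: pd.DataFrame,
    by,
    *,
    min_group_n: int = 3,
) -> pd.DataFrame:
    """Mean/median mutation rate per metadata group.

    ``by`` lists metadata columns (e.g. ``["disease_group", "tissue"]``).
    Groups smaller than ``min_group_n`` are kept but flagged; empty groups
    are simply absent.  Raises ``KeyError`` on an unknown grouping column.
    """
    by = list(by)
    for key in by:
        if key not in cells.columns:
            raise KeyError(f"unknown grouping key {key!r}")
    base = cells.drop(columns=["n_mutations", "mutation_rate"], errors="ignore")
    merged = base.merge(profiles[["cell_id", "n_mutations", "mutation_rate"]], on="cell_id")
    if merged.empty:
        return pd.DataFrame(columns=by + ["mean_rate", "median_rate", "mean_count", "n", "low_n"])
    g = merged.groupby(by, observed=True)
    out = g.agg(
        mean_rate=("mutation_rate", "mean"),
        median_rate=("mutation_rate", "median"),
        mean_count=("n_mutations", "mean"),
        n=("mutation_rate", "size"),
    ).reset_index()
    out["low_n"] = out["n"] < min_group_n
    if out["low_n"].any():
        log.info("%d group(s) below min_group_n=%d", int(out["low_n"].sum()), min_group_n)
    return out


@dataclass(frozen=True)
class IncrementResult:
    """Mean heavy-chain mutation-count increase from MBCs to PCs for one
    donor and one TI region — the readout whose inflamed-vs-non-inflamed
    contrast indexes impaired SHM after MBC reactivation."""

    donor_id: str
    region: str
    value: float
    n_mbc: int
    n_pc: int


def mbc_to_pc_increment(
    cells: pd.DataFrame,
    profiles: pd.DataFrame,
    donor_id: str,
    region: str,
    *,
    tissue: str = "TI",
    cell_type_column: str = "cell_type",
    min_cells: int = 5,
) -> IncrementResult:
    """mean(PC mutation counts) - mean(MBC mutation counts) in one donor/region.

    ``region`` is the inflammation state (``inflamed`` / ``non_inflamed``).
    Raises :class:`InsufficientDataError` (reason included) when either
    compartment has fewer than ``min_cells`` cells — a missing value, not a
    zero.
    """
    base = cells.drop(columns=["n_mutations"], errors="ignore")
    merged = base.merge(profiles[["cell_id", "n_mutations"]], on="cell_id")
    sel = merged[
        (merged["donor_id"] == donor_id)
        & (merged["tissue"] == tissue)
        & (merged["inflammation"] == region)
    ]
    mbc = sel.loc[sel[cell_type_column] == "MBC", "n_mutations"]
    pc = sel.loc[sel[cell_type_column] == "PC", "n_mutations"]
    if len(mbc) < min_cells or len(pc) < min_cells:
        raise InsufficientDataError(
            f"donor {donor_id}, region {region}: {len(mbc)} MBCs and "
            f"{len(pc)} PCs (need >= {min_cells} of each)"
        )
    return IncrementResult(
        donor_id=donor_id,
        region=region,
        value=float(pc.mean() - mbc.mean()),
        n_mbc=int(len(mbc)),
        n_pc=int(len(pc)),
    )
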