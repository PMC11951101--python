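"""Clonotype assignment, clonal expansion and repertoire diversity.

A clonotype is donor-scoped: cells sharing donor, allele-stripped heavy V and
J genes, and the exact junction amino-acid sequence.  Expansion is the
fraction of cells in a compartment whose (compartment-restricted) clonotype
has two or more members.  Diversity is Shannon entropy over clone sizes
(natural log), with depth-matched downsampling (rarefaction) for comparisons
between compartments of unequal size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .exceptions import DepthError, InsufficientDataError
from .records import strip_allele

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Clonotype:
    clonotype_id: str
    donor_id: str
    v_gene: str
    j_gene: str
    junction_aa: str
    member_cells: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.member_cells)


def assign_clonotypes(cells: pd.DataFrame):
    """Group cells into donor-scoped heavy-chain clonotypes.

    ``cells`` needs columns cell_id, donor_id, v_call, j_call, junction_aa
    (one heavy chain per cell).  Cells with an empty junction are excluded
    and reported.  Clonotype ids are ordinals within the lexicographically
    sorted key order, so the partition and the ids are invariant to input
    row order.

    Returns ``(clonotypes, assignment, excluded)`` where ``assignment`` maps
    cell_id -> clonotype_id (a pandas Series) and ``excluded`` lists the
    cell_ids dropped for missing junctions.
    """
    df = cells.copy()
    ok = df["junction_aa"].astype(str).str.len() > 0
    excluded = df.loc[~ok, "cell_id"].tolist()
    if excluded:
        log.info("%d cell(s) lack junction_aa; excluded from clonotyping", len(excluded))
    df = df[ok]
    keys = pd.DataFrame(
        {
            "donor_id": df["donor_id"].astype(str),
            "v_gene": df["v_call"].map(strip_allele),
            "j_gene": df["j_call"].map(strip_allele),
            "junction_aa": df["junction_aa"].astype(str),
            "cell_id": df["cell_id"].astype(str),
        }
    )
    clonotypes: list[Clonotype] = []
    assignment: dict[str, str] = {}
    grouped = keys.groupby(["donor_id", "v_gene", "j_gene", "junction_aa"], sort=True)
    counter: dict[str, int] = {}
    for (donor, v, j, junc), sub in grouped:
        i = counter.get(donor, 0)
        counter[donor] = i + 1
        cid = f"{donor}.ct{i:05d}"
        members = frozenset(sub["cell_id"])
        clonotypes.append(Clonotype(cid, donor, v, j, junc, members))
        for cell in members:
            assignment[cell] = cid
    return clonotypes, pd.Series(assignment, name="clonotype_id"), excluded


def expanded_fraction(clone_labels) -> float:
    """Fraction of cells whose clonotype (within the supplied set of cells)
    has size >= 2.  ``clone_labels`` is one label per cell."""
    labels = pd.Series(list(clone_labels))
    if labels.empty:
        raise InsufficientDataError("expanded_fraction of an empty compartment")
    sizes = labels.map(labels.value_counts())
    return float((sizes >= 2).mean())


def shannon_entropy(clone_sizes) -> float:
    """Shannon entropy (natural log) of a clone-size distribution:
    H = -sum p_i ln p_i with p_i = size_i / sum(sizes)."""
    sizes = np.asarray(list(clone_sizes), dtype=float)
    if sizes.size == 0:
        raise ValueError("shannon_entropy of an empty size vector")
    if (sizes <= 0).any():
        raise ValueError("clone sizes must be positive")
    return float(_scipy_entropy(sizes))


def rarefied_entropy(clone_labels, depth: int, n_resamples: int = 100,
                     seed: int = 0) -> tuple[float, float]:
    """Depth-matched Shannon entropy: subsample ``depth`` cells without
    replacement ``n_resamples`` times and return (mean, sd) of the entropy
    of the induced clone-size distributions.  Reproducible given ``seed``.
    """
    labels = np.asarray(list(clone_labels))
    n = labels.size
    if depth > n:
        raise DepthError(f"rarefaction depth {depth} exceeds {n} cells")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_resamples)
    for i in range(n_resamples):
        sub = rng.choice(labels, size=depth, replace=False)
        _, counts = np.unique(sub, return_counts=True)
        vals[i] = shannon_entropy(counts)
    return float(vals.mean()), float(vals.std(ddof=0))


def vgene_usage(cells: pd.DataFrame, by) -> pd.DataFrame:
    """Allele-stripped IGHV usage frequencies per group.

    Returns a long frame (group columns, v_gene, frequency); frequencies sum
    to 1 within each group.  Empty groups are absent rows.
    """
    by = list(by)
    df = cells.copy()
    df["v_gene"] = df["v_call"].map(strip_allele)
    counts = df.groupby(by + ["v_gene"], observed=True).size().rename("count").reset_index()
    totals = counts.groupby(by, observed=True)["count"].transform("sum")
    counts["frequency"] = counts["count"] / totals
    return counts.drop(columns="count")


def clonal_stats(
    cells: pd.DataFrame,
    assignment: pd.Series,
    by,
    *,
    rarefy_depth: int | None = None,
    n_resamples: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-compartment clonal summary: cells, clonotypes, expanded fraction
    and Shannon entropy (optionally rarefied to ``rarefy_depth``).

    Clonotype sizes are compartment-restricted: a clone counts as expanded in
    a compartment only if >= 2 of its members fall inside it.
    """
    by = list(by)
    df = cells.copy()
    df["clonotype_id"] = df["cell_id"].map(assignment)
    df = df.dropna(subset=["clonotype_id"])
    rows = []
    for key, sub in df.groupby(by, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        labels = sub["clonotype_id"]
        sizes = labels.value_counts().to_numpy()
        row = dict(zip(by, key))
        row["n_cells"] = int(len(sub))
        row["n_clonotypes"] = int(len(sizes))
        row["expanded_fraction"] = expanded_fraction(labels)
        row["shannon_entropy"] = shannon_entropy(sizes)
        if rarefy_depth is not None and rarefy_depth <= len(sub):
            m, s = rarefied_entropy(labels, rarefy_depth, n_resamples, seed)
            row["entropy_rarefied_mean"] = m
            row["entropy_rarefied_sd"] = s
            row["entropy_depth"] = rarefy_depth
            row["entropy_resamples"] = n_resamples
        rows.append(row)
    return pd.DataFrame(rows)
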