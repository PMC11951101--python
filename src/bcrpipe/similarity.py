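"""Clonotype sharing between B-cell subsets and tissues.

The similarity between two compartments of one donor's repertoire is the
overlap coefficient on their clonotype identity sets,
``|A & B| / min(|A|, |B|)`` — symmetric, bounded in [0, 1], equal to 1 when
the smaller set is contained in the larger, and robust to the large size
asymmetry between MBC and PC compartments.  A Jaccard option
(``|A & B| / |A | B|``) is provided for sensitivity analysis.  Sharing is
only defined within a donor; group-level matrices are means of per-donor
matrices, keeping the donor as the unit of replication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import CrossDonorError, InsufficientDataError
from . import stats as _stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityEntry:
    donor_id: str
    subset_a: str
    subset_b: str
    n_clonotypes_a: int
    n_clonotypes_b: int
    n_shared: int
    similarity: float
    note: str = ""


def pairwise_similarity(clonotypes_a, clonotypes_b, metric: str = "overlap") -> float:
    """Set similarity between two clonotype identity sets.

    ``overlap``: |A&B| / min(|A|, |B|); ``jaccard``: |A&B| / |A|B|.
    Returns 0.0 when either set is empty (flagged by callers as degenerate).
    """
    a, b = set(clonotypes_a), set(clonotypes_b)
    if not a or not b:
        return 0.0
    shared = len(a & b)
    if metric == "overlap":
        return shared / min(len(a), len(b))
    if metric == "jaccard":
        return shared / len(a | b)
    raise ValueError(f"unknown metric {metric!r}; use 'overlap' or 'jaccard'")


def pairwise_entry(
    donor_a: str,
    subset_a: str,
    clonotypes_a,
    donor_b: str,
    subset_b: str,
    clonotypes_b,
    metric: str = "overlap",
) -> SimilarityEntry:
    """Build a :class:`SimilarityEntry`; cross-donor comparisons are a
    domain error — clonotype sharing is only meaningful within one donor."""
    if donor_a != donor_b:
        raise CrossDonorError(
            f"cannot compare clonotype sets across donors ({donor_a} vs {donor_b})"
        )
    a, b = set(clonotypes_a), set(clonotypes_b)
    note = "" if a and b else "empty clonotype set"
    return SimilarityEntry(
        donor_id=donor_a,
        subset_a=subset_a,
        subset_b=subset_b,
        n_clonotypes_a=len(a),
        n_clonotypes_b=len(b),
        n_shared=len(a & b),
        similarity=pairwise_similarity(a, b, metric),
        note=note,
    )


def _compartment_sets(cells: pd.DataFrame, assignment: pd.Series, compartments: dict):
    """Per (donor, compartment-name) clonotype identity sets.

    ``compartments`` maps a name to a column->value(s) filter dict applied to
    the cells table.
    """
    df = cells.copy()
    df["clonotype_id"] = df["cell_id"].map(assignment)
    df = df.dropna(subset=["clonotype_id"])
    out: dict[tuple[str, str], set] = {}
    for name, flt in compartments.items():
        mask = pd.Series(True, index=df.index)
        for col, val in flt.items():
            allowed = val if isinstance(val, (list, tuple, set, frozenset)) else [val]
            mask &= df[col].isin(list(allowed))
        for donor, sub in df[mask].groupby("donor_id"):
            out[(str(donor), name)] = set(sub["clonotype_id"])
    return out


def similarity_matrix(
    cells: pd.DataFrame,
    assignment: pd.Series,
    compartments: dict,
    *,
    metric: str = "overlap",
    min_clonotypes: int = 10,
):
    """Per-donor similarity matrices over the given compartments, plus their
    mean across donors.

    An entry is missing (NaN), not zero, when either compartment has fewer
    than ``min_clonotypes`` clonotypes in that donor; the diagonal is 1 by
    convention.  The group-level matrix averages per-donor matrices over
    donors with a non-missing entry.  Raises
    :class:`InsufficientDataError` when no donor passes the floor anywhere.
    """
    names = list(compartments)
    sets = _compartment_sets(cells, assignment, compartments)
    donors = sorted({d for d, _ in sets})
    per_donor: dict[str, pd.DataFrame] = {}
    for donor in donors:
        mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
        for i, na in enumerate(names):
            a = sets.get((donor, na), set())
            if len(a) >= min_clonotypes:
                mat.loc[na, na] = 1.0
            for nb in names[i + 1:]:
                b = sets.get((donor, nb), set())
                if len(a) < min_clonotypes or len(b) < min_clonotypes:
                    continue
                s = pairwise_similarity(a, b, metric)
                mat.loc[na, nb] = s
                mat.loc[nb, na] = s
        per_donor[donor] = mat
    stacked = np.stack([m.to_numpy() for m in per_donor.values()]) if per_donor else None
    if stacked is None or np.isnan(stacked).all():
        raise InsufficientDataError(
            f"no donor has >= {min_clonotypes} clonotypes in any compartment pair"
        )
    with np.errstate(invalid="ignore"):
        mean = pd.DataFrame(np.nanmean(stacked, axis=0), index=names, columns=names)
    return per_donor, mean


def cross_tissue_similarity(
    cells: pd.DataFrame,
    assignment: pd.Series,
    cell_type_pair: tuple[str, str],
    tissue_pair: tuple[str, str],
    *,
    cell_type_column: str = "cell_type",
    metric: str = "overlap",
    min_clonotypes: int = 10,
) -> pd.DataFrame:
    """Per-donor sharing between (cell type, tissue) compartments, e.g.
    colonic MBCs vs TI PCs.  Donors failing the clonotype floor are reported
    with a reason and a missing similarity."""
    (ct_a, ct_b), (ti_a, ti_b) = cell_type_pair, tissue_pair
    comps = {
        f"{ct_a}:{ti_a}": {cell_type_column: ct_a, "tissue": ti_a},
        f"{ct_b}:{ti_b}": {cell_type_column: ct_b, "tissue": ti_b},
    }
    sets = _compartment_sets(cells, assignment, comps)
    names = list(comps)
    donors = sorted({d for d, _ in sets})
    rows = []
    for donor in donors:
        a = sets.get((donor, names[0]), set())
        b = sets.get((donor, names[1]), set())
        if len(a) < min_clonotypes or len(b) < min_clonotypes:
            rows.append(
                dict(donor_id=donor, subset_a=names[0], subset_b=names[1],
                     n_clonotypes_a=len(a), n_clonotypes_b=len(b),
                     n_shared=len(a & b), similarity=np.nan,
                     note=f"fewer than {min_clonotypes} clonotypes"))
            continue
        e = pairwise_entry(donor, names[0], a, donor, names[1], b, metric)
        rows.append(e.__dict__ | {})
    return pd.DataFrame(rows)


def compare_similarity_groups(
    entries: pd.DataFrame,
    group_column: str,
    *,
    test: str = "t_two_tailed",
    pair_column: str | None = None,
):
    """Compare per-donor similarity between two groups (disease groups, or
    inflamed vs non-inflamed regions with ``test='paired_t'`` and
    ``pair_column='donor_id'``).  Delegates to :func:`bcrpipe.stats.compare_groups`.
    """
    df = entries.dropna(subset=["similarity"])
    groups = df[group_column].unique()
    if len(groups) < 2:
        raise InsufficientDataError(
            f"need >= 2 groups in {group_column!r}, found {len(groups)}"
        )
    pair_keys = df[pair_column] if pair_column else None
    return _stats.compare_groups(
        df["similarity"], df[group_column], test=test, pair_keys=pair_keys
    )


def permutation_null_similarity(
    cells: pd.DataFrame,
    assignment: pd.Series,
    compartment_a: dict,
    compartment_b: dict,
    *,
    n_permutations: int = 200,
    metric: str = "overlap",
    seed: int = 0,
) -> pd.DataFrame:
    """Within-donor permutation null for compartment sharing.

    For each donor, pool the cells of both compartments, shuffle which cells
    belong to which compartment (clone labels ride along), and recompute the
    similarity.  Returns per-donor observed similarity and the one-sided
    permutation p-value P(null >= observed); under no designed sharing the
    observed value should be indistinguishable from this null.
    """
    rng = np.random.default_rng(seed)
    df = cells.copy()
    df["clonotype_id"] = df["cell_id"].map(assignment)
    df = df.dropna(subset=["clonotype_id"])

    def mask_for(flt):
        m = pd.Series(True, index=df.index)
        for col, val in flt.items():
            allowed = val if isinstance(val, (list, tuple, set, frozenset)) else [val]
            m &= df[col].isin(list(allowed))
        return m

    ma, mb = mask_for(compartment_a), mask_for(compartment_b)
    rows = []
    for donor, sub in df.groupby("donor_id"):
        ia = sub.index[ma.loc[sub.index]]
        ib = sub.index[mb.loc[sub.index]]
        if len(ia) == 0 or len(ib) == 0:
            continue
        labels_a = df.loc[ia, "clonotype_id"]
        labels_b = df.loc[ib, "clonotype_id"]
        obs = pairwise_similarity(set(labels_a), set(labels_b), metric)
        pooled = np.concatenate([labels_a.to_numpy(), labels_b.to_numpy()])
        na = len(ia)
        null = np.empty(n_permutations)
        for k in range(n_permutations):
            perm = rng.permutation(pooled)
            null[k] = pairwise_similarity(set(perm[:na]), set(perm[na:]), metric)
        p = (1.0 + np.sum(null >= obs)) / (n_permutations + 1.0)
        rows.append(dict(donor_id=donor, observed=obs,
                         null_mean=float(null.mean()), p_value=float(p)))
    return pd.DataFrame(rows)
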