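"""Per-cell gene-signature scores and subset proportions.

The signature score of a cell is the mean log-normalized expression of the
gene set minus the mean over an expression-matched control set: genes are
binned by their mean expression across cells, and each gene-set gene draws
control genes from its own bin (excluding the gene set itself).  Bin
matching makes the score's expectation zero when gene-set membership is
exchangeable with the controls, so shifts measure signal, not baseline
expression.  Scoring is seed-deterministic and invariant to the column
order of the matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ScoringError
from .records import GeneSet

log = logging.getLogger(__name__)


def score_signature(
    expr: pd.DataFrame,
    gene_set: GeneSet,
    *,
    n_bins: int = 25,
    n_ctrl_per_gene: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression-bin-matched control score for one signature.

    Parameters
    ----------
    expr
        Cells x genes matrix of log-normalized values (cell ids on the
        index, gene symbols on the columns; symbols matched exactly).
    n_bins
        Number of equal-size mean-expression bins (default 25).
    n_ctrl_per_gene
        Control genes drawn per gene-set gene, with replacement when the bin
        pool is smaller (default 100).

    Returns a tidy frame (cell_id, signature_name, score).  Raises
    :class:`ScoringError` when no gene-set gene is in the matrix; warns when
    fewer than half are.
    """
    genes = expr.columns.to_numpy(dtype=object)
    in_set = sorted(set(gene_set.genes) & set(genes))
    if not in_set:
        raise ScoringError(f"signature {gene_set.name!r}: no genes found in matrix")
    if len(in_set) < 0.5 * len(gene_set.genes):
        log.warning(
            "signature %s: only %d/%d genes present in matrix",
            gene_set.name, len(in_set), len(gene_set.genes),
        )

    means = expr.mean(axis=0)
    # rank genes by (mean, name) so bin membership is independent of column order
    order = sorted(genes, key=lambda g: (means[g], g))
    bin_of = {g: (i * n_bins) // len(order) for i, g in enumerate(order)}
    pools: dict[int, list[str]] = {}
    set_genes = set(gene_set.genes)
    for g in order:
        if g not in set_genes:
            pools.setdefault(bin_of[g], []).append(g)

    rng = np.random.default_rng(seed)
    ctrl_genes: list[str] = []
    for g in in_set:
        pool = pools.get(bin_of[g])
        if not pool:  # whole bin is inside the gene set: fall back to all controls
            pool = [x for x in order if x not in set_genes]
            if not pool:
                raise ScoringError(
                    f"signature {gene_set.name!r}: no control genes available"
                )
        replace = len(pool) < n_ctrl_per_gene
        ctrl_genes.extend(rng.choice(pool, size=n_ctrl_per_gene, replace=replace))

    score = expr[in_set].mean(axis=1).to_numpy() - expr[ctrl_genes].mean(axis=1).to_numpy()
    return pd.DataFrame(
        {
            "cell_id": expr.index.astype(str),
            "signature_name": gene_set.name,
            "score": score,
        }
    )


def score_signatures(expr, gene_sets, **kwargs) -> pd.DataFrame:
    """Score several signatures; concatenated tidy frame."""
    return pd.concat(
        [score_signature(expr, gs, **kwargs) for gs in gene_sets],
        ignore_index=True,
    )


def subset_proportions(
    cells: pd.DataFrame,
    numerator: dict,
    denominator: dict,
    per=("donor_id", "tissue"),
) -> pd.DataFrame:
    """Per-donor (x tissue, ...) proportion of numerator cells among
    denominator cells.

    Both filters are column->value(s) dicts on the cells table; the
    numerator must select a subset of the denominator (filters must nest),
    otherwise a ``ValueError`` is raised.  Records with an empty denominator
    are omitted (with a log line), not reported as zero.
    """
    per = list(per)

    def mask_for(flt):
        m = pd.Series(True, index=cells.index)
        for col, val in flt.items():
            allowed = val if isinstance(val, (list, tuple, set, frozenset)) else [val]
            m &= cells[col].isin(list(allowed))
        return m

    num_mask, den_mask = mask_for(numerator), mask_for(denominator)
    if (num_mask & ~den_mask).any():
        raise ValueError(
            "numerator filter selects cells outside the denominator; "
            "proportion filters must nest"
        )
    rows = []
    for key, sub in cells.groupby(per, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        den = int(den_mask.loc[sub.index].sum())
        if den == 0:
            log.info("empty denominator for %s; record omitted", dict(zip(per, key)))
            continue
        num = int((num_mask & den_mask).loc[sub.index].sum())
        row = dict(zip(per, key))
        row.update(n_numerator=num, n_denominator=den, proportion=num / den)
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        raise InsufficientDataError("no group has a nonempty denominator")
    return out


def isotype_frequencies(
    cells: pd.DataFrame,
    chains: pd.DataFrame,
    by,
    *,
    level: str = "isotype_class",
) -> pd.DataFrame:
    """Isotype (or isotype-class) frequency per group, heavy chains only.

    Cells whose isotype is unknown are excluded from the denominator, per
    the missing-c_call policy.  ``chains`` must carry cell_id and an
    ``isotype``/``isotype_class`` column (see :func:`bcrpipe.shm.call_isotype`).
    """
    by = list(by)
    merged = cells.merge(chains[["cell_id", level]], on="cell_id")
    merged = merged[merged[level] != "unknown"]
    counts = merged.groupby(by + [level], observed=True).size().rename("count").reset_index()
    totals = counts.groupby(by, observed=True)["count"].transform("sum")
    counts["frequency"] = counts["count"] / totals
    return counts
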