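"""Readers and writers for the standard formats the pipeline touches.

AIRR Rearrangement TSV (community schema column names), FASTA germline
references, GMT gene sets, cell-metadata TSV and dense-TSV / MatrixMarket
expression matrices.  All readers validate strictly; a rejected row is
reported, never silently dropped.  The missing-value dialect on write is the
empty string, never ``NA``/``None``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import FormatError, InsufficientDataError, RecordValidationError
from .records import ChainRecord, GeneSet

log = logging.getLogger(__name__)

#: Column order of the AIRR Rearrangement TSV written by this package.
#: ``junction`` is the nucleotide junction per the AIRR schema; the
#: amino-acid junction is ``junction_aa``.
AIRR_COLUMNS = (
    "sequence_id",
    "cell_id",
    "locus",
    "v_call",
    "j_call",
    "c_call",
    "junction",
    "junction_aa",
    "sequence_alignment",
    "germline_alignment",
)

#: Columns that must be present for a file to be read at all.
AIRR_REQUIRED = (
    "sequence_id",
    "v_call",
    "j_call",
    "junction_aa",
    "sequence_alignment",
    "germline_alignment",
)


def read_airr(path, *, on_invalid: str = "raise"):
    """Read an AIRR Rearrangement TSV into :class:`~bcrpipe.records.ChainRecord` s.

    Parameters
    ----------
    path
        Tab-separated file with AIRR column names.
    on_invalid
        ``"raise"`` (default): raise :class:`RecordValidationError` listing
        every offending row.  ``"report"``: return ``(records, rejections)``
        where ``rejections`` is a list of ``(sequence_id, reason)`` pairs.

    Raises
    ------
    FormatError
        If a mandatory column is absent (the message names it).
    RecordValidationError
        If any row violates a chain invariant and ``on_invalid="raise"``.
    """
    if on_invalid not in {"raise", "report"}:
        raise ValueError(f"on_invalid must be 'raise' or 'report', got {on_invalid!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in AIRR_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory AIRR column(s): {', '.join(missing)}")

    records: list[ChainRecord] = []
    rejections: list[tuple[str, str]] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        rec = ChainRecord(
            sequence_id=d.get("sequence_id", ""),
            cell_id=d.get("cell_id", ""),
            locus=d.get("locus", ""),
            v_call=d.get("v_call", ""),
            j_call=d.get("j_call", ""),
            c_call=d.get("c_call", ""),
            junction_aa=d.get("junction_aa", ""),
            junction_nt=d.get("junction", ""),
            sequence_alignment=d.get("sequence_alignment", ""),
            germline_alignment=d.get("germline_alignment", ""),
        )
        problems = rec.problems()
        if problems:
            for p in problems:
                rejections.append((rec.sequence_id, p))
        else:
            records.append(rec)

    if rejections and on_invalid == "raise":
        lines = "; ".join(f"{sid}: {why}" for sid, why in rejections[:10])
        more = "" if len(rejections) <= 10 else f" (+{len(rejections) - 10} more)"
        raise RecordValidationError(
            f"{path}: {len(rejections)} invalid row(s): {lines}{more}",
            rejections=rejections,
        )
    if on_invalid == "report":
        return records, rejections
    return records


def write_airr(records, path) -> None:
    """Write chains as AIRR Rearrangement TSV with a deterministic column order.

    Empty fields are written as empty strings (never ``"NA"``); an empty
    record list yields a header-only file.
    """
    rows = [
        {
            "sequence_id": r.sequence_id,
            "cell_id": r.cell_id,
            "locus": r.locus,
            "v_call": r.v_call,
            "j_call": r.j_call,
            "c_call": r.c_call,
            "junction": r.junction_nt,
            "junction_aa": r.junction_aa,
            "sequence_alignment": r.sequence_alignment,
            "germline_alignment": r.germline_alignment,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(AIRR_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def airr_to_frame(records) -> pd.DataFrame:
    """Tabular view of chain records (columns as in :data:`AIRR_COLUMNS`)."""
    return pd.DataFrame(
        [
            {
                "sequence_id": r.sequence_id,
                "cell_id": r.cell_id,
                "locus": r.locus,
                "v_call": r.v_call,
                "j_call": r.j_call,
                "c_call": r.c_call,
                "junction": r.junction_nt,
                "junction_aa": r.junction_aa,
                "sequence_alignment": r.sequence_alignment,
                "germline_alignment": r.germline_alignment,
            }
            for r in records
        ],
        columns=list(AIRR_COLUMNS),
    )


def select_heavy_chains(records) -> tuple[dict, list[tuple[str, str]]]:
    """Pick one IGH chain per cell.

    If a cell carries more than one heavy chain, keep the one with the highest
    ``duplicate_count``/``umi_count`` when such an attribute is present on the
    record, else the lexicographically smallest ``sequence_id``; the choice is
    logged.  Returns ``(cell_id -> ChainRecord, dropped)`` where ``dropped``
    lists ``(cell_id, sequence_id)`` of discarded chains.
    """
    by_cell: dict[str, list] = {}
    for r in records:
        if r.locus == "IGH":
            by_cell.setdefault(r.cell_id, []).append(r)
    chosen: dict = {}
    dropped: list[tuple[str, str]] = []
    for cell_id, chains in by_cell.items():
        if len(chains) == 1:
            chosen[cell_id] = chains[0]
            continue
        def sort_key(c):
            umi = getattr(c, "duplicate_count", None)
            return (-(umi if umi is not None else 0), c.sequence_id)
        chains = sorted(chains, key=sort_key)
        chosen[cell_id] = chains[0]
        for extra in chains[1:]:
            dropped.append((cell_id, extra.sequence_id))
        log.info(
            "cell %s has %d heavy chains; kept %s",
            cell_id, len(chains), chains[0].sequence_id,
        )
    return chosen, dropped


def read_germline_fasta(path) -> dict[str, str]:
    """Read a germline V/J segment FASTA into ``{name: sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_germline_fasta(segments: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in segments.items()),
        str(path),
        "fasta",
    )


def read_gene_sets(path) -> list[GeneSet]:
    """Read GMT: one gene set per line, ``name<TAB>description<TAB>gene...``.

    Duplicate genes within a line are collapsed; a line with fewer than three
    fields raises :class:`FormatError` naming the line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and at "
                    f"least one gene ({len(fields)} field(s) found)"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: GMT line has no genes")
            sets.append(GeneSet(name=name, genes=frozenset(genes)))
    return sets


def write_gene_sets(sets, path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, ""] + sorted(gs.genes)) + "\n")


def read_expression(path, cells=None, *, rows_path=None, cols_path=None) -> pd.DataFrame:
    """Read a log-normalized cells x genes matrix (dense TSV or MTX triplet).

    Dense TSV: first column = cell ids, header = gene symbols.  MatrixMarket:
    pass ``rows_path`` (cell ids, one per line) and ``cols_path`` (gene
    symbols).  When ``cells`` is given, the matrix is restricted to those
    cells; missing cells are logged, and an empty intersection raises
    :class:`InsufficientDataError`.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if rows_path is None or cols_path is None:
            raise FormatError("MTX input needs rows_path (cells) and cols_path (genes)")
        from scipy.io import mmread

        mat = mmread(str(path)).toarray()
        row_labels = Path(rows_path).read_text().split()
        col_labels = Path(cols_path).read_text().split()
        if mat.shape != (len(row_labels), len(col_labels)):
            raise FormatError(
                f"{path}: matrix shape {mat.shape} does not match "
                f"{len(row_labels)} row labels x {len(col_labels)} column labels"
            )
        df = pd.DataFrame(mat, index=row_labels, columns=col_labels)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)

    if cells is not None:
        cells = list(cells)
        present = [c for c in cells if c in df.index]
        absent = [c for c in cells if c not in df.index]
        if not present:
            raise InsufficientDataError(
                f"{path}: none of the {len(cells)} requested cells are in the matrix"
            )
        if absent:
            log.warning("%s: %d requested cell(s) absent from matrix", path, len(absent))
        df = df.loc[present]
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read the per-cell metadata TSV (cell_id, donor_id, disease_group,
    tissue, inflammation, sorted_gate, optional cluster_label/cell_type)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"cell_id", "donor_id", "disease_group", "tissue", "inflammation"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata column(s): {', '.join(sorted(missing))}")
    return df
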