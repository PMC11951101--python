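"""End-to-end cohort analysis.

Chains the stages in study order: heavy-chain selection, per-chain SHM
profiling, naive-threshold calibration on the sorted naive gate, isotype
calling, in-silico MBC classification, and donor-scoped clonotyping.  The
result object carries the per-cell table every downstream summary
(expansion, diversity, similarity, proportions, association) starts from.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import clonotypes as _clono
from . import shm as _shm
from .exceptions import InsufficientDataError
from .io import select_heavy_chains
from .records import ChainRecord


def records_from_frame(airr: pd.DataFrame) -> list[ChainRecord]:
    """Chain records from an AIRR-columned DataFrame (in-memory inverse of
    :func:`bcrpipe.io.read_airr`)."""
    get = lambda row, col: str(row.get(col, "") or "")
    return [
        ChainRecord(
            sequence_id=get(row, "sequence_id"),
            cell_id=get(row, "cell_id"),
            locus=get(row, "locus"),
            v_call=get(row, "v_call"),
            j_call=get(row, "j_call"),
            c_call=get(row, "c_call"),
            junction_aa=get(row, "junction_aa"),
            junction_nt=get(row, "junction"),
            sequence_alignment=get(row, "sequence_alignment"),
            germline_alignment=get(row, "germline_alignment"),
        )
        for row in airr.to_dict("records")
    ]


@dataclass
class CohortAnalysis:
    """Analysis state for one cohort.

    ``cells`` is the metadata table augmented with the heavy chain's V/J
    calls, junction, mutation profile, isotype call, the in-silico
    ``inferred_type`` and the clonotype id.  ``chains`` is the per-heavy-
    chain table.  ``threshold`` is the naive-calibrated mutation threshold.
    """

    cells: pd.DataFrame
    chains: pd.DataFrame
    threshold: _shm.NaiveThreshold
    clonotypes: list
    assignment: pd.Series
    excluded_cells: list
    light_profiles: pd.DataFrame | None = None


def analyze_cohort(
    airr: pd.DataFrame,
    metadata: pd.DataFrame,
    *,
    quantile: float = 0.99,
    min_calibration_n: int = 50,
    chain_scope: str = "heavy_only",
) -> CohortAnalysis:
    """Run the full repertoire analysis on one cohort.

    ``airr`` holds one row per chain (AIRR columns), ``metadata`` one row per
    cell with donor/tissue/inflammation/sorted_gate labels and optional
    upstream cell_type / cluster_label.  The naive threshold is calibrated
    on heavy chains of ``sorted_gate == "naive"`` cells.
    """
    records = records_from_frame(airr)
    heavy_by_cell, _dropped = select_heavy_chains(records)
    heavy = list(heavy_by_cell.values())
    profiles = _shm.profile_chains(heavy)

    iso_calls = [_shm.call_isotype(r) for r in heavy]
    chains = profiles.merge(
        pd.DataFrame(
            {
                "sequence_id": [r.sequence_id for r in heavy],
                "v_call": [r.v_call for r in heavy],
                "j_call": [r.j_call for r in heavy],
                "c_call": [r.c_call for r in heavy],
                "junction_aa": [r.junction_aa for r in heavy],
                "isotype": [c.isotype for c in iso_calls],
                "isotype_class": [c.isotype_class for c in iso_calls],
                "class_switched": [c.class_switched for c in iso_calls],
            }
        ),
        on="sequence_id",
    )

    naive_cells = set(metadata.loc[metadata["sorted_gate"] == "naive", "cell_id"])
    naive_counts = chains.loc[chains["cell_id"].isin(naive_cells), "n_mutations"]
    if naive_counts.empty:
        raise InsufficientDataError(
            "no sorted naive cells with heavy chains; cannot calibrate threshold"
        )
    threshold = _shm.calibrate_naive_threshold(
        naive_counts, quantile,
        min_calibration_n=min_calibration_n, chain_scope=chain_scope,
    )

    cells = _shm.classify_naive_memory(metadata, chains, threshold)
    cells = cells.merge(
        chains[
            ["cell_id", "v_call", "j_call", "junction_aa", "n_mutations",
             "comparable_length", "mutation_rate", "isotype", "isotype_class",
             "class_switched"]
        ],
        on="cell_id",
        how="left",
    )

    clono_input = cells.dropna(subset=["v_call"])
    clonos, assignment, excluded = _clono.assign_clonotypes(clono_input)
    cells["clonotype_id"] = cells["cell_id"].map(assignment)

    light_profiles = None
    light = [r for r in records if r.locus in {"IGK", "IGL"}]
    if light:
        light_profiles = _shm.profile_chains(light)

    return CohortAnalysis(
        cells=cells,
        chains=chains,
        threshold=threshold,
        clonotypes=clonos,
        assignment=assignment,
        excluded_cells=excluded,
        light_profiles=light_profiles,
    )
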