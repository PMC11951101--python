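"""Domain record types.

The pipeline's unit objects: one immunoglobulin chain with its germline-gapped
alignment (:class:`ChainRecord`), one cell with its sample labels
(:class:`CellRecord`), one donor (:class:`DonorRecord`) and one gene set
(:class:`GeneSet`).  Tabular pipeline stages operate on pandas DataFrames
whose columns mirror these fields; the dataclasses are the validated
record-level interchange used by the IO layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import BcrPipeError

LOCI = frozenset({"IGH", "IGK", "IGL"})
ALIGNMENT_ALPHABET = frozenset("ACGTN.-")
UNAMBIGUOUS_BASES = frozenset("ACGT")

DISEASE_GROUPS = ("CD", "nonIBD")
TISSUES = ("blood", "colon", "TI")
INFLAMMATION_STATES = ("inflamed", "non_inflamed", "not_applicable")
SORTED_GATES = ("antigen_experienced", "naive")
CELL_TYPES = ("NBC", "MBC", "GCBC", "PC")


def strip_allele(call: str) -> str:
    """Collapse a V/J allele call to its gene, e.g. ``IGHV3-23*01`` -> ``IGHV3-23``.

    The raw call is always preserved on the record; stripping happens only at
    grouping time (clonotyping, usage tables).
    """
    return call.split("*", 1)[0].strip()


@dataclass
class ChainRecord:
    """One immunoglobulin chain with a germline-gapped V-region alignment."""

    sequence_id: str
    cell_id: str
    locus: str
    v_call: str
    j_call: str
    c_call: str
    junction_aa: str
    junction_nt: str
    sequence_alignment: str
    germline_alignment: str

    def problems(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        out: list[str] = []
        if self.locus and self.locus not in LOCI:
            out.append(f"unknown locus {self.locus!r}")
        if len(self.sequence_alignment) != len(self.germline_alignment):
            out.append(
                "alignment length mismatch: sequence_alignment has "
                f"{len(self.sequence_alignment)} characters, germline_alignment "
                f"has {len(self.germline_alignment)}"
            )
        bad = (set(self.sequence_alignment) | set(self.germline_alignment)) - ALIGNMENT_ALPHABET
        if bad:
            out.append(f"alignment contains characters outside A/C/G/T/N/./-: {sorted(bad)}")
        if not self.v_call:
            out.append("empty v_call")
        return out

    @property
    def v_gene(self) -> str:
        return strip_allele(self.v_call)

    @property
    def j_gene(self) -> str:
        return strip_allele(self.j_call)


@dataclass
class CellRecord:
    """One cell: sample-design labels plus its retained chains.

    ``inflammation`` must be ``not_applicable`` for blood cells; pipeline-
    assigned ``cell_type`` must be consistent with the sort gate (a
    naive-gated cell is never labelled MBC/GCBC/PC).
    """

    cell_id: str
    donor_id: str
    disease_group: str
    tissue: str
    inflammation: str
    sorted_gate: str = "antigen_experienced"
    cluster_label: str | None = None
    cell_type: str | None = None
    heavy_chain: ChainRecord | None = None
    light_chains: list[ChainRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.tissue == "blood" and self.inflammation != "not_applicable":
            raise BcrPipeError(
                f"cell {self.cell_id}: blood cells must have inflammation "
                f"'not_applicable', got {self.inflammation!r}"
            )
        if self.sorted_gate == "naive" and self.cell_type in {"MBC", "GCBC", "PC"}:
            raise BcrPipeError(
                f"cell {self.cell_id}: naive-gated cell labelled {self.cell_type}"
            )


@dataclass
class DonorRecord:
    """One study participant.  ``disease_score`` (SES-CD-like severity) is
    defined for CD donors only."""

    donor_id: str
    disease_group: str
    disease_score: float | None = None

    def __post_init__(self):
        if self.disease_score is not None and self.disease_group != "CD":
            raise BcrPipeError(
                f"donor {self.donor_id}: disease_score is only defined for CD donors"
            )
        if self.disease_score is not None and self.disease_score < 0:
            raise BcrPipeError(f"donor {self.donor_id}: negative disease_score")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (case-sensitive, no alias resolution)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise BcrPipeError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)
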