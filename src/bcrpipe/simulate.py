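"""Synthetic multi-donor B-cell cohort generator.

Emits a fully synthetic study — germline V/J reference, single-cell AIRR
heavy-chain repertoires with clonal structure, Poisson SHM and isotype
switching, per-cell metadata, donor disease scores, and a small expression
matrix with matching gene sets — together with ground truth, so every
pipeline stage has a parameter-recovery test.

Design of the generative model (all effects are tunable through
:class:`CohortConfig`; the defaults in :func:`default_cd_scenario` encode a
Crohn's-disease-like contrast):

* donors: two disease groups; CD donors contribute blood, colon, and both
  non-inflamed and inflamed terminal-ileum (TI) regions; controls have no
  inflamed region.
* clones: per (site, cell type) a fixed number of clones with geometric
  sizes; within a clone every cell shares the clone's V/J calls and exact
  amino-acid junction, so generator clones and the exact-junction clonotype
  rule coincide by construction.
* SHM: each cell's mutation count is Poisson with a stratum mean
  (cell type x disease group x site); mutations are i.i.d. uniform
  substitutions over the V region — no hotspot model, which is sufficient
  to exercise counting and thresholding.
* isotypes: drawn per cell from a stratum probability vector; sorted naive
  blood cells are unswitched with a small calibration-level mutation rate.
* MBC->PC sharing: each plasma-cell clone adopts the identity of a random
  memory-B-cell clone of the same donor with probability ``s``, so the
  expected fraction of PC cells in MBC-shared clones is ``s`` and sharing is
  donor-wide across tissues.
* severity: each CD donor's disease score is linear in its realized
  resident-like MBC proportion in the TI plus Gaussian noise.
* expression: TI MBC/PC cells get a small log-normal-like matrix in which
  interferon-response gene sets are shifted upward in inflamed-region cells.

Everything is driven by one :class:`numpy.random.Generator`; identical
config + seed reproduce the outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import write_airr  # noqa: F401  (re-exported convenience)
from .io import write_gene_sets, write_germline_fasta
from .records import GeneSet, strip_allele

#: site name -> (tissue, inflammation) as recorded in cell metadata
SITES = {
    "blood": ("blood", "not_applicable"),
    "colon": ("colon", "non_inflamed"),
    "TI_non_inflamed": ("TI", "non_inflamed"),
    "TI_inflamed": ("TI", "inflamed"),
}

_AA = np.array(list("ADEFGHIKLMNPQRSTVY"))
_NT = np.array(list("ACGT"))

#: frequently used human IGHV genes; the synthetic reference reuses these
#: names (with synthetic sequences) so usage tables read like real data
_V_GENE_NAMES = [
    "IGHV3-23", "IGHV1-2", "IGHV4-34", "IGHV3-7", "IGHV1-69", "IGHV3-48",
    "IGHV4-39", "IGHV3-30", "IGHV5-51", "IGHV1-18", "IGHV3-33", "IGHV4-59",
    "IGHV3-15", "IGHV1-46", "IGHV3-21", "IGHV2-5", "IGHV6-1", "IGHV3-11",
    "IGHV4-4", "IGHV1-8", "IGHV3-74", "IGHV2-70", "IGHV7-4-1", "IGHV3-53",
    "IGHV4-31", "IGHV1-24", "IGHV3-9", "IGHV5-10-1", "IGHV4-61", "IGHV3-43",
]

_ISOTYPE_TO_C_CALL = {
    "IgM": "IGHM", "IgD": "IGHD",
    "IgG1": "IGHG1", "IgG2": "IGHG2", "IgG3": "IGHG3", "IgG4": "IGHG4",
    "IgA1": "IGHA1", "IgA2": "IGHA2", "IgE": "IGHE",
}


@dataclass
class CohortConfig:
    """Ground-truth parameters of the synthetic study.

    Stratum-valued parameters (``shm_lambda``, ``isotype_probs``,
    ``usage_boost``) are dicts keyed by ``(cell_type,)``,
    ``(cell_type, group)`` or ``(cell_type, group, site)``; the most specific
    key wins.
    """

    n_donors: dict = field(default_factory=lambda: {"CD": 8, "nonIBD": 7})
    sites_by_group: dict = field(default_factory=lambda: {
        "CD": ["blood", "colon", "TI_non_inflamed", "TI_inflamed"],
        "nonIBD": ["blood", "colon", "TI_non_inflamed"],
    })
    #: expected clones per (site, cell_type)
    n_clones: dict = field(default_factory=lambda: {
        ("blood", "NBC"): 80, ("blood", "MBC"): 40, ("blood", "PC"): 30,
        ("colon", "MBC"): 50, ("colon", "GCBC"): 30, ("colon", "PC"): 55,
        ("TI_non_inflamed", "MBC"): 50, ("TI_non_inflamed", "GCBC"): 40,
        ("TI_non_inflamed", "PC"): 55,
        ("TI_inflamed", "MBC"): 50, ("TI_inflamed", "GCBC"): 40,
        ("TI_inflamed", "PC"): 55,
    })
    #: geometric clone-size parameter (P(size=k) = p(1-p)^(k-1)) per cell
    #: type, optionally overridden per (cell_type, group): CD memory B cells
    #: are more clonally expanded (smaller p) than controls
    clone_size_p: dict = field(default_factory=lambda: {
        "NBC": 0.95, "MBC": 0.55, "GCBC": 0.50, "PC": 0.60,
        ("MBC", "CD"): 0.45,
    })
    #: Poisson SHM mean per stratum
    shm_lambda: dict = field(default_factory=lambda: {
        ("NBC",): 0.3,
        ("MBC", "nonIBD"): 6.0, ("MBC", "CD"): 4.0,
        ("GCBC", "nonIBD"): 5.0, ("GCBC", "CD"): 3.5,
        ("PC", "nonIBD"): 12.0, ("PC", "CD"): 10.0,
        ("PC", "CD", "TI_inflamed"): 6.0,
    })
    #: isotype probability vector per stratum
    isotype_probs: dict = field(default_factory=lambda: {
        ("NBC",): {"IgM": 0.92, "IgD": 0.08},
        ("MBC",): {"IgM": 0.30, "IgD": 0.04, "IgA1": 0.26, "IgA2": 0.10,
                   "IgG1": 0.20, "IgG2": 0.06, "IgG3": 0.04},
        ("MBC", "CD", "TI_inflamed"): {
            "IgM": 0.50, "IgD": 0.04, "IgA1": 0.14, "IgA2": 0.06,
            "IgG1": 0.18, "IgG2": 0.05, "IgG3": 0.03},
        ("GCBC",): {"IgM": 0.25, "IgA1": 0.30, "IgA2": 0.10,
                    "IgG1": 0.25, "IgG2": 0.06, "IgG3": 0.04},
        ("PC",): {"IgM": 0.12, "IgA1": 0.40, "IgA2": 0.18, "IgG1": 0.18,
                  "IgG2": 0.06, "IgG3": 0.04, "IgG4": 0.02},
        ("PC", "CD", "TI_inflamed"): {
            "IgM": 0.12, "IgA1": 0.20, "IgA2": 0.10, "IgG1": 0.42,
            "IgG2": 0.08, "IgG3": 0.05, "IgG4": 0.03},
    })
    #: fraction of PC clones sharing identity with an MBC clone, per group
    mbc_pc_sharing: dict = field(default_factory=lambda: {"CD": 0.30, "nonIBD": 0.05})
    #: extra probability mass on specific V genes per (cell_type, group)
    usage_boost: dict = field(default_factory=lambda: {
        ("MBC", "CD"): {"IGHV3-23": 0.08},
    })
    #: geometric decay of baseline V-gene usage weights
    usage_decay: float = 0.88
    n_v: int = 30
    n_j: int = 6
    v_length: int = 300
    junction_aa_length: int = 13
    #: per-donor resident-like MBC target fraction, Uniform(low, high)
    resident_fraction_range: dict = field(default_factory=lambda: {
        "CD": (0.05, 0.45), "nonIBD": (0.05, 0.25),
    })
    disease_score_intercept: float = 2.0
    disease_score_slope: float = 30.0
    disease_score_noise_sd: float = 1.5
    emit_light_chains: bool = False
    light_shm_scale: float = 0.8
    #: expression model: TI MBC/PC cells, background + IFN shift in inflamed
    expression_n_genes: int = 300
    expression_ifn_set_size: int = 30
    expression_ifn_shift: float = 0.8
    expression_noise_sd: float = 0.4
    expression_max_cells: int = 1500
    emit_expression: bool = True

    def validate(self) -> None:
        for key, probs in self.isotype_probs.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"isotype probabilities for {key} sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"negative isotype probability for {key}")
        for key, lam in self.shm_lambda.items():
            if lam < 0:
                raise ConfigError(f"negative SHM mean for {key}")
        for grp, s in self.mbc_pc_sharing.items():
            if not 0 <= s <= 1:
                raise ConfigError(f"sharing fraction for {grp} must be in [0,1], got {s}")
            if s > 0:
                sites = self.sites_by_group.get(grp, [])
                has_pc = any((site, "PC") in self.n_clones for site in sites)
                has_mbc = any((site, "MBC") in self.n_clones for site in sites)
                if has_pc and not has_mbc:
                    raise ConfigError(
                        f"group {grp}: sharing fraction {s} > 0 but the "
                        "composition has PC clones and no MBC clones"
                    )
        for p in self.clone_size_p.values():
            if not 0 < p <= 1:
                raise ConfigError("geometric clone-size parameter must be in (0,1]")


def _resolve(table: dict, cell_type: str, group: str, site: str):
    for key in ((cell_type, group, site), (cell_type, group), (cell_type,)):
        if key in table:
            return table[key]
    raise ConfigError(f"no value for stratum ({cell_type}, {group}, {site})")


@dataclass
class CohortTruth:
    """Generator ground truth: per-cell clone/type/mutation labels, per-donor
    parameters, and the realized config."""

    cells: pd.DataFrame
    donors: pd.DataFrame
    config: CohortConfig


@dataclass
class SyntheticCohort:
    """One realized synthetic study, as in-memory tables plus ground truth."""

    airr: pd.DataFrame
    metadata: pd.DataFrame
    donors: pd.DataFrame
    germline: dict
    expression: pd.DataFrame | None
    gene_sets: list
    truth: CohortTruth
    seed: int

    def write(self, out_dir) -> None:
        """Write the cohort as plain-text files (AIRR TSV, metadata TSV,
        donors TSV, germline FASTA, expression TSV, GMT, truth/ tables)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.airr.to_csv(out / "airr.tsv", sep="\t", index=False)
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        self.donors.to_csv(out / "donors.tsv", sep="\t", index=False)
        write_germline_fasta(self.germline, out / "germline.fasta")
        if self.expression is not None:
            self.expression.to_csv(out / "expr.tsv", sep="\t")
            write_gene_sets(self.gene_sets, out / "signatures.gmt")
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        self.truth.cells.to_csv(truth_dir / "cells.tsv", sep="\t", index=False)
        self.truth.donors.to_csv(truth_dir / "donors.tsv", sep="\t", index=False)
        cfg = {
            f.name: _jsonable(getattr(self.config, f.name))
            for f in dataclasses.fields(self.config)
        }
        (truth_dir / "config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True))

    @property
    def config(self) -> CohortConfig:
        return self.truth.config


def _jsonable(v):
    if isinstance(v, dict):
        return {"|".join(map(str, k)) if isinstance(k, tuple) else str(k): _jsonable(x)
                for k, x in v.items()}
    if isinstance(v, tuple):
        return list(v)
    return v


def build_germline(n_v: int = 30, n_j: int = 6, v_length: int = 300,
                   seed: int = 0, *, j_length: int = 48,
                   include_light: bool = False) -> dict[str, str]:
    """Random unambiguous-base germline segments named IMGT-style
    (``IGHV{family}-{n}*01``, ``IGHJ{n}*01``), deterministic per seed."""
    if n_v < 1 or n_j < 1:
        raise ConfigError("need at least one V and one J segment")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for i in range(n_v):
        if i < len(_V_GENE_NAMES):
            name = f"{_V_GENE_NAMES[i]}*01"
        else:
            name = f"IGHV{(i % 7) + 1}-{i + 50}*01"
        out[name] = "".join(rng.choice(_NT, size=v_length))
    for j in range(n_j):
        out[f"IGHJ{j + 1}*01"] = "".join(rng.choice(_NT, size=j_length))
    if include_light:
        for i in range(8):
            out[f"IGKV{i + 1}-1*01"] = "".join(rng.choice(_NT, size=v_length))
        for j in range(4):
            out[f"IGKJ{j + 1}*01"] = "".join(rng.choice(_NT, size=j_length))
    return out


def _usage_weights(v_names, decay, boost):
    w = decay ** np.arange(len(v_names))
    w = w / w.sum()
    if boost:
        genes = [strip_allele(v) for v in v_names]
        for gene, extra in boost.items():
            if gene not in genes:
                raise ConfigError(f"usage boost names unknown V gene {gene}")
            w[genes.index(gene)] += extra
        w = w / w.sum()
    return w


def _random_junction(rng, length, used: set) -> str:
    # conserved anchors: C ... W
    while True:
        core = "".join(rng.choice(_AA, size=length - 2))
        junc = "C" + core + "W"
        if junc not in used:
            used.add(junc)
            return junc


def _mutate(rng, germ_arr: np.ndarray, n_mut: int) -> str:
    """Place n_mut substitutions at distinct uniform positions; each
    substitution changes the base (shift by 1..3 in A<C<G<T order)."""
    seq = germ_arr.copy()
    if n_mut > 0:
        pos = rng.choice(seq.size, size=n_mut, replace=False)
        shift = rng.integers(1, 4, size=n_mut)
        seq[pos] = (seq[pos] + shift) % 4
    return "".join(_NT[seq])


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate one synthetic cohort under ``config`` (see module docstring).

    Identical config + seed reproduce every table byte-for-byte.
    """
    config = config if config is not None else default_cd_scenario()
    config.validate()
    rng = np.random.default_rng(seed)

    germline = build_germline(
        config.n_v, config.n_j, config.v_length,
        seed=int(rng.integers(2**31)),
        include_light=config.emit_light_chains,
    )
    v_names = [n for n in germline if n.startswith("IGHV")]
    j_names = [n for n in germline if n.startswith("IGHJ")]
    kv_names = [n for n in germline if n.startswith("IGKV")]
    kj_names = [n for n in germline if n.startswith("IGKJ")]
    nt_index = {c: i for i, c in enumerate(_NT)}
    germ_arrays = {
        name: np.array([nt_index[c] for c in seq], dtype=np.int8)
        for name, seq in germline.items()
    }

    airr_rows: list[dict] = []
    meta_rows: list[dict] = []
    donor_rows: list[dict] = []
    truth_rows: list[dict] = []
    truth_donor_rows: list[dict] = []

    for group in sorted(config.n_donors):
        n_share = config.mbc_pc_sharing.get(group, 0.0)
        for d in range(config.n_donors[group]):
            donor_id = f"{group}{d + 1:02d}"
            lo, hi = config.resident_fraction_range[group]
            resident_target = float(rng.uniform(lo, hi))
            used_junctions: set[str] = set()
            mbc_registry: list[tuple[str, str, str, str]] = []
            cell_counter = 0
            ti_mbc_total = 0
            ti_mbc_resident = 0

            sites = config.sites_by_group[group]
            # MBC clones first so the PC sharing registry is populated
            plan = []
            for ct in ("MBC", "GCBC", "PC", "NBC"):
                for site in sites:
                    if (site, ct) in config.n_clones:
                        plan.append((site, ct))

            for site, cell_type in plan:
                tissue, inflammation = SITES[site]
                n_clones = config.n_clones[(site, cell_type)]
                p_geom = config.clone_size_p.get(
                    (cell_type, group), config.clone_size_p[cell_type]
                )
                lam = _resolve(config.shm_lambda, cell_type, group, site)
                iso = _resolve(config.isotype_probs, cell_type, group, site)
                iso_names = sorted(iso)
                iso_p = np.array([iso[k] for k in iso_names])
                iso_p = iso_p / iso_p.sum()
                boost = config.usage_boost.get((cell_type, group))
                weights = _usage_weights(v_names, config.usage_decay, boost)
                gate = "naive" if cell_type == "NBC" else "antigen_experienced"

                sizes = rng.geometric(p_geom, size=n_clones)
                for k, size in enumerate(sizes):
                    shared = (
                        cell_type == "PC"
                        and mbc_registry
                        and rng.random() < n_share
                    )
                    if shared:
                        v_call, j_call, junc_aa, junc_nt = (
                            mbc_registry[rng.integers(len(mbc_registry))]
                        )
                    else:
                        v_call = v_names[rng.choice(len(v_names), p=weights)]
                        j_call = j_names[rng.integers(len(j_names))]
                        junc_aa = _random_junction(
                            rng, config.junction_aa_length, used_junctions
                        )
                        junc_nt = "".join(rng.choice(_NT, size=3 * len(junc_aa)))
                    if cell_type == "MBC":
                        mbc_registry.append((v_call, j_call, junc_aa, junc_nt))
                    clone_id = f"{donor_id}.{site}.{cell_type}.{k:04d}"
                    germ_arr = germ_arrays[v_call]
                    germ_seq = germline[v_call]

                    for _ in range(int(size)):
                        cell_id = f"{donor_id}_c{cell_counter:05d}"
                        cell_counter += 1
                        n_mut = int(min(rng.poisson(lam), config.v_length))
                        obs = _mutate(rng, germ_arr, n_mut)
                        isotype = iso_names[rng.choice(len(iso_names), p=iso_p)]
                        if cell_type == "MBC":
                            if site == "blood":
                                cluster = "MBC_circulating"
                            elif rng.random() < resident_target:
                                cluster = "MBC_resident_like"
                            else:
                                cluster = "MBC_conventional"
                            if tissue == "TI":
                                ti_mbc_total += 1
                                ti_mbc_resident += cluster == "MBC_resident_like"
                        else:
                            cluster = ""
                        airr_rows.append(dict(
                            sequence_id=f"{cell_id}_IGH",
                            cell_id=cell_id, locus="IGH",
                            v_call=v_call, j_call=j_call,
                            c_call=_ISOTYPE_TO_C_CALL[isotype],
                            junction=junc_nt, junction_aa=junc_aa,
                            sequence_alignment=obs,
                            germline_alignment=germ_seq,
                        ))
                        if config.emit_light_chains and kv_names:
                            kv = kv_names[rng.integers(len(kv_names))]
                            kj = kj_names[rng.integers(len(kj_names))]
                            n_mut_l = int(min(
                                rng.poisson(lam * config.light_shm_scale),
                                config.v_length,
                            ))
                            obs_l = _mutate(rng, germ_arrays[kv], n_mut_l)
                            junc_l = "C" + "".join(
                                rng.choice(_AA, size=config.junction_aa_length - 2)
                            ) + "F"
                            airr_rows.append(dict(
                                sequence_id=f"{cell_id}_IGK",
                                cell_id=cell_id, locus="IGK",
                                v_call=kv, j_call=kj, c_call="IGKC",
                                junction="".join(rng.choice(_NT, size=3 * len(junc_l))),
                                junction_aa=junc_l,
                                sequence_alignment=obs_l,
                                germline_alignment=germline[kv],
                            ))
                        meta_rows.append(dict(
                            cell_id=cell_id, donor_id=donor_id,
                            disease_group=group, tissue=tissue,
                            inflammation=inflammation, sorted_gate=gate,
                            cluster_label=cluster, cell_type=cell_type,
                        ))
                        truth_rows.append(dict(
                            cell_id=cell_id, donor_id=donor_id,
                            clone_id=clone_id, cell_type=cell_type,
                            cluster=cluster, site=site,
                            n_mutations_true=n_mut, isotype_true=isotype,
                        ))

            resident_prop = ti_mbc_resident / ti_mbc_total if ti_mbc_total else np.nan
            if group == "CD":
                score = (
                    config.disease_score_intercept
                    + config.disease_score_slope * resident_prop
                    + rng.normal(0.0, config.disease_score_noise_sd)
                )
                score = float(max(score, 0.5))
            else:
                score = None
            donor_rows.append(dict(
                donor_id=donor_id, disease_group=group,
                disease_score="" if score is None else round(score, 3),
            ))
            truth_donor_rows.append(dict(
                donor_id=donor_id, disease_group=group,
                resident_target=resident_target,
                resident_prop_ti=resident_prop,
                disease_score=np.nan if score is None else score,
            ))

    airr = pd.DataFrame(airr_rows)
    metadata = pd.DataFrame(meta_rows)
    donors = pd.DataFrame(donor_rows)
    truth = CohortTruth(
        cells=pd.DataFrame(truth_rows),
        donors=pd.DataFrame(truth_donor_rows),
        config=config,
    )

    expression, gene_sets = (None, [])
    if config.emit_expression:
        expression, gene_sets = _simulate_expression(config, metadata, rng)

    return SyntheticCohort(
        airr=airr, metadata=metadata, donors=donors, germline=germline,
        expression=expression, gene_sets=gene_sets, truth=truth, seed=seed,
    )


def _simulate_expression(config, metadata, rng):
    """TI MBC/PC expression: gene baselines + Gaussian noise, interferon-set
    columns shifted upward in inflamed-region cells."""
    sel = metadata[
        (metadata["tissue"] == "TI") & metadata["cell_type"].isin(["MBC", "PC"])
    ]
    cells = sel["cell_id"].tolist()
    if len(cells) > config.expression_max_cells:
        idx = rng.choice(len(cells), size=config.expression_max_cells, replace=False)
        sel = sel.iloc[np.sort(idx)]
        cells = sel["cell_id"].tolist()
    k = config.expression_ifn_set_size
    ifn1 = [f"IFI{i + 1:03d}" for i in range(k)]
    ifn2 = [f"GBP{i + 1:03d}" for i in range(k)]
    n_bg = max(config.expression_n_genes - 2 * k, 0)
    background = [f"BG{i + 1:04d}" for i in range(n_bg)]
    genes = ifn1 + ifn2 + background
    base = rng.uniform(0.5, 3.0, size=len(genes))
    mat = base + rng.normal(0.0, config.expression_noise_sd, size=(len(cells), len(genes)))
    inflamed = (sel["inflammation"] == "inflamed").to_numpy()
    ifn_cols = np.arange(2 * k)
    mat[np.ix_(inflamed, ifn_cols)] += config.expression_ifn_shift
    mat = np.clip(mat, 0.0, None)
    expr = pd.DataFrame(np.round(mat, 4), index=cells, columns=genes)
    sets = [
        GeneSet("IFN_I_RESPONSE", frozenset(ifn1)),
        GeneSet("IFN_II_RESPONSE", frozenset(ifn2)),
    ]
    return expr, sets


def default_cd_scenario() -> CohortConfig:
    """Canonical scenario: 8 CD donors with an inflamed TI region plus 7
    non-IBD controls, lower SHM in CD for all antigen-experienced subsets,
    an IgA->IgG1 isotype shift in inflamed-TI PCs, an IgM increase in
    inflamed-TI MBCs, higher MBC-PC clonotype sharing in CD, and disease
    scores positively tied to the resident-like MBC proportion."""
    return CohortConfig()


def simulate_proportion_score_pairs(
    n_donors: int,
    rho: float,
    seed: int = 0,
    *,
    prop_mean: float = 0.25,
    prop_sd: float = 0.08,
    score_mean: float = 8.0,
    score_sd: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Donor-level (proportion, disease score) pairs with designed Pearson
    correlation ``rho`` (bivariate normal; proportions clipped to (0, 1),
    which is a negligible perturbation at the default marginals).

    This is the light-weight generator used for association calibration:
    type-I error under ``rho=0`` and recovery of a designed ``rho``.
    """
    if not -1 <= rho <= 1:
        raise ConfigError(f"rho must be in [-1, 1], got {rho}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_donors, 2))
    x = z[:, 0]
    y = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
    props = np.clip(prop_mean + prop_sd * x, 1e-3, 1 - 1e-3)
    scores = score_mean + score_sd * y
    return props, scores
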