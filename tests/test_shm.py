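"""SHM quantification, naive-threshold calibration, isotype and MBC calls."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bcrpipe as bp
from bcrpipe.exceptions import (
    CalibrationError,
    DegenerateAlignmentError,
    InsufficientDataError,
)
from conftest import tiny_config


def chain(obs, germ, sid="s1"):
    return bp.ChainRecord(
        sequence_id=sid, cell_id="c1", locus="IGH",
        v_call="IGHV1-2*01", j_call="IGHJ1*01", c_call="IGHM",
        junction_aa="CARW", junction_nt="TGT",
        sequence_alignment=obs, germline_alignment=germ,
    )


def brute_force_count(obs, germ):
    """Independent per-position comparator (the oracle)."""
    n_mut = n_comp = 0
    for a, b in zip(obs.upper(), germ.upper()):
        if a in "ACGT" and b in "ACGT":
            n_comp += 1
            n_mut += a != b
    return n_mut, n_comp


class TestCountMutations:
    @pytest.mark.parametrize(
        "obs,germ,n_mut,n_comp",
        [
            ("ATGCATGC", "ATGCATGC", 0, 8),
            ("ATGAATGC", "ATGCATGC", 1, 8),
            ("ATGNATGC", "ATGCATGC", 0, 7),
            ("A-GCATGC", "ATGCATGC", 0, 7),
            ("ATGC.TGC", "ATGCATGC", 0, 7),
            ("TTTT", "AAAA", 4, 4),
        ],
    )
    def test_examples(self, obs, germ, n_mut, n_comp):
        p = bp.count_mutations(chain(obs, germ))
        assert (p.n_mutations, p.comparable_length) == (n_mut, n_comp)
        assert p.mutation_rate == pytest.approx(n_mut / n_comp)

    def test_rate_of_single_mismatch(self):
        assert bp.count_mutations(chain("ATGAATGC", "ATGCATGC")).mutation_rate == 0.125

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        alphabet = np.array(list("ACGTN.-"))
        for _ in range(1000):
            length = rng.integers(1, 80)
            obs = "".join(rng.choice(alphabet, size=length, p=[.2]*4 + [.1, .05, .05]))
            germ = "".join(rng.choice(alphabet, size=length, p=[.2]*4 + [.1, .05, .05]))
            n_mut, n_comp = brute_force_count(obs, germ)
            if n_comp == 0:
                with pytest.raises(DegenerateAlignmentError):
                    bp.count_mutations(chain(obs, germ))
                continue
            p = bp.count_mutations(chain(obs, germ))
            assert (p.n_mutations, p.comparable_length) == (n_mut, n_comp)

    def test_extra_mismatch_adds_exactly_one(self):
        base = chain("ATGCATGC", "ATGCATGC")
        extended = chain("ATGCATGCT", "ATGCATGCA")
        assert (
            bp.count_mutations(extended).n_mutations
            == bp.count_mutations(base).n_mutations + 1
        )

    def test_degenerate_alignment_errors(self):
        with pytest.raises(DegenerateAlignmentError, match="s1"):
            bp.count_mutations(chain("NNNN", "ACGT"))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            bp.count_mutations(chain("ACG", "ACGT"))


class TestNaiveThreshold:
    def test_nearest_rank_example(self):
        counts = [0] * 98 + [1, 2]
        t = bp.calibrate_naive_threshold(counts, 0.99)
        assert t.threshold_count == 1
        assert t.n_naive_chains == 100

    def test_all_zero_counts(self):
        assert bp.calibrate_naive_threshold([0] * 60, 0.99).threshold_count == 0

    def test_quantile_one_gives_maximum(self):
        t = bp.calibrate_naive_threshold([0, 0, 5], 1.0, min_calibration_n=3)
        assert t.threshold_count == 5

    def test_too_few_chains_raises(self):
        with pytest.raises(CalibrationError, match="fallback"):
            bp.calibrate_naive_threshold([0] * 10, 0.99)

    @given(
        counts=st.lists(st.integers(0, 20), min_size=5, max_size=200),
        q=st.tuples(st.floats(0.05, 1.0), st.floats(0.05, 1.0)),
    )
    def test_raising_quantile_never_lowers_threshold(self, counts, q):
        lo, hi = sorted(q)
        t_lo = bp.calibrate_naive_threshold(counts, lo, min_calibration_n=1)
        t_hi = bp.calibrate_naive_threshold(counts, hi, min_calibration_n=1)
        assert t_hi.threshold_count >= t_lo.threshold_count

    @given(counts=st.lists(st.integers(0, 30), min_size=20, max_size=500))
    def test_nearest_rank_guarantee(self, counts):
        """At most (1 - q) of the calibration chains strictly exceed the
        threshold."""
        q = 0.9
        t = bp.calibrate_naive_threshold(counts, q, min_calibration_n=1)
        frac_above = np.mean(np.asarray(counts) > t.threshold_count)
        assert frac_above <= 1 - q + 1e-12


class TestIsotype:
    @pytest.mark.parametrize(
        "c_call,isotype,iso_class,switched",
        [
            ("IGHG1", "IgG1", "IgG", True),
            ("ighg1", "IgG1", "IgG", True),
            ("IGHM", "IgM", "IgM", False),
            ("IGHD", "IgD", "IgD", False),
            ("IGHA2*01", "IgA2", "IgA", True),
            ("IGHE", "IgE", "IgE", True),
            ("", "unknown", "unknown", False),
            ("IGKC", "unknown", "unknown", False),
        ],
    )
    def test_prefix_calls(self, c_call, isotype, iso_class, switched):
        call = bp.call_isotype(c_call)
        assert (call.isotype, call.isotype_class, call.class_switched) == (
            isotype, iso_class, switched,
        )


class TestClassifyMbc:
    threshold = bp.NaiveThreshold(2, 0.99, 100)

    def test_switched_unmutated_is_mbc(self):
        p = bp.MutationProfile("s", 0, 100)
        assert bp.classify_mbc(p, bp.call_isotype("IGHG1"), self.threshold) == "MBC"

    def test_mutated_igm_is_mbc(self):
        p = bp.MutationProfile("s", 5, 100)
        assert bp.classify_mbc(p, bp.call_isotype("IGHM"), self.threshold) == "MBC"

    def test_unmutated_igm_is_naive_like(self):
        p = bp.MutationProfile("s", 0, 100)
        assert bp.classify_mbc(p, bp.call_isotype("IGHM"), self.threshold) == "naive_like"

    def test_igd_subthreshold_is_naive_like(self):
        p = bp.MutationProfile("s", 1, 100)
        assert bp.classify_mbc(p, bp.call_isotype("IGHD"), self.threshold) == "naive_like"

    @given(thr=st.integers(0, 50), n_mut=st.integers(0, 50))
    def test_switched_cell_never_naive_like(self, thr, n_mut):
        t = bp.NaiveThreshold(thr, 0.99, 100)
        p = bp.MutationProfile("s", n_mut, 60)
        assert bp.classify_mbc(p, bp.call_isotype("IGHA1"), t) == "MBC"


class TestSummaries:
    def test_mean_of_two_cells(self, analysis):
        import pandas as pd

        cells = pd.DataFrame(
            {"cell_id": ["a", "b"], "grp": ["g", "g"]}
        )
        profiles = pd.DataFrame(
            {"cell_id": ["a", "b"], "n_mutations": [0, 10],
             "mutation_rate": [0.0, 0.1]}
        )
        out = bp.shm_summary(cells, profiles, ["grp"])
        assert out.loc[0, "mean_rate"] == pytest.approx(0.05)
        assert out.loc[0, "n"] == 2

    def test_unknown_grouping_key(self, analysis):
        with pytest.raises(KeyError, match="nope"):
            bp.shm_summary(analysis.cells, analysis.chains, ["nope"])

    def test_disease_contrast_recovers_design(self, cohort, analysis):
        """CD MBC mutation mean below non-IBD, each within 3 SE of its
        designed Poisson mean."""
        cells = analysis.cells
        mbc = cells[cells["cell_type"] == "MBC"]
        out = bp.shm_summary(mbc, analysis.chains, ["disease_group"])
        out = out.set_index("disease_group")
        lam = cohort.config.shm_lambda
        for grp in ("CD", "nonIBD"):
            design = lam[("MBC", grp)]
            n = out.loc[grp, "n"]
            se = np.sqrt(design / n)
            assert abs(out.loc[grp, "mean_count"] - design) < 3 * se
        assert out.loc["CD", "mean_count"] < out.loc["nonIBD", "mean_count"]


class TestIncrement:
    def make_tables(self, mbc_counts, pc_counts):
        import pandas as pd

        rows, profs = [], []
        for i, c in enumerate(mbc_counts):
            rows.append(dict(cell_id=f"m{i}", donor_id="d1", tissue="TI",
                             inflammation="non_inflamed", cell_type="MBC"))
            profs.append(dict(cell_id=f"m{i}", n_mutations=c))
        for i, c in enumerate(pc_counts):
            rows.append(dict(cell_id=f"p{i}", donor_id="d1", tissue="TI",
                             inflammation="non_inflamed", cell_type="PC"))
            profs.append(dict(cell_id=f"p{i}", n_mutations=c))
        return pd.DataFrame(rows), pd.DataFrame(profs)

    def test_simple_increment(self):
        cells, profiles = self.make_tables([4, 6], [10, 12])
        inc = bp.mbc_to_pc_increment(cells, profiles, "d1", "non_inflamed", min_cells=2)
        assert inc.value == pytest.approx(6.0)

    def test_identical_distributions_give_zero(self):
        cells, profiles = self.make_tables([3, 5, 7], [3, 5, 7])
        inc = bp.mbc_to_pc_increment(cells, profiles, "d1", "non_inflamed", min_cells=3)
        assert inc.value == pytest.approx(0.0)

    def test_insufficient_cells_is_missing_with_reason(self):
        cells, profiles = self.make_tables([4], [10, 12])
        with pytest.raises(InsufficientDataError, match="d1"):
            bp.mbc_to_pc_increment(cells, profiles, "d1", "non_inflamed", min_cells=2)

    def test_region_ordering_recovered_across_replicates(self):
        """Designed increment 6 (non-inflamed) vs 2 (inflamed): the ordering
        is recovered in >= 95% of seeded replicates."""
        cfg = tiny_config(n_donors={"CD": 1, "nonIBD": 0})
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            c = bp.simulate_cohort(cfg, seed=seed)
            profiles = bp.profile_chains(bp.records_from_frame(c.airr))
            inc_n = bp.mbc_to_pc_increment(c.metadata, profiles, "CD01", "non_inflamed")
            inc_i = bp.mbc_to_pc_increment(c.metadata, profiles, "CD01", "inflamed")
            hits += inc_n.value > inc_i.value
        assert hits >= 0.95 * n_rep
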