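"""Signature scoring (bin-matched controls), proportions, association and
the group-comparison tests."""

import numpy as np
import pandas as pd
import pytest

import bcrpipe as bp
from bcrpipe.exceptions import (
    InsufficientDataError,
    PairingError,
    ScoringError,
    UndefinedStatisticError,
)


def random_matrix(n_cells=2000, n_genes=500, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    base = rng.uniform(0.5, 3.0, size=n_genes)
    mat = base + rng.normal(0, 0.4, size=(n_cells, n_genes))
    return pd.DataFrame(
        np.clip(mat, 0, None),
        index=[f"c{i}" for i in range(n_cells)],
        columns=genes,
    )


class TestScoreSignature:
    def test_exchangeable_gene_set_scores_near_zero(self):
        """Gene-set genes drawn at random from the matrix are exchangeable
        with their bin-matched controls: mean score ~ 0."""
        expr = random_matrix()
        rng = np.random.default_rng(1)
        genes = rng.choice(expr.columns, size=50, replace=False)
        gs = bp.GeneSet("NULLSET", frozenset(genes))
        scores = bp.score_signature(expr, gs, seed=2)
        assert abs(scores["score"].mean()) < 0.02

    def test_constructed_shift_recovered(self):
        """A +1 log-unit shift of the gene set in 10% of cells is read out
        as ~+1 in those cells and ~0 elsewhere (a small shifted fraction
        keeps gene means, hence bin assignments, near baseline)."""
        expr = random_matrix(seed=5)
        genes = list(expr.columns[:40])
        shifted_cells = expr.index[:200]
        expr.loc[shifted_cells, genes] += 1.0
        gs = bp.GeneSet("SHIFT", frozenset(genes))
        scores = bp.score_signature(expr, gs, seed=3).set_index("cell_id")["score"]
        assert scores.loc[shifted_cells].mean() == pytest.approx(1.0, abs=0.15)
        assert scores.drop(shifted_cells).mean() == pytest.approx(0.0, abs=0.15)

    def test_shift_contrast_invariant_to_shifted_fraction(self):
        """Even when half the cells are shifted (which moves the gene-set
        genes into higher expression bins), the shifted-vs-unshifted score
        contrast still equals the designed shift."""
        expr = random_matrix(seed=5)
        genes = list(expr.columns[:40])
        shifted_cells = expr.index[:1000]
        expr.loc[shifted_cells, genes] += 1.0
        gs = bp.GeneSet("SHIFT", frozenset(genes))
        scores = bp.score_signature(expr, gs, seed=3).set_index("cell_id")["score"]
        contrast = scores.loc[shifted_cells].mean() - scores.drop(shifted_cells).mean()
        assert contrast == pytest.approx(1.0, abs=0.1)

    def test_seed_determinism(self):
        expr = random_matrix(n_cells=200, n_genes=200)
        gs = bp.GeneSet("S", frozenset(expr.columns[:20]))
        a = bp.score_signature(expr, gs, seed=7)
        b = bp.score_signature(expr, gs, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_gene_order_invariance(self):
        expr = random_matrix(n_cells=200, n_genes=200)
        gs = bp.GeneSet("S", frozenset(expr.columns[:20]))
        a = bp.score_signature(expr, gs, seed=7)
        shuffled = expr.sample(frac=1, axis=1, random_state=11)
        b = bp.score_signature(shuffled, gs, seed=7)
        assert np.allclose(a["score"], b["score"])

    def test_absent_gene_set_errors(self):
        expr = random_matrix(n_cells=50, n_genes=50)
        with pytest.raises(ScoringError, match="MISSING"):
            bp.score_signature(expr, bp.GeneSet("MISSING", frozenset({"NOPE"})))

    def test_agrees_with_scanpy_scorer(self):
        """Independent cross-check: per-cell scores correlate strongly with
        scanpy's expression-bin control scorer on shifted data."""
        sc = pytest.importorskip("scanpy")
        import anndata as ad

        expr = random_matrix(n_cells=400, n_genes=300, seed=9)
        genes = list(expr.columns[:30])
        expr.loc[expr.index[:200], genes] += 1.0
        gs = bp.GeneSet("S", frozenset(genes))
        ours = bp.score_signature(expr, gs, seed=0).set_index("cell_id")["score"]

        adata = ad.AnnData(expr.to_numpy())
        adata.obs_names = expr.index
        adata.var_names = expr.columns
        sc.tl.score_genes(adata, genes, score_name="scanpy_score", ctrl_size=100,
                          n_bins=25, random_state=0)
        r = np.corrcoef(ours.to_numpy(), adata.obs["scanpy_score"].to_numpy())[0, 1]
        assert r > 0.95

    def test_ifn_shift_in_synthetic_cohort(self, cohort):
        """Inflamed-region cells score higher on the interferon signature."""
        scores = bp.score_signature(cohort.expression, cohort.gene_sets[0], seed=0)
        merged = scores.merge(
            cohort.metadata[["cell_id", "inflammation"]], on="cell_id"
        )
        means = merged.groupby("inflammation")["score"].mean()
        assert means["inflamed"] > means["non_inflamed"] + 0.3


class TestProportions:
    cells = pd.DataFrame(
        dict(
            cell_id=[f"c{i}" for i in range(12)],
            donor_id=["d1"] * 12,
            tissue=["TI"] * 12,
            cell_type=["MBC"] * 12,
            cluster_label=["cl2"] * 3 + ["cl1"] * 9,
        )
    )

    def test_simple_fraction(self):
        out = bp.subset_proportions(
            self.cells,
            numerator={"cell_type": "MBC", "cluster_label": "cl2"},
            denominator={"cell_type": "MBC"},
        )
        assert out.loc[0, "proportion"] == pytest.approx(0.25)

    def test_non_nesting_filters_error(self):
        with pytest.raises(ValueError, match="nest"):
            bp.subset_proportions(
                self.cells,
                numerator={"cluster_label": ["cl1", "cl2"]},
                denominator={"cluster_label": "cl1"},
            )

    def test_sibling_proportions_sum_to_one(self):
        parts = [
            bp.subset_proportions(
                self.cells,
                numerator={"cell_type": "MBC", "cluster_label": cl},
                denominator={"cell_type": "MBC"},
            ).loc[0, "proportion"]
            for cl in ("cl1", "cl2")
        ]
        assert sum(parts) == pytest.approx(1.0)


class TestAssociation:
    def test_collinear_r_is_one(self):
        res = bp.correlate_with_disease([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4])
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope == pytest.approx(10.0)

    def test_constant_proportions_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            bp.correlate_with_disease([0.2, 0.2, 0.2], [1, 2, 3])

    def test_fewer_than_three_donors_errors(self):
        with pytest.raises(InsufficientDataError):
            bp.correlate_with_disease([0.1, 0.2], [1, 2])

    def test_matches_closed_form_pearson(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = bp.correlate_with_disease(x, y)
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res.pearson_r == pytest.approx(r, abs=1e-12)

    def test_designed_correlation_recovered(self):
        """Mean estimated r over seeded replicates is close to the designed
        donor-level correlation (quick version of the calibration run)."""
        rs = []
        for seed in range(50):
            props, scores = bp.simulate_proportion_score_pairs(9, 0.8, seed=seed)
            rs.append(bp.correlate_with_disease(props, scores).pearson_r)
        assert np.mean(rs) == pytest.approx(0.8, abs=0.1)


class TestCompareGroups:
    def test_identical_groups_t_zero_p_one(self):
        res = bp.compare_groups([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_equal_groups_anova_f_zero(self):
        res = bp.compare_groups(
            [1, 2, 3] * 3, ["a"] * 3 + ["b"] * 3 + ["c"] * 3, test="anova_tukey"
        )
        assert res.statistic == pytest.approx(0.0)

    def test_tukey_adjusted_not_below_pooled_pairwise_t(self):
        """Family-wise Tukey p is never below the unadjusted pairwise t
        computed with the same pooled within-group variance and error df."""
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 10) for m in (0, 0.5, 1)]
        values = np.concatenate(groups)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = bp.compare_groups(values, labels, test="anova_tukey")
        n = 10
        df_err = len(values) - 3
        msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_err
        by_name = dict(zip("abc", groups))
        for row in res.pairwise.itertuples():
            t = abs(row.mean_diff) / np.sqrt(msw * (2 / n))
            raw = 2 * sps.t.sf(t, df_err)
            assert row.p_adjusted >= raw - 1e-12

    def test_mann_whitney_two_sided(self):
        res = bp.compare_groups([1, 2, 3], ["a", "a", "b"], test="mann_whitney")
        assert 0 < res.p_value <= 1

    def test_paired_t_unmatched_donors_listed(self):
        with pytest.raises(PairingError, match="d3"):
            bp.compare_groups(
                [1, 2, 3, 4],
                ["x", "x", "y", "y"],
                test="paired_t",
                pair_keys=["d1", "d2", "d1", "d3"],
            )

    def test_bh_adjustment_not_below_raw(self):
        p = [0.01, 0.04, 0.2, 0.9]
        adj = bp.benjamini_hochberg(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
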