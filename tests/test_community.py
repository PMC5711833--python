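"""Community-stage operations against brute-force and scikit-bio oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import skbio
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from thermosip import (
    bray_curtis,
    correlation_heatmap,
    enrichment_screen,
    pcoa,
    permanova,
    rarefy,
)
from thermosip.community import benjamini_hochberg


def random_counts(rng, n_taxa=5, n_samples=8, depth=200):
    cols = {f"s{j}": rng.multinomial(depth, rng.dirichlet(np.ones(n_taxa)))
            for j in range(n_samples)}
    return pd.DataFrame(cols, index=[f"t{i}" for i in range(n_taxa)])


class TestRarefy:
    def test_columns_sum_exactly_to_depth(self, rng):
        table = random_counts(rng, n_taxa=20, depth=500)
        out = rarefy(table, depth=100, seed=1)
        assert (out.sum(axis=0) == 100).all()

    def test_full_depth_preserves_column(self, rng):
        table = random_counts(rng, n_taxa=10, depth=300)
        out = rarefy(table, depth=300, seed=1)
        pd.testing.assert_frame_equal(out, table)

    def test_single_otu_sample(self):
        table = pd.DataFrame({"s": [50, 0, 0]}, index=list("abc"))
        assert rarefy(table, depth=20, seed=0)["s"].tolist() == [20, 0, 0]

    def test_seed_determinism(self, rng):
        table = random_counts(rng, n_taxa=30, depth=1000)
        pd.testing.assert_frame_equal(rarefy(table, 400, seed=7), rarefy(table, 400, seed=7))

    def test_shallow_sample_dropped_with_warning(self):
        table = pd.DataFrame({"deep": [80, 120], "shallow": [5, 5]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="shallow"):
            out = rarefy(table, depth=50, seed=0)
        assert list(out.columns) == ["deep"]

    def test_hypergeometric_expectation(self):
        # expected rarefied count is depth * count_i / total
        table = pd.DataFrame({"s": [100, 300, 600]}, index=list("abc"))
        draws = np.stack([rarefy(table, 100, seed=s)["s"].to_numpy() for s in range(100)])
        assert np.allclose(draws.mean(axis=0), [10, 30, 60], rtol=0.02, atol=0.5)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        tbl = pd.DataFrame({"a": [5, 5, 0], "b": [5, 5, 0], "c": [0, 0, 10]},
                           index=list("xyz"))
        d = bray_curtis(tbl)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == 1.0
        assert np.allclose(np.diag(d), 0.0)

    def test_hand_value(self):
        tbl = pd.DataFrame({"a": [0.5, 0.5, 0.0], "b": [0.25, 0.25, 0.5]})
        assert bray_curtis(tbl).loc["a", "b"] == pytest.approx(0.5, rel=1e-12)

    def test_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(5):
            tbl = random_counts(rng, n_taxa=5, n_samples=8)
            d = bray_curtis(tbl)
            x = tbl.to_numpy(float)
            x = x / x.sum(axis=0, keepdims=True)
            for i, a in enumerate(tbl.columns):
                for j, b in enumerate(tbl.columns):
                    expected = 1 - 2 * np.minimum(x[:, i], x[:, j]).sum() / (
                        x[:, i].sum() + x[:, j].sum()
                    )
                    assert d.iloc[i, j] == pytest.approx(expected, abs=1e-12)
            assert np.allclose(d, d.T, atol=1e-12)
            assert ((d.to_numpy() >= -1e-12) & (d.to_numpy() <= 1 + 1e-12)).all()

    def test_all_zero_sample_rejected(self):
        tbl = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="zero"):
            bray_curtis(tbl)


class TestPcoa:
    def test_euclidean_line_reconstruction(self):
        # 1-D points: classical MDS is exact, axis 1 restores all distances
        pts = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = pcoa(pd.DataFrame(d, index=list("abcde"), columns=list("abcde")))
        c1 = res.coordinates["PC1"].to_numpy()
        rec = np.abs(c1[:, None] - c1[None, :])
        assert np.allclose(rec, d, atol=1e-8)

    def test_two_point_embedding(self):
        d = pd.DataFrame([[0, 0.6], [0.6, 0]], index=["a", "b"], columns=["a", "b"])
        coords = pcoa(d).coordinates["PC1"].to_numpy()
        assert np.allclose(np.sort(np.abs(coords)), [0.3, 0.3])

    def test_eigenvalue_sum_equals_centered_trace(self, rng):
        tbl = random_counts(rng, n_taxa=6, n_samples=7)
        d = bray_curtis(tbl)
        res = pcoa(d)
        dm = d.to_numpy()
        n = dm.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = j @ (-0.5 * dm**2) @ j
        all_evals = np.concatenate([res.eigenvalues, res.negative_eigenvalues])
        assert all_evals.sum() == pytest.approx(np.trace(b), rel=1e-8, abs=1e-10)

    def test_against_scikit_bio(self, rng):
        tbl = random_counts(rng, n_taxa=8, n_samples=6)
        d = bray_curtis(tbl)
        mine = pcoa(d, k=2).coordinates.to_numpy()
        ref = skbio_pcoa(skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)))
        ref_xy = ref.samples.iloc[:, :2].to_numpy()
        assert np.allclose(np.abs(mine), np.abs(ref_xy), atol=1e-8)

    def test_too_many_axes(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="positive eigenvalues"):
            pcoa(d, k=2)


class TestPermanova:
    def toy(self):
        ids = [f"s{i}" for i in range(6)]
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        return (pd.DataFrame(d, index=ids, columns=ids),
                pd.DataFrame({"grp": ["a"] * 3 + ["b"] * 3}, index=ids))

    def test_separated_groups_exact_enumeration(self):
        d, meta = self.toy()
        res = permanova(d, meta, terms="grp", n_permutations=10_000)
        assert res.exact
        assert res.table.loc[0, "p_value"] == pytest.approx(0.1, abs=1e-12)

    def test_r2_decomposition_sums_to_one(self, rng):
        tbl = random_counts(rng, n_taxa=10, n_samples=12)
        d = bray_curtis(tbl)
        meta = pd.DataFrame({"f1": (["a", "b"] * 6), "f2": ["x"] * 6 + ["y"] * 6},
                            index=d.index)
        res = permanova(d, meta, terms=["f1", "f2"], n_permutations=99, seed=3)
        assert res.table["R2"].sum() == pytest.approx(1.0, rel=1e-10)

    def test_pseudo_f_matches_scikit_bio_oneway(self, rng):
        tbl = random_counts(rng, n_taxa=10, n_samples=10)
        d = bray_curtis(tbl)
        meta = pd.DataFrame({"grp": ["a"] * 5 + ["b"] * 5}, index=d.index)
        mine = permanova(d, meta, terms="grp", n_permutations=99, seed=0)
        ref = skbio_permanova(skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
                              grouping=meta["grp"].to_numpy(), permutations=99)
        assert mine.table.loc[0, "pseudo_F"] == pytest.approx(ref["test statistic"], rel=1e-8)

    def test_exact_and_sampled_p_agree(self, rng):
        tbl = random_counts(rng, n_taxa=8, n_samples=7)
        d = bray_curtis(tbl)
        meta = pd.DataFrame({"grp": ["a"] * 3 + ["b"] * 4}, index=d.index)
        exact = permanova(d, meta, terms="grp", n_permutations=7000, seed=0)
        assert exact.exact
        sampled = permanova(d, meta, terms="grp", n_permutations=999, seed=1)
        # Monte-Carlo error ~ 3*sqrt(p(1-p)/999)
        p = exact.table.loc[0, "p_value"]
        assert abs(sampled.table.loc[0, "p_value"] - p) < 3 * np.sqrt(p * (1 - p) / 999) + 1e-3

    def test_null_pvalues_uniform(self, rng):
        # no group structure: permutation p-values are uniform on (0, 1].
        # A 3+3 design has 10 distinct splits, so exact p lives on the grid
        # {0.1, ..., 1.0}; randomized smoothing by the grid spacing makes the
        # null distribution exactly continuous-uniform for the KS test.
        pvals = []
        for _ in range(100):
            tbl = random_counts(rng, n_taxa=6, n_samples=6, depth=100)
            d = bray_curtis(tbl)
            meta = pd.DataFrame({"grp": ["a"] * 3 + ["b"] * 3}, index=d.index)
            pvals.append(permanova(d, meta, terms="grp", n_permutations=10_000).table.loc[0, "p_value"])
        smoothed = np.asarray(pvals) - rng.uniform(0, 0.1, size=len(pvals))
        assert kstest(smoothed, "uniform").statistic < 0.163  # KS alpha=0.01, n=100

    def test_singleton_level_rejected(self):
        d, meta = self.toy()
        meta2 = meta.copy()
        meta2.iloc[0, 0] = "c"
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(d, meta2, terms="grp")

    def test_blocked_permutations_respect_blocks(self):
        d, meta = self.toy()
        meta = meta.assign(block=["r1", "r2", "r3"] * 2)
        res = permanova(d, meta, terms="grp", n_permutations=10_000, blocks="block")
        assert res.exact
        # within-block swaps: 2^3 = 8 distinct permutations
        assert res.n_permutations == 8


class TestEnrichmentScreen:
    def test_identical_groups_zero_fold_change(self, rng):
        tbl = random_counts(rng, n_taxa=12, n_samples=4)
        dup = pd.concat([tbl, tbl.add_suffix("_d")], axis=1)
        res = enrichment_screen(dup, list(tbl.columns),
                                [f"{c}_d" for c in tbl.columns], seed=0)
        assert np.allclose(res.table["log2_fold_change"], 0.0, atol=1e-12)
        assert not res.table["significant"].any()

    def test_bh_oracle_three_otu_toy(self):
        p = np.array([0.01, 0.04, 0.03])
        adj = benjamini_hochberg(p)
        # ordered: 0.01*3/1=0.03, 0.03*3/2=0.045, 0.04*3/3=0.04 -> capped 0.04
        assert np.allclose(adj, [0.03, 0.04, 0.04])
        assert (adj >= p - 1e-15).all()

    def test_qvalues_monotone_in_raw_p(self, rng):
        tbl = random_counts(rng, n_taxa=30, n_samples=8, depth=500)
        res = enrichment_screen(tbl, [f"s{j}" for j in range(4)],
                                [f"s{j}" for j in range(4, 8)], seed=2)
        t = res.table.sort_values("p_value")
        assert (np.diff(t["q_value"]) >= -1e-12).all()
        assert (t["q_value"] >= t["p_value"] - 1e-12).all()


class TestCorrelations:
    def make_enrichment(self, otus):
        from thermosip.community import EnrichmentResult

        tbl = pd.DataFrame({"log2_fold_change": np.linspace(2, -2, len(otus)),
                            "statistic": np.zeros(len(otus)),
                            "p_value": np.ones(len(otus)),
                            "q_value": np.ones(len(otus)),
                            "direction": np.ones(len(otus), dtype=int),
                            "significant": np.ones(len(otus), dtype=bool)}, index=otus)
        return EnrichmentResult(tbl, "toy", 0.01, 0, 0)

    def test_perfect_and_inverse_monotone(self):
        ids = [f"s{i}" for i in range(5)]
        counts = pd.DataFrame(
            {s: [10 * (i + 1), 10 * (5 - i), 7] for i, s in enumerate(ids)},
            index=["up", "down", "flat"],
        )
        soil = pd.DataFrame({"var": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=ids)
        enr = self.make_enrichment(["up", "down", "flat"])
        out = correlation_heatmap(enr, counts, soil, cluster_columns=False)
        assert out.loc["up", "var"] == pytest.approx(1.0)
        assert out.loc["down", "var"] == pytest.approx(-1.0)

    def test_sum_d_squared_formula_oracle(self, rng):
        # Spearman rho via 1 - 6*sum(d^2)/(n(n^2-1)) on tie-free vectors
        ids = [f"s{i}" for i in range(5)]
        counts = pd.DataFrame({s: [c, 50 - c] for s, c in zip(ids, [3, 9, 27, 14, 40])},
                              index=["otu", "rest"])
        y = np.array([2.0, 7.0, 1.0, 9.0, 4.0])
        soil = pd.DataFrame({"var": y}, index=ids)
        enr = self.make_enrichment(["otu"])
        out = correlation_heatmap(enr, counts, soil, cluster_columns=False)
        rel = counts.loc["otu"].to_numpy() / counts.sum(axis=0).to_numpy()
        dr = pd.Series(rel).rank().to_numpy() - pd.Series(y).rank().to_numpy()
        expected = 1 - 6 * (dr**2).sum() / (5 * 24)
        assert out.loc["otu", "var"] == pytest.approx(expected, rel=1e-12)

    def test_constant_variable_is_nan(self):
        ids = [f"s{i}" for i in range(4)]
        counts = pd.DataFrame({s: [i + 1, 5] for i, s in enumerate(ids)},
                              index=["otu", "rest"])
        soil = pd.DataFrame({"const": np.ones(4)}, index=ids)
        enr = self.make_enrichment(["otu"])
        out = correlation_heatmap(enr, counts, soil, cluster_columns=False)
        assert np.isnan(out.loc["otu", "const"])

    def test_rows_ordered_by_fold_change(self, rng):
        tbl = random_counts(rng, n_taxa=6, n_samples=5)
        soil = pd.DataFrame({"v1": rng.normal(size=5), "v2": rng.normal(size=5)},
                            index=tbl.columns)
        enr = self.make_enrichment(list(tbl.index[::-1]))
        out = correlation_heatmap(enr, tbl, soil, cluster_columns=False)
        fc = enr.table.loc[out.index, "log2_fold_change"]
        assert (np.diff(fc) <= 0).all()
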