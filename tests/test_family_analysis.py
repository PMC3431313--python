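import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import cophenet

from h1blocks.errors import ConfigurationError, ValidationError
from h1blocks.family_analysis import (ClusterSet, FamilyCatalog,
                                      binding_level_comparison,
                                      binomial_enrichment, detect_clusters,
                                      family_enrichment, family_zscore_matrix,
                                      hierarchical_order,
                                      FamilyEnrichmentReport)
from h1blocks.target_annotation import TargetTable
from .conftest import make_annotation, make_pvalues


def binomial_upper_tail_oracle(k: int, n: int, pi: float) -> float:
    """Independent brute-force pmf summation of P(X >= k).

    Summed in 50-digit arithmetic so the oracle's own rounding never limits
    the comparison.
    """
    import mpmath
    with mpmath.workdps(50):
        p = mpmath.mpf(pi)
        total = mpmath.mpf(0)
        term = mpmath.binomial(n, k) * p**k * (1 - p)**(n - k)
        for j in range(k, n + 1):
            total += term
            if term < total * mpmath.mpf("1e-45") and j > n * pi:
                break
            term = term * (n - j) / (j + 1) * p / (1 - p) if j < n else term
        return float(total)


def run_length_cluster_oracle(families: list, min_run: int = 3) -> list[tuple]:
    """Brute-force scan: maximal runs of equal non-null family labels."""
    runs = []
    i = 0
    while i < len(families):
        f = families[i]
        j = i
        while j < len(families) and families[j] == f:
            j += 1
        if f is not None and j - i >= min_run:
            runs.append((f, i, j))
        i = j
    return runs


def annotation_from_family_order(order, chrom="chr1"):
    genes = [(chrom, 1_000 * i, 1_000 * i + 500, "+", f"g{i}", fam)
             for i, fam in enumerate(order)]
    return make_annotation(genes, chrom_sizes={chrom: 1_000 * len(order) + 10_000})


class TestDetectClusters:
    def test_simple_run_detected(self):
        ann = annotation_from_family_order(["A", "A", "A", "B"])
        cs = detect_clusters(ann)
        assert len(cs) == 1
        row = cs.clusters.iloc[0]
        assert row["family_id"] == "A" and row["n_genes"] == 3

    def test_interrupted_run_not_detected(self):
        ann = annotation_from_family_order(["A", "B", "A", "A"])
        assert len(detect_clusters(ann)) == 0

    def test_no_family_gene_breaks_run(self):
        ann = annotation_from_family_order(["A", "A", None, "A"])
        assert len(detect_clusters(ann)) == 0

    def test_max_intervening_relaxation(self):
        ann = annotation_from_family_order(["A", "A", None, "A"])
        cs = detect_clusters(ann, max_intervening=1)
        assert len(cs) == 1 and cs.clusters.iloc[0]["n_genes"] == 3

    def test_matches_run_length_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(123)
        labels = ["A", "B", "C", None]
        for _ in range(1000):
            order = [labels[i] for i in rng.integers(0, 4, size=rng.integers(3, 25))]
            ann = annotation_from_family_order(order)
            got = detect_clusters(ann)
            expected = run_length_cluster_oracle(order)
            assert len(got) == len(expected)
            for (fam, i, j), row in zip(expected, got.clusters.itertuples()):
                assert row.family_id == fam and row.n_genes == j - i

    def test_cluster_span_coordinates(self, three_gene_cluster):
        cs = detect_clusters(three_gene_cluster)
        row = cs.clusters.iloc[0]
        assert (row["start"], row["end"]) == (10_000, 25_000)


class TestBinomialEnrichment:
    def test_all_successes_closed_form(self):
        assert binomial_enrichment(10, 10, 0.5) == pytest.approx(2.0 ** -10, rel=1e-12)

    def test_k_zero_is_one(self):
        assert binomial_enrichment(0, 20, 0.3) == 1.0

    def test_matches_pmf_summation(self):
        assert binomial_enrichment(8, 20, 0.3) == pytest.approx(
            binomial_upper_tail_oracle(8, 20, 0.3), rel=1e-12)

    @pytest.mark.parametrize("n", [10, 100, 1000, 5000])
    def test_oracle_grid(self, n):
        for pi in (0.05, 0.28, 0.5, 0.9):
            for k in {0, 1, n // 10, n // 3, n // 2, n - 1, n}:
                expected = binomial_upper_tail_oracle(k, n, pi)
                if expected < 1e-290:
                    continue
                assert binomial_enrichment(k, n, pi) == pytest.approx(
                    expected, rel=1e-12)

    def test_invalid_pi_rejected(self):
        with pytest.raises(ConfigurationError):
            binomial_enrichment(1, 10, 1.5)


class TestFamilyEnrichment:
    def test_headline_percentage(self):
        report = FamilyEnrichmentReport(k=1659, n=4535, pi_f=0.28, p=None,
                                        k_c=0, n_c=0, pi_c=None, p_c=None)
        assert report.pct_family == 37

    def _genome(self, seed=0):
        rng = np.random.default_rng(seed)
        order = []
        for fam in range(10):
            order.extend([f"fam{fam}"] * 6)
        order.extend([None] * 140)
        rng.shuffle(order)
        return annotation_from_family_order(order)

    def test_random_targets_give_uniformish_p(self):
        ann = self._genome()
        catalog = FamilyCatalog.from_annotation(ann)
        clusters = detect_clusters(ann, catalog)
        rng = np.random.default_rng(0)
        ids = ann.genes["gene_id"].to_numpy()
        ps = []
        for _ in range(200):
            chosen = rng.choice(ids, size=60, replace=False)
            tt = TargetTable(pd.DataFrame({
                "gene_id": ids,
                "category": np.where(np.isin(ids, chosen), "genic", "none")}))
            ps.append(family_enrichment(tt, catalog, ann, clusters).p)
        assert 0.25 <= float(np.median(ps)) <= 0.75

    def test_planted_clustered_targets_power(self):
        # 200 genes, blocks only on clustered families: clustered enrichment
        # among targets must be overwhelming
        order = []
        for fam in range(5):
            order.extend([f"cfam{fam}"] * 6)     # clustered families
        for fam in range(5):
            for _ in range(6):                   # dispersed families, interleaved
                order.extend([f"dfam{fam}", None])
        order.extend([None] * 110)
        ann = annotation_from_family_order(order)
        catalog = FamilyCatalog.from_annotation(ann)
        clusters = detect_clusters(ann, catalog)
        clustered_ids = clusters.gene_ids()
        ids = ann.genes["gene_id"].to_numpy()
        tt = TargetTable(pd.DataFrame({
            "gene_id": ids,
            "category": np.where(np.isin(ids, sorted(clustered_ids)),
                                 "genic", "none")}))
        report = family_enrichment(tt, catalog, ann, clusters)
        assert report.p_c is not None and report.p_c < 1e-6

    def test_empty_target_set_flagged(self, caplog):
        ann = self._genome()
        catalog = FamilyCatalog.from_annotation(ann)
        tt = TargetTable(pd.DataFrame({"gene_id": ann.genes["gene_id"],
                                       "category": "none"}))
        with caplog.at_level("WARNING"):
            report = family_enrichment(tt, catalog, ann)
        assert report.n == 0 and report.p is None


class TestBindingLevelComparison:
    def test_identical_groups(self):
        scores = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0,
                            "d": 1.0, "e": 2.0, "f": 3.0})
        out = binding_level_comparison(scores, ["a", "b", "c"], ["d", "e", "f"])
        assert out["p"] == pytest.approx(1.0)
        assert out["clustered"]["median"] == out["nonclustered"]["median"]

    def test_exact_small_sample_p(self):
        scores = pd.Series({"a": 1, "b": 2, "c": 3, "d": 4, "e": 5, "f": 6},
                           dtype=float)
        out = binding_level_comparison(scores, ["a", "b", "c"], ["d", "e", "f"])
        # exhaustive: 20 arrangements of ranks, 2 as extreme per side
        assert out["method"] == "exact"
        assert out["p"] == pytest.approx(0.1)

    def test_planted_higher_clustered_binding(self):
        rng = np.random.default_rng(5)
        clustered = {f"c{i}": v for i, v in enumerate(rng.normal(5, 1, 50))}
        dispersed = {f"d{i}": v for i, v in enumerate(rng.normal(2, 1, 50))}
        scores = pd.Series({**clustered, **dispersed})
        out = binding_level_comparison(scores, list(clustered), list(dispersed))
        assert out["clustered"]["median"] > out["nonclustered"]["median"]
        assert out["p"] < 1e-6

    def test_empty_group_rejected(self):
        scores = pd.Series({"a": 1.0})
        with pytest.raises(ValidationError):
            binding_level_comparison(scores, ["a"], ["missing"])


class TestFamilyZscoreMatrix:
    def _tracks_and_genome(self, hot_family=None, n_fam=11, score_hot=10.0):
        # genes spaced 10 kb apart so +/-3 kb genic regions never overlap
        genes = []
        for fam in range(n_fam):
            for j in range(3):
                i = fam * 3 + j
                genes.append(("chr1", 10_000 * i + 4_000, 10_000 * i + 6_000,
                              "+", f"g{i}", f"fam{fam}"))
        ann = make_annotation(genes, chrom_sizes={"chr1": 10_000 * n_fam * 3 + 10_000})
        n_win = ann.chrom_sizes["chr1"] // 100
        scores = np.zeros(n_win)
        if hot_family is not None:
            genes = ann.genes[ann.genes["family_id"] == hot_family]
            for g in genes.itertuples():
                w0, w1 = (g.start - 3000) // 100, (g.end + 3000) // 100
                scores[max(w0, 0): w1] = score_hot
        return {"s1": make_pvalues({"chr1": scores})}, ann

    def test_constant_scores_give_zero_z(self):
        tracks, ann = self._tracks_and_genome()
        z, dropped = family_zscore_matrix(tracks, ann,
                                          FamilyCatalog.from_annotation(ann))
        assert not dropped
        np.testing.assert_allclose(z.to_numpy(), 0.0)

    def test_hot_family_stands_out(self):
        tracks, ann = self._tracks_and_genome(hot_family="fam0")
        z, _ = family_zscore_matrix(tracks, ann,
                                    FamilyCatalog.from_annotation(ann))
        assert z.loc["fam0", "s1"] > 3

    def test_columns_standardized(self):
        rng = np.random.default_rng(2)
        tracks, ann = self._tracks_and_genome()
        tracks["s1"].score["chr1"][:] = rng.uniform(0, 5, len(tracks["s1"].score["chr1"]))
        tracks["s2"] = make_pvalues(
            {"chr1": rng.uniform(0, 5, len(tracks["s1"].score["chr1"]))})
        z, _ = family_zscore_matrix(tracks, ann,
                                    FamilyCatalog.from_annotation(ann))
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_dropping_sample_leaves_other_columns(self):
        rng = np.random.default_rng(3)
        tracks, ann = self._tracks_and_genome()
        n = len(tracks["s1"].score["chr1"])
        tracks["s1"].score["chr1"][:] = rng.uniform(0, 5, n)
        tracks["s2"] = make_pvalues({"chr1": rng.uniform(0, 5, n)})
        z_both, _ = family_zscore_matrix(tracks, ann,
                                         FamilyCatalog.from_annotation(ann))
        z_one, _ = family_zscore_matrix({"s1": tracks["s1"]}, ann,
                                        FamilyCatalog.from_annotation(ann))
        pd.testing.assert_series_equal(z_both["s1"], z_one["s1"])


class TestHierarchicalOrder:
    def test_identical_columns_merge_first(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=10)
        mat = pd.DataFrame({
            "a": base, "b": base,
            "c": rng.normal(size=10), "d": rng.normal(size=10),
        }, index=[f"f{i}" for i in range(10)])
        order, z = hierarchical_order(mat, axis="samples")
        first = {mat.columns[int(z[0, 0])], mat.columns[int(z[0, 1])]}
        assert first == {"a", "b"}

    def test_hand_computed_merge_order(self):
        t = np.linspace(0, 2 * np.pi, 12)
        mat = pd.DataFrame({
            "r1": np.sin(t), "r2": np.sin(t) + 0.01 * np.cos(3 * t),
            "r3": -np.sin(t),
        }).T
        order, z = hierarchical_order(mat, axis="families")
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(9)
        mat = pd.DataFrame(rng.normal(size=(8, 6)),
                           index=[f"f{i}" for i in range(8)])
        _, z1 = hierarchical_order(mat)
        perm = rng.permutation(8)
        _, z2 = hierarchical_order(mat.iloc[perm])
        # topology compared through label-aligned cophenetic distances
        d1 = pd.DataFrame(np.zeros((8, 8)), index=mat.index, columns=mat.index)
        d2 = d1.copy()
        from scipy.spatial.distance import squareform
        d1.iloc[:, :] = squareform(cophenet(z1))
        labels2 = mat.index[perm]
        c2 = pd.DataFrame(squareform(cophenet(z2)), index=labels2, columns=labels2)
        c2 = c2.loc[mat.index, mat.index]
        np.testing.assert_allclose(d1.to_numpy(), c2.to_numpy(), atol=1e-10)

    def test_constant_row_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(size=(4, 5)),
                           index=["a", "b", "c", "flat"])
        mat.loc["flat"] = 1.0
        with caplog.at_level("WARNING"):
            order, _ = hierarchical_order(mat)
        assert "flat" not in order and "flat" in caplog.text
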