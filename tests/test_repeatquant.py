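"""Quantification and normalization: arithmetic contracts, invariances,
exact oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxy.annotation import ChromosomeMap
from toxy.samples import SampleMeta
from toxy import repeatquant as rq


def make_table(values: dict, feature_class="TE", state="raw"):
    df = pd.DataFrame(values)
    df.index.name = "feature"
    return rq.FeatureCountTable(df, feature_class, state)


@pytest.fixture()
def gene_table():
    counts = pd.DataFrame({
        "s1": [10, 20, 30, 7], "s2": [5, 15, 25, 3],
    }, index=["gA", "gB", "gC", "gX"])
    fclass = pd.Series("gene", index=counts.index)
    return rq.FeatureCountTable(counts, fclass, "raw")


@pytest.fixture()
def chrom_map():
    return ChromosomeMap(
        {"gA": "chr2", "gB": "chr2", "gC": "chr3", "gX": "chrX"},
        {"chr2": "autosome", "chr3": "autosome", "chrX": "X"},
    )


class TestCountFeatures:
    def test_direct_tally(self):
        alns = pd.DataFrame({
            "qname": [f"r{i}" for i in range(5)], "mate": 1,
            "ref": ["ISY-like"] * 5, "start": 0, "end": 100,
            "strand": "+", "mapq": 60,
        })
        t = rq.count_features({"s1": alns}, ["ISY-like", "other"])
        assert t.counts.loc["ISY-like", "s1"] == 5
        assert t.counts.loc["other", "s1"] == 0
        assert t.state == "raw"

    def test_secondary_records_excluded(self):
        alns = pd.DataFrame({
            "qname": ["r0", "r1"], "mate": 1, "ref": ["t", "t"],
            "start": 0, "end": 100, "strand": "+", "mapq": 0,
            "is_primary": [False, False],
        })
        t = rq.count_features({"s1": alns}, ["t"])
        assert (t.counts == 0).all().all()

    def test_empty_alignments_give_zero_column(self):
        t = rq.count_features({"s1": pd.DataFrame(columns=["qname", "mate", "ref"])},
                              ["t1", "t2"])
        assert (t.counts["s1"] == 0).all()


class TestAutosomalMedianNormalization:
    def test_arithmetic_from_the_stated_rule(self, gene_table, chrom_map):
        # autosomal counts {10, 20, 30} in s1 -> median 20; TE count 40 -> 40/20+1
        te = make_table({"s1": [40], "s2": [50]})
        te.counts.index = ["te1"]
        norm = rq.normalize_autosomal_median(te, gene_table, chrom_map)
        assert norm.counts.loc["te1", "s1"] == pytest.approx(40 / 20 + 1)
        assert norm.counts.loc["te1", "s2"] == pytest.approx(50 / 15 + 1)
        assert norm.state == "autosomal_median+pseudocount"

    def test_scale_invariance_per_library(self, gene_table, chrom_map):
        te = make_table({"s1": [40, 8], "s2": [50, 2]})
        base = rq.normalize_autosomal_median(te, gene_table, chrom_map)
        scaled_genes = rq.FeatureCountTable(
            gene_table.counts.assign(s1=gene_table.counts["s1"] * 7),
            gene_table.feature_class, "raw")
        scaled_te = rq.FeatureCountTable(
            te.counts.assign(s1=te.counts["s1"] * 7), te.feature_class, "raw")
        scaled = rq.normalize_autosomal_median(scaled_te, scaled_genes, chrom_map)
        pd.testing.assert_frame_equal(base.counts, scaled.counts)

    def test_zero_median_raises_naming_sample(self, chrom_map):
        genes = make_table({"s1": [0, 0, 1]}, feature_class="gene")
        genes.counts.index = ["gA", "gB", "gC"]
        genes.feature_class = pd.Series("gene", index=genes.counts.index)
        te = make_table({"s1": [5]})
        with pytest.raises(rq.NormalizationError, match="s1"):
            rq.normalize_autosomal_median(te, genes, chrom_map)

    def test_matches_brute_force_oracle(self, rng, chrom_map):
        raw = pd.DataFrame(rng.integers(1, 100, size=(6, 3)).astype(float),
                           index=["gA", "gB", "gC", "gX", "te1", "te2"],
                           columns=["s1", "s2", "s3"])
        fclass = pd.Series(["gene"] * 4 + ["TE"] * 2, index=raw.index)
        table = rq.FeatureCountTable(raw, fclass, "raw")
        norm = rq.normalize_autosomal_median(table, table, chrom_map)
        for col in raw.columns:
            med = float(np.median(sorted([raw.loc["gA", col], raw.loc["gB", col],
                                          raw.loc["gC", col]])))
            for f in raw.index:
                assert norm.counts.loc[f, col] == pytest.approx(
                    raw.loc[f, col] / med + 1)

    def test_state_only_advances(self, gene_table, chrom_map):
        te = make_table({"s1": [40], "s2": [50]})
        norm = rq.normalize_autosomal_median(te, gene_table, chrom_map)
        with pytest.raises(rq.NormalizationError):
            rq.normalize_autosomal_median(norm, gene_table, chrom_map)


DNA_DESIGN = [SampleMeta("dF", "d", "female", 10, 1, "DNA"),
              SampleMeta("dM", "d", "male", 10, 1, "DNA")]
RNA_DESIGN = [SampleMeta("rF", "d", "female", 10, 1, "RNA"),
              SampleMeta("rM", "d", "male", 10, 1, "RNA")]


class TestCopyNumberNormalization:
    def test_equal_folds_cancel(self):
        rna = make_table({"rF": [2.0], "rM": [4.0]}, state="autosomal_median+pseudocount")
        dna = make_table({"dF": [1.0], "dM": [2.0]}, state="autosomal_median+pseudocount")
        out = rq.copy_number_normalize(rna, dna, RNA_DESIGN, DNA_DESIGN)
        assert out.counts.loc[0, "rM"] / out.counts.loc[0, "rF"] == pytest.approx(1.0)
        assert out.state == "copy_number"

    def test_unit_dna_is_identity(self):
        rna = make_table({"rF": [2.0, 3.0], "rM": [4.0, 5.0]},
                         state="autosomal_median+pseudocount")
        dna = make_table({"dF": [1.0, 1.0], "dM": [1.0, 1.0]},
                         state="autosomal_median+pseudocount")
        out = rq.copy_number_normalize(rna, dna, RNA_DESIGN, DNA_DESIGN)
        pd.testing.assert_frame_equal(out.counts, rna.counts, check_names=False)

    def test_matches_elementwise_division_oracle(self, rng):
        vals = rng.uniform(0.5, 10, size=(5, 2))
        dvals = rng.uniform(0.5, 4, size=(5, 2))
        rna = make_table({"rF": vals[:, 0], "rM": vals[:, 1]},
                         state="autosomal_median+pseudocount")
        dna = make_table({"dF": dvals[:, 0], "dM": dvals[:, 1]},
                         state="autosomal_median+pseudocount")
        out = rq.copy_number_normalize(rna, dna, RNA_DESIGN, DNA_DESIGN)
        np.testing.assert_allclose(out.counts["rF"], vals[:, 0] / dvals[:, 0])
        np.testing.assert_allclose(out.counts["rM"], vals[:, 1] / dvals[:, 1])

    def test_zero_dna_becomes_missing_not_zero(self):
        rna = make_table({"rF": [2.0], "rM": [4.0]}, state="autosomal_median+pseudocount")
        dna = make_table({"dF": [0.0], "dM": [2.0]}, state="autosomal_median+pseudocount")
        with pytest.warns(UserWarning, match="undefined"):
            out = rq.copy_number_normalize(rna, dna, RNA_DESIGN, DNA_DESIGN)
        assert np.isnan(out.counts.loc[0, "rF"])
        assert out.counts.loc[0, "rM"] == pytest.approx(2.0)


class TestSexFold:
    DESIGN = [SampleMeta(s, "d", sex, 10, i, "RNA")
              for sex, ids in (("male", ["m1", "m2"]), ("female", ["f1", "f2"]))
              for i, s in enumerate(ids)]

    def test_symmetry_and_log2(self):
        t = make_table({"m1": [4.0, 2.0], "m2": [4.0, 2.0],
                        "f1": [1.0, 2.0], "f2": [1.0, 2.0]},
                       state="autosomal_median+pseudocount")
        folds = rq.sex_fold_difference(t, self.DESIGN, 10)
        assert folds.iloc[0] == pytest.approx(2.0)   # log2(4/1)
        assert folds.iloc[1] == pytest.approx(0.0)   # equal means

    def test_missing_sex_raises(self):
        t = make_table({"m1": [1.0]}, state="autosomal_median+pseudocount")
        with pytest.raises(ValueError, match="female"):
            rq.sex_fold_difference(t, [self.DESIGN[0]], 10)


class TestWilcoxon:
    def test_identical_vectors_give_p_one(self):
        t = make_table({"m1": [1.0, 2, 3], "f1": [1.0, 2, 3]},
                       state="autosomal_median+pseudocount")
        design = [SampleMeta("m1", "d", "male", 10, 1, "RNA"),
                  SampleMeta("f1", "d", "female", 10, 1, "RNA")]
        _, p = rq.compare_sexes_wilcoxon(t, design, 10)
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_oracle_n6(self, rng):
        from itertools import combinations
        from scipy.stats import rankdata
        x = rng.normal(1.0, 1, 6)
        y = rng.normal(0.0, 1, 6)
        from toxy._stats import rank_sum_test
        w, p = rank_sum_test(x, y, method="exact")
        ranks = rankdata(np.concatenate([x, y]))
        mu = 6 * 13 / 2
        obs = abs(ranks[:6].sum() - mu)
        hits = sum(abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9
                   for idx in combinations(range(12), 6))
        assert p == pytest.approx(hits / 924)

    def test_exact_matches_scipy_without_ties(self, rng):
        from scipy.stats import mannwhitneyu
        from toxy._stats import rank_sum_test
        x, y = rng.normal(size=7), rng.normal(size=5)
        _, p = rank_sum_test(x, y, method="exact")
        assert p == pytest.approx(
            mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)

    def test_single_element_groups(self):
        from toxy._stats import rank_sum_test
        _, p = rank_sum_test([1.0], [2.0])
        assert p == pytest.approx(1.0)  # exact two-point test


class TestCorrelationCluster:
    def test_duplicated_columns_correlate_and_sit_adjacent(self):
        base = np.array([1.0, 2, 4, 8, 3])
        t = make_table({"a1": base, "a2": base, "b": base[::-1]},
                       state="autosomal_median+pseudocount")
        corr, order, _ = rq.correlation_cluster(t)
        assert corr.loc["a1", "a2"] == pytest.approx(1.0)
        assert abs(order.index("a1") - order.index("a2")) == 1

    def test_two_anticorrelated_groups_split_at_two_cluster_cut(self):
        up = np.array([1.0, 2, 3, 4, 5])
        t = make_table({"u1": up, "u2": up * 2, "d1": up[::-1], "d2": up[::-1] * 3},
                       state="autosomal_median+pseudocount")
        from scipy.cluster.hierarchy import fcluster
        corr, order, Z = rq.correlation_cluster(t)
        labels = fcluster(Z, 2, criterion="maxclust")
        groups = dict(zip(t.samples, labels))
        assert groups["u1"] == groups["u2"] != groups["d1"] == groups["d2"]

    def test_column_permutation_gives_same_tree(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 10, size=(8, 5))
        cols = list("abcde")
        t1 = make_table(dict(zip(cols, vals.T)), state="autosomal_median+pseudocount")
        perm = ["c", "a", "e", "b", "d"]
        t2 = rq.FeatureCountTable(t1.counts[perm], t1.feature_class,
                                  "autosomal_median+pseudocount")
        _, order1, _ = rq.correlation_cluster(t1)
        _, order2, _ = rq.correlation_cluster(t2)
        # same merge structure: adjacency sets of leaves agree
        def pairs(order):
            return {frozenset(p) for p in zip(order, order[1:])}
        assert pairs(order1) == pairs(order2)


class TestYEnrichment:
    DESIGN = DNA_DESIGN

    def test_threshold_boundary(self):
        dna = make_table({"dF": [4.0, 10.0, 5.0], "dM": [10.0, 4.0, 10.0]},
                         state="autosomal_median+pseudocount")
        dna.counts.index = ["above", "below", "exact"]
        res = rq.classify_y_enriched(dna, self.DESIGN)
        assert "above" in res.y_enriched       # ratio 2.5
        assert "below" in res.remaining        # ratio 0.4
        assert "exact" in res.y_enriched       # ratio 2.0, boundary inclusive
        assert res.table.loc["above", "ratio"] == pytest.approx(2.5)

    def test_zero_female_flagged_infinite(self):
        dna = make_table({"dF": [0.0], "dM": [3.0]},
                         state="autosomal_median+pseudocount")
        res = rq.classify_y_enriched(dna, self.DESIGN)
        assert np.isinf(res.table["ratio"].iloc[0])
        assert len(res.y_enriched) == 1

    def test_partition_matches_brute_force_scan(self, rng):
        n = 303
        dna = make_table({"dF": rng.uniform(0.5, 5, n), "dM": rng.uniform(0.5, 5, n)},
                         state="autosomal_median+pseudocount")
        dna.counts.index = [f"te{i}" for i in range(n)]
        res = rq.classify_y_enriched(dna, self.DESIGN)
        expect = {f for f in dna.counts.index
                  if dna.counts.loc[f, "dM"] / dna.counts.loc[f, "dF"] >= 2}
        assert res.y_enriched == expect
        assert res.y_enriched | res.remaining == set(dna.counts.index)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 50), col=st.integers(0, 2))
def test_scale_invariance_property(scale, col):
    """Multiplying any one library's raw counts by a positive constant
    leaves normalized values, folds and classifications unchanged."""
    rng = np.random.default_rng(7)
    raw = pd.DataFrame(rng.integers(1, 200, size=(6, 3)).astype(float),
                       index=["gA", "gB", "gC", "gX", "te1", "te2"],
                       columns=["s1", "s2", "s3"])
    fclass = pd.Series(["gene"] * 4 + ["TE"] * 2, index=raw.index)
    cm = ChromosomeMap({"gA": "a", "gB": "a", "gC": "a", "gX": "x"},
                       {"a": "autosome", "x": "X"})
    t1 = rq.FeatureCountTable(raw, fclass, "raw")
    scaled = raw.copy()
    scaled.iloc[:, col] *= scale
    t2 = rq.FeatureCountTable(scaled, fclass, "raw")
    n1 = rq.normalize_autosomal_median(t1, t1, cm)
    n2 = rq.normalize_autosomal_median(t2, t2, cm)
    pd.testing.assert_frame_equal(n1.counts, n2.counts)
    # conservation: feature set unchanged
    assert list(n1.counts.index) == list(raw.index)
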