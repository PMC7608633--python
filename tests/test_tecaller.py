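"""Dual-junction insertion caller: filtering rules, chaining, novelty, truth
recovery on simulated reads."""

import numpy as np
import pandas as pd
import pytest

from toxy import tecaller as tc
from toxy.synthdata import (ChromosomeSpec, SyntheticGenomeSpec, make_genome,
                            plant_insertions, simulate_dna_reads)


def aln(qname, mate, ref, start, strand="+", mapq=60, end=None):
    return {"qname": qname, "mate": mate, "ref": ref, "start": start,
            "end": end if end is not None else start + 100,
            "strand": strand, "mapq": mapq}


def frame(rows):
    return pd.DataFrame(rows)


class TestFindJunctionPairs:
    def test_fully_genomic_pair_excluded(self):
        g = frame([aln("p1", 1, "c", 100), aln("p1", 2, "c", 400, "-")])
        t = frame([aln("x", 1, "fam", 0)])
        assert len(tc.find_junction_pairs(g, t)) == 0

    def test_multimapping_genome_side_excluded(self):
        g = frame([aln("p1", 1, "c", 100, mapq=0)])
        t = frame([aln("p1", 2, "famA", 10)])
        assert len(tc.find_junction_pairs(g, t)) == 0
        # two placements for the same read also disqualify, despite mapq
        g2 = frame([aln("p1", 1, "c", 100), aln("p1", 1, "c", 5000)])
        assert len(tc.find_junction_pairs(g2, t)) == 0

    def test_te_mate_with_genome_placement_excluded(self):
        g = frame([aln("p1", 1, "c", 100), aln("p1", 2, "c", 400, "-")])
        t = frame([aln("p1", 2, "famA", 10, "-")])
        assert len(tc.find_junction_pairs(g, t)) == 0

    def test_qualifying_pair_kept_with_family(self):
        g = frame([aln("p1", 1, "c", 100)])
        t = frame([aln("p1", 2, "famA", 10, "-")])
        pairs = tc.find_junction_pairs(g, t)
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert (row["chrom"], row["strand"], row["family"]) == ("c", "+", "famA")

    def test_te_side_direction_irrelevant(self):
        g = frame([aln("p1", 1, "c", 100), aln("p2", 1, "c", 130)])
        t = frame([aln("p1", 2, "famA", 10, "-"), aln("p2", 2, "famA", 10, "+")])
        assert len(tc.find_junction_pairs(g, t)) == 2

    def test_simulated_truth_fragments_all_recovered(self, clean_caller_data):
        rs, ins = clean_caller_data
        pairs = tc.find_junction_pairs(rs.genome_alignments, rs.te_alignments)
        labels = rs.truth_labels()
        got = set(pairs["qname"])
        assert got  # some junction pairs exist
        # no reference-only fragment sneaks in
        assert all(labels[q].startswith("ins:") for q in got)


class TestClusterJunctions:
    def _pairs(self, positions, strand="+", chrom="c", family="f"):
        return frame([
            {"qname": f"p{i}", "chrom": chrom, "start": p, "end": p + 100,
             "strand": strand, "family": family}
            for i, p in enumerate(positions)])

    def test_within_gap_joins(self):
        out = tc.cluster_junctions(self._pairs([100, 150]))
        assert len(out) == 1
        assert out["support"].iloc[0] == 2

    def test_beyond_gap_splits(self):
        out = tc.cluster_junctions(self._pairs([100, 250]))
        assert len(out) == 2

    def test_single_linkage_chain(self):
        # innermost bases 199, 279, 359: consecutive gaps 80 < 100 chain up
        out = tc.cluster_junctions(self._pairs([100, 180, 260]))
        assert len(out) == 1
        assert out["support"].iloc[0] == 3

    def test_representative_is_innermost_base(self):
        fwd = tc.cluster_junctions(self._pairs([100, 150]))
        assert fwd["position"].iloc[0] == 150 + 100 - 1  # max end - 1
        rev = tc.cluster_junctions(self._pairs([100, 150], strand="-"))
        assert rev["position"].iloc[0] == 100            # min start

    def test_matches_transitive_closure_oracle(self, rng):
        pos = np.sort(rng.integers(0, 5_000, 60))
        out = tc.cluster_junctions(self._pairs(pos))
        # oracle: union-find over all pairs closer than gap
        inner = pos + 99
        parent = list(range(len(pos)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if abs(int(inner[i]) - int(inner[j])) < 100:
                    parent[find(i)] = find(j)
        n_groups = len({find(i) for i in range(len(pos))})
        assert len(out) == n_groups
        assert out["support"].sum() == len(pos)


class TestCallInsertions:
    def _clusters(self, rows):
        return pd.DataFrame(rows, columns=tc.CLUSTER_COLUMNS)

    def test_forward_then_reverse_within_gap_calls(self):
        out = tc.call_insertions(self._clusters([
            ("c", "forward", "f", 1000, 5, 900, 1000),
            ("c", "reverse", "f", 1050, 4, 1050, 1200)]))
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["pos5"], row["pos3"]) == (1000, 1050)
        assert (row["support5"], row["support3"]) == (5, 4)

    def test_forward_only_never_calls(self):
        out = tc.call_insertions(self._clusters([
            ("c", "forward", "f", 1000, 9, 900, 1000)]))
        assert len(out) == 0

    def test_distance_at_or_beyond_gap_rejected(self):
        out = tc.call_insertions(self._clusters([
            ("c", "forward", "f", 1000, 5, 900, 1000),
            ("c", "reverse", "f", 1150, 4, 1150, 1200)]))
        assert len(out) == 0

    def test_family_agreement_required_by_default(self):
        clusters = self._clusters([
            ("c", "forward", "fA", 1000, 5, 900, 1000),
            ("c", "reverse", "fB", 1050, 4, 1050, 1200)])
        assert len(tc.call_insertions(clusters)) == 0
        assert len(tc.call_insertions(clusters, require_same_family=False)) == 1

    def test_each_cluster_used_once(self):
        out = tc.call_insertions(self._clusters([
            ("c", "forward", "f", 1000, 5, 900, 1000),
            ("c", "forward", "f", 1040, 5, 1000, 1040),
            ("c", "reverse", "f", 1060, 4, 1060, 1100)]))
        # the nearer forward cluster wins; the other stays unpaired
        assert len(out) == 1
        assert out["pos5"].iloc[0] == 1040


class TestNoveltyFilter:
    def _calls(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos5", "sample_id"])
        df["pos3"] = df["pos5"] + 40
        df["family"] = "f"
        df["support5"] = df["support3"] = 1
        return df

    def test_shared_site_removed_from_both(self):
        calls = self._calls([("c", 1000, "s1"), ("c", 1000, "s2")])
        assert len(tc.filter_novel(calls)) == 0

    def test_sites_sixty_bp_apart_survive(self):
        calls = self._calls([("c", 1000, "s1"), ("c", 1060, "s2")])
        assert len(tc.filter_novel(calls)) == 2

    def test_same_sample_duplicates_not_removed(self):
        calls = self._calls([("c", 1000, "s1"), ("c", 1010, "s1")])
        assert len(tc.filter_novel(calls)) == 2

    def test_matches_quadratic_oracle(self, rng):
        n = 120
        calls = self._calls([
            ("c" + str(rng.integers(2)), int(rng.integers(0, 3_000)),
             f"s{rng.integers(4)}")
            for _ in range(n)])
        out = tc.filter_novel(calls, radius=50)
        keep = []
        for i in range(n):
            ok = True
            for j in range(n):
                if i == j:
                    continue
                if (calls["chrom"][i] == calls["chrom"][j]
                        and calls["sample_id"][i] != calls["sample_id"][j]
                        and abs(calls["pos5"][i] - calls["pos5"][j]) < 50):
                    ok = False
            if ok:
                keep.append(i)
        expect = calls.iloc[keep].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            out.sort_values(["chrom", "pos5", "sample_id"], ignore_index=True),
            expect.sort_values(["chrom", "pos5", "sample_id"], ignore_index=True))


@pytest.fixture(scope="module")
def clean_caller_data():
    """200-kb TE-free genome with 3 planted insertions, 30x reads."""
    spec = SyntheticGenomeSpec(
        chromosomes=[ChromosomeSpec("c", 200_000, te_density=0, gene_density=5)],
        n_te_families=4, te_length_range=(500, 800), seed=5)
    g, lib, ann, truth = make_genome(spec)
    ins = plant_insertions(ann, lib, ["s1"], 3, cell_fraction=1.0, seed=21)
    truth.insertions = ins
    rs = simulate_dna_reads(g, ann, truth, lib, "s1", depth=30, seed=22)
    return rs, ins


class TestEndToEnd:
    def test_planted_insertions_called_exactly(self, clean_caller_data):
        rs, ins = clean_caller_data
        calls = tc.call_pipeline(rs.genome_alignments, rs.te_alignments)
        recall, precision, _ = tc.match_calls(calls, ins, sample_id="s1")
        assert recall == 1.0 and precision == 1.0
        assert len(calls) == len(ins)

    def test_call_positions_bracket_insertion_point(self, clean_caller_data):
        rs, ins = clean_caller_data
        calls = tc.call_pipeline(rs.genome_alignments, rs.te_alignments)
        for c in calls.itertuples():
            p = int(ins.loc[(ins["chrom"] == c.chrom)
                            & ((ins["pos"] - c.pos5).abs() <= 150), "pos"].iloc[0])
            assert c.pos5 < p <= c.pos3
            assert 0 < c.pos3 - c.pos5 < 100

    def test_conservative_gate_drops_call_without_one_side(self, clean_caller_data):
        rs, ins = clean_caller_data
        pairs = tc.find_junction_pairs(rs.genome_alignments, rs.te_alignments)
        # remove every reverse-side fragment of the first insertion
        p0 = int(ins["pos"].iloc[0])
        drop = (pairs["strand"] == "-") & ((pairs["start"] - p0).abs() < 1000)
        clusters = tc.cluster_junctions(pairs[~drop])
        calls = tc.call_insertions(clusters)
        recall, _, _ = tc.match_calls(calls, ins, sample_id="s1")
        assert len(calls) == len(ins) - 1
        assert recall == pytest.approx((len(ins) - 1) / len(ins))

    def test_input_record_order_irrelevant(self, clean_caller_data):
        rs, _ = clean_caller_data
        calls1 = tc.call_pipeline(rs.genome_alignments, rs.te_alignments)
        perm = np.random.default_rng(0).permutation(len(rs.genome_alignments))
        shuffled = rs.genome_alignments.iloc[perm].reset_index(drop=True)
        calls2 = tc.call_pipeline(shuffled, rs.te_alignments.iloc[::-1]
                                  .reset_index(drop=True))
        pd.testing.assert_frame_equal(calls1, calls2)

    def test_more_depth_never_loses_planted_calls(self):
        spec = SyntheticGenomeSpec(
            chromosomes=[ChromosomeSpec("c", 150_000, te_density=0, gene_density=0)],
            n_te_families=3, te_length_range=(500, 700), seed=6)
        g, lib, ann, truth = make_genome(spec)
        ins = plant_insertions(ann, lib, ["s1"], 2, cell_fraction=1.0, seed=1)
        truth.insertions = ins

        def called(depth):
            rs = simulate_dna_reads(g, ann, truth, lib, "s1", depth=depth, seed=3)
            calls = tc.call_pipeline(rs.genome_alignments, rs.te_alignments)
            _, _, m = tc.match_calls(calls, ins, sample_id="s1")
            return set(zip(m.loc[m["matched"], "chrom"],
                           m.loc[m["matched"], "family"]))

        assert called(15) <= called(30) or called(15) == called(30)


class TestExonControl:
    def test_chimera_free_reads_give_zero_calls(self, clean_caller_data):
        rs, _ = clean_caller_data
        # exon "library" alignments: nothing maps there in clean data
        exon_alns = rs.te_alignments.iloc[0:0]
        counts = tc.exon_control({"s1": (rs.genome_alignments, exon_alns)},
                                 exon_index=["exon1"])
        assert counts["s1"] == 0

    def test_single_junction_chimeras_still_zero_calls(self):
        spec = SyntheticGenomeSpec(
            chromosomes=[ChromosomeSpec("c", 150_000, te_density=0, gene_density=0)],
            n_te_families=3, te_length_range=(500, 700), seed=8)
        g, lib, ann, truth = make_genome(spec)
        rs = simulate_dna_reads(g, ann, truth, lib, "s1", depth=20,
                                chimera_rate=0.02, seed=9)
        assert (rs.truth_labels() == "chimera").sum() > 0
        calls = tc.call_pipeline(rs.genome_alignments, rs.te_alignments)
        assert len(calls) == 0

    def test_empty_exon_index_errors(self):
        with pytest.raises(ValueError, match="empty"):
            tc.exon_control({}, exon_index=[])
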