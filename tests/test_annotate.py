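"""k-mer placement, relative-position rules, COG/pangenome/replicon maps."""

import numpy as np
import pandas as pd
import pytest

from halogwas.annotate import (
    CdsRecord, KmerPlacement, assign_replicons, classify_hits, cog_tally,
    hit_summary, locate_kmers, locate_kmers_indexed, match_to_pangenome,
    relative_position, replicon_summary,
)
from halogwas.kmers import canonical, reverse_complement


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def naive_scan(kmer, scaffolds):
    """Brute-force oracle: scan both orientations at every offset."""
    kc = canonical(kmer)
    rc = reverse_complement(kc)
    out = set()
    for sid, seq in scaffolds:
        for i in range(len(seq) - len(kc) + 1):
            window = seq[i:i + len(kc)]
            if window == kc:
                out.add((kc, sid, i + 1, "+"))
            if window == rc and rc != kc:
                out.add((kc, sid, i + 1, "-"))
    return out


class TestLocateKmers:
    def test_prefix_match_plus_strand(self):
        seq = "ACGTACGTACGTAGGGTTT"
        kmer = seq[:13]
        hits = locate_kmers([kmer], [("sc", seq)])
        assert (hits[0].scaffold_id, hits[0].start, hits[0].strand) == \
            ("sc", 1, "+")

    def test_revcomp_occurrence_reported_minus(self, rng):
        kmer = "AACCGGTTACGTA"
        assert canonical(kmer) == kmer
        seq = random_seq(rng, 40) + reverse_complement(kmer) + \
            random_seq(rng, 40)
        hits = [p for p in locate_kmers([kmer], [("sc", seq)])
                if p.strand == "-"]
        assert len(hits) == 1 and hits[0].start == 41

    def test_matches_naive_scan_oracle(self, rng):
        scaffolds = [("sc1", random_seq(rng, 1000))]
        queries = [random_seq(rng, 13) for _ in range(40)] + \
            [scaffolds[0][1][i:i + 13] for i in (0, 100, 987)]
        got = {(p.kmer, p.scaffold_id, p.start, p.strand)
               for p in locate_kmers(queries, scaffolds)}
        expected = set()
        for q in queries:
            expected |= naive_scan(q, scaffolds)
        assert got == expected

    def test_indexed_locator_agrees_with_reference(self, rng):
        scaffolds = [("sc1", random_seq(rng, 800)),
                     ("sc2", random_seq(rng, 500))]
        queries = [scaffolds[0][1][i:i + 13] for i in range(0, 780, 37)]
        ref = {(p.kmer, p.scaffold_id, p.start, p.strand)
               for p in locate_kmers(queries, scaffolds)}
        fast = {(p.kmer, p.scaffold_id, p.start, p.strand)
                for p in locate_kmers_indexed(queries, scaffolds)}
        assert ref == fast

    def test_scaffold_revcomp_transforms_positions(self, rng):
        seq = random_seq(rng, 300)
        kmer = seq[100:113]
        fwd = locate_kmers([kmer], [("sc", seq)])
        rev = locate_kmers([kmer], [("sc", reverse_complement(seq))])
        assert len(fwd) == len(rev) == 1
        assert rev[0].start == len(seq) - fwd[0].end + 1


# hand-computed expectation table for the six-feature toy annotation:
# placement start -> list of (relative_position, locus, hit_class)
TOY_EXPECTATIONS = {
    1100: [(0, "g1", "gene")],                      # inside + strand CDS
    887: [(-101, "g1", "regulatory"),               # 101 nt upstream of g1
          (-587, "g4", "regulatory")],              # also 3' of - strand g4
    388: [(-600, "g1", "regulatory"),               # boundary: exactly -600
          (-88, "g4", "regulatory")],               # and 3' of - strand g4
    387: [(-87, "g4", "regulatory")],               # g1 now at -601: dropped
    2800: [(-400, "g2", "regulatory"),              # divergent promoters:
           (-388, "g3", "regulatory")],             # one k-mer, two CDSs
    3100: [(-88, "g3", "regulatory")],              # g2 at -700: dropped
    1595: [(0, "g1", "gene")],                      # overlap by tail
    4500: [(-288, "g6", "regulatory")],             # g5 behind, g6 ahead
    30: [],                                         # intergenic
    2000: [(0, "g2", "gene")],                      # inside - strand CDS
}


class TestRelativePosition:
    def placement(self, start):
        return KmerPlacement("A" * 13, "chr", start, "+")

    @pytest.mark.parametrize("start", sorted(TOY_EXPECTATIONS))
    def test_hand_computed_table(self, start, toy_cds):
        got = relative_position(self.placement(start), toy_cds)
        expected = [(rel, locus) for rel, locus, _ in
                    TOY_EXPECTATIONS[start]]
        assert sorted(got) == sorted(expected)

    def test_other_scaffold_ignored(self, toy_cds):
        p = KmerPlacement("A" * 13, "other", 1100, "+")
        assert relative_position(p, toy_cds) == []

    def test_window_boundary_inclusive_exclusive(self):
        cds = [CdsRecord("c", 1000, 1500, "+", "g")]
        at_600 = KmerPlacement("A" * 13, "c", 388, "+")   # end 400
        at_601 = KmerPlacement("A" * 13, "c", 387, "+")   # end 399
        assert relative_position(at_600, cds) == [(-600, "g")]
        assert relative_position(at_601, cds) == []


class TestClassifyHits:
    def test_full_toy_table(self, toy_cds):
        placements = [KmerPlacement("A" * 13, "chr", s, "+")
                      for s in sorted(TOY_EXPECTATIONS)]
        hits = classify_hits(placements, toy_cds)
        for start, expected in TOY_EXPECTATIONS.items():
            sub = hits[hits["start"] == start]
            if not expected:
                assert list(sub["hit_class"]) == ["intergenic"]
                continue
            got = sorted(zip(sub["relative_position"], sub["locus"],
                             sub["hit_class"]))
            assert got == sorted(expected)

    def test_summary_counts_distinct_targets(self, toy_cds):
        placements = [KmerPlacement("A" * 13, "chr", s, "+")
                      for s in sorted(TOY_EXPECTATIONS)]
        hits = classify_hits(placements, toy_cds)
        summary = hit_summary(hits)
        assert summary["n_distinct_cds"] == 2          # g1, g2
        assert summary["n_distinct_regulatory_regions"] == 5
        assert summary["n_intergenic"] == 1

    def test_empty_inputs_empty_tables(self):
        hits = classify_hits([], [])
        assert hits.empty
        assert hit_summary(hits)["n_gene_hits"] == 0

    def test_every_placement_gets_exactly_one_class_per_target(self,
                                                               toy_cds,
                                                               rng):
        starts = rng.integers(1, 4900, size=60)
        placements = [KmerPlacement("A" * 13, "chr", int(s), "+")
                      for s in starts]
        hits = classify_hits(placements, toy_cds)
        assert set(hits["hit_class"]) <= {"gene", "regulatory", "intergenic"}
        gene_rows = hits[hits["hit_class"] == "gene"]
        assert (gene_rows["relative_position"] == 0).all()
        reg = hits[hits["hit_class"] == "regulatory"]["relative_position"]
        assert ((reg >= -600) & (reg < 0)).all()


class TestPangenome:
    def matrix(self):
        return pd.DataFrame(
            {"strainA": ["a_1", "a_2", None],
             "strainB": ["b_1", None, "b_9"],
             "strainC": ["c_1", None, None]},
            index=["clu1", "clu2", "clu3"])

    def test_locus_maps_to_its_cluster(self):
        matches, unmatched = match_to_pangenome(["a_2", "b_9"],
                                                self.matrix())
        assert matches["a_2"]["cluster"] == "clu2"
        assert matches["a_2"]["strain_unique"]
        assert matches["b_9"]["cluster"] == "clu3"
        assert not unmatched

    def test_unknown_locus_reported_not_fatal(self):
        matches, unmatched = match_to_pangenome(["nope"], self.matrix())
        assert matches == {} and unmatched == ["nope"]

    def test_shared_cluster_distribution(self):
        matches, _ = match_to_pangenome(["a_1"], self.matrix())
        assert matches["a_1"]["n_strains"] == 3
        assert not matches["a_1"]["strain_unique"]


class TestCogTally:
    def hits(self, classes):
        return pd.DataFrame({
            "hit_class": ["gene"] * len(classes),
            "cog_class": classes,
            "locus": [f"l{i}" for i in range(len(classes))],
        })

    def test_known_counts(self):
        table = cog_tally(self.hits(["G", "G", "G", "G", "K", "K", "M"]))
        assert table.loc["G", "panel"] == 4
        assert table.loc["K", "panel"] == 2
        assert table.loc["M", "panel"] == 1

    def test_missing_class_counted_unclassified(self):
        table = cog_tally(self.hits(["G", None]))
        assert table.loc["unclassified", "panel"] == 1

    def test_empty_input(self):
        assert cog_tally(self.hits([])).empty


class TestReplicons:
    def refs(self, rng):
        return {"chromosome": random_seq(rng, 3000),
                "pSymA": random_seq(rng, 2000),
                "pSymB": random_seq(rng, 2000)}

    def test_verbatim_slice_fully_contained(self, rng):
        refs = self.refs(rng)
        scaffold = refs["chromosome"][500:1500]
        out = assign_replicons([("sc", scaffold)], refs)
        assert out[0].replicon == "chromosome"
        assert out[0].containment == pytest.approx(1.0)

    def test_unrelated_scaffold_unknown(self, rng):
        out = assign_replicons([("sc", random_seq(rng, 1000))],
                               self.refs(rng))
        assert out[0].replicon == "unknown"

    def test_chimera_rejected_by_margin(self, rng):
        refs = self.refs(rng)
        chimera = refs["chromosome"][:500] + refs["pSymA"][:500]
        out = assign_replicons([("sc", chimera)], refs)
        assert out[0].replicon == "unknown"

    def test_summary_percentages_sum_to_100(self, rng):
        refs = self.refs(rng)
        scaffolds = [("a", refs["chromosome"][:800]),
                     ("b", refs["pSymA"][:800]),
                     ("c", random_seq(rng, 800))]
        summary = replicon_summary(assign_replicons(scaffolds, refs))
        assert summary["percent"].sum() == pytest.approx(100.0)
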