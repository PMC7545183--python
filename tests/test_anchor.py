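import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feralscan.anchor import (
    anchor_scaffolds,
    assembly_stats,
    assign_chromosome,
    build_pseudomolecules,
    map_probe_reads,
    place_and_orient,
    simulate_probe_reads,
)
from feralscan.synthetic import generate_scaffold_world, random_dna
from feralscan.te import revcomp


class TestSimulateProbeReads:
    def test_minimal_scaffold_one_pair(self):
        rng = np.random.default_rng(0)
        reads = simulate_probe_reads({"sc": random_dna(rng, 1000)})
        assert len(reads) == 2  # one pair
        assert reads[0].offset == 0 and reads[1].offset == 500

    def test_count_formula(self):
        rng = np.random.default_rng(0)
        reads = simulate_probe_reads({"sc": random_dna(rng, 1000 + 2500)})
        assert len(reads) == 2 * 3  # floor(2500/1000)+1 pairs

    def test_short_scaffold_zero_reads_flagged(self):
        with pytest.warns(UserWarning):
            reads = simulate_probe_reads({"sc": "ACGT" * 100})
        assert reads == []

    def test_offsets_reconstruct_positions(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 5000)
        for r in simulate_probe_reads({"sc": seq}):
            assert seq[r.offset : r.offset + 500] == r.seq

    def test_outer_span_mode(self):
        rng = np.random.default_rng(2)
        reads = simulate_probe_reads({"sc": random_dna(rng, 1500)}, span_mode="outer")
        assert len(reads) == 2  # span 1500 -> exactly one pair


class TestMapProbeReads:
    def setup_ref(self):
        rng = np.random.default_rng(3)
        return {"chr1A": random_dna(rng, 10_000), "chr2B": random_dna(rng, 10_000)}

    def test_verbatim_read_hits_source(self):
        ref = self.setup_ref()
        reads = simulate_probe_reads({"sc": ref["chr2B"][2_000:4_000]})
        hits = map_probe_reads(reads, ref)
        assert (hits["chrom"] == "chr2B").all()
        assert hits["pos"].iloc[0] == 2_000
        assert (hits["strand"] == "+").all()

    def test_duplicated_read_unmapped(self):
        rng = np.random.default_rng(4)
        probe = random_dna(rng, 500)
        filler = random_dna(rng, 2000)
        ref = {"chr1A": probe + filler + probe + random_dna(rng, 500)}
        reads = simulate_probe_reads({"sc": probe + filler[:500]})
        hits = map_probe_reads(reads, ref)
        assert hits.loc[hits["offset"] == 0, "chrom"].isna().all()

    def test_reverse_complement_hits_minus_strand(self):
        ref = self.setup_ref()
        reads = simulate_probe_reads({"sc": revcomp(ref["chr1A"][1_000:3_000])})
        hits = map_probe_reads(reads, ref)
        assert (hits["strand"] == "-").all()


class TestAssignChromosome:
    def hits(self, counts):
        rows = []
        for chrom, n in counts.items():
            for k in range(n):
                rows.append({"chrom": chrom, "ordinal": k, "mate": 0, "offset": k * 500,
                             "pos": k * 500, "strand": "+"})
        return pd.DataFrame(rows)

    def test_below_min_reads_goes_chrun(self):
        assert assign_chromosome(self.hits({"chr1A": 21}))[0] == "chrUn"

    def test_at_min_reads_assigned(self):
        chrom, n = assign_chromosome(self.hits({"chr1A": 22}))
        assert chrom == "chr1A" and n == 22

    def test_majority_wins(self):
        assert assign_chromosome(self.hits({"chr1A": 30, "chr1B": 5}))[0] == "chr1A"

    def test_tie_breaks_lexicographically(self):
        with pytest.warns(UserWarning):
            chrom, _ = assign_chromosome(self.hits({"chr2B": 25, "chr1A": 25}))
        assert chrom == "chr1A"


class TestPlaceAndOrient:
    def test_forward_scaffold(self):
        rng = np.random.default_rng(5)
        ref = {"chr1A": random_dna(rng, 50_000)}
        sc = {"sc": ref["chr1A"][10_000 : 10_000 + 20_000]}
        hits = map_probe_reads(simulate_probe_reads(sc), ref)
        pos, orient = place_and_orient(hits)
        assert orient == "+"
        assert abs(pos - (10_000 + 20_000 / 2)) < 2_000

    def test_reverse_scaffold(self):
        rng = np.random.default_rng(6)
        ref = {"chr1A": random_dna(rng, 50_000)}
        sc = {"sc": revcomp(ref["chr1A"][10_000 : 30_000])}
        hits = map_probe_reads(simulate_probe_reads(sc), ref)
        _, orient = place_and_orient(hits)
        assert orient == "-"

    def test_no_continuous_run_demotes(self):
        rng = np.random.default_rng(7)
        scattered = pd.DataFrame(
            {
                "chrom": ["chr1A"] * 6,
                "ordinal": range(6),
                "mate": 0,
                "offset": np.arange(6) * 1000,
                "pos": rng.permutation(6) * 50_000,
                "strand": ["+", "-"] * 3,
            }
        )
        with pytest.warns(UserWarning):
            assert place_and_orient(scattered) is None


class TestEndToEndWorld:
    def test_exact_recovery_of_synthetic_world(self):
        ref, scaffolds, truth = generate_scaffold_world(seed=17)
        placements = anchor_scaffolds(scaffolds, ref)
        assert len(placements) == len(scaffolds)
        for _, row in placements.iterrows():
            chrom, off, strand = truth.placements[row["scaffold"]]
            assert row["chrom"] == chrom
            if chrom != "chrUn":
                assert row["orientation"] == strand
        # order along each chromosome matches the truth offsets
        for chrom in set(c for c, _, _ in truth.placements.values() if c != "chrUn"):
            sub = placements[placements["chrom"] == chrom].sort_values("position")
            true_order = sorted(
                (truth.placements[s][1], s) for s in sub["scaffold"]
            )
            assert list(sub["scaffold"]) == [s for _, s in true_order]

    def test_pseudomolecule_length_identity(self):
        ref, scaffolds, truth = generate_scaffold_world(seed=18)
        placements = anchor_scaffolds(scaffolds, ref)
        seqs, agp = build_pseudomolecules(placements, scaffolds, gap=300)
        placed = placements[placements["chrom"] != "chrUn"]
        expected = placed["scaffold"].map(lambda s: len(scaffolds[s])).sum() + 300 * (
            len(placed) - placed["chrom"].nunique()
        )
        assert sum(len(s) for c, s in seqs.items() if c != "chrUn") == expected

    def test_agp_components_reproduce_scaffolds(self):
        ref, scaffolds, truth = generate_scaffold_world(seed=19, n_scaffolds=6)
        placements = anchor_scaffolds(scaffolds, ref)
        seqs, agp = build_pseudomolecules(placements, scaffolds)
        for _, row in agp[agp["component_type"] == "W"].iterrows():
            piece = seqs[row["object"]][row["object_beg"] - 1 : row["object_end"]]
            original = scaffolds[row["component_id"]]
            assert piece == (revcomp(original) if row["orientation"] == "-" else original)

    def test_two_scaffold_gap_arithmetic(self):
        placements = pd.DataFrame(
            {
                "scaffold": ["a", "b"],
                "chrom": ["chr1A", "chr1A"],
                "position": [1.0, 2.0],
                "orientation": ["+", "+"],
                "n_supporting": [30, 30],
            }
        )
        seqs, _ = build_pseudomolecules(placements, {"a": "A" * 120, "b": "C" * 80})
        assert len(seqs["chr1A"]) == 120 + 80 + 300

    def test_single_scaffold_no_gap(self):
        placements = pd.DataFrame(
            {
                "scaffold": ["a"],
                "chrom": ["chr1A"],
                "position": [1.0],
                "orientation": ["+"],
                "n_supporting": [30],
            }
        )
        seqs, _ = build_pseudomolecules(placements, {"a": "A" * 120})
        assert len(seqs["chr1A"]) == 120


class TestAssemblyStats:
    def test_small_example(self):
        stats = assembly_stats([5, 4, 3, 2, 1])
        assert stats["n50"] == 4  # cumulative 5+4=9 >= 7.5
        assert stats["max"] == 5 and stats["total"] == 15

    def test_single_sequence(self):
        assert assembly_stats([1234])["n50"] == 1234

    def test_published_gap_fraction(self):
        stats = assembly_stats([14_707_915_341], gap_bases=153_963_770)
        assert round(100 * stats["gap_fraction"], 2) == 1.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assembly_stats([])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=40))
    def test_matches_brute_force(self, lengths):
        from tests.oracles import n50_brute

        stats = assembly_stats(lengths)
        assert stats["n50"] == n50_brute(lengths, 50)
        assert stats["n90"] == n50_brute(lengths, 90)
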