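"""Helix enumeration, composition sub-runs, and motif selection."""

import numpy as np
import pytest

from duplexscan.helices import (Helix, HelixCriteria, composition_subruns,
                                enumerate_helices, linker_paired_count,
                                pair_class, select_motifs, strand_distance)
from duplexscan.structure_io import PairTable, StructureRecord, \
    parse_dot_bracket

from conftest import (compatible_sequence, oracle_helices, oracle_select,
                      random_pair_table, random_stacked_table)


class TestEnumerate:
    def test_single_hairpin_stack(self):
        pt = parse_dot_bracket("((((....))))")
        helices = enumerate_helices(pt)
        assert len(helices) == 1
        assert helices[0].length_bp == 4
        assert helices[0].pairs == ((1, 12), (2, 11), (3, 10), (4, 9))

    def test_stacking_break_splits_helices(self):
        pt = PairTable.from_pairs(
            20, [(1, 20), (2, 19), (3, 18), (6, 14), (7, 13)])
        helices = enumerate_helices(pt)
        assert [h.length_bp for h in helices] == [3, 2]
        assert helices[1].pairs == ((6, 14), (7, 13))

    def test_all_unpaired(self):
        assert enumerate_helices(parse_dot_bracket("." * 30)) == []

    def test_partition_property(self, rng):
        """Helix lengths sum to the number of pairs; no pair in two helices."""
        for _ in range(50):
            pt = random_stacked_table(rng, int(rng.integers(10, 150)))
            helices = enumerate_helices(pt)
            all_pairs = [p for h in helices for p in h.pairs]
            assert len(all_pairs) == len(set(all_pairs)) == len(pt.pairs())

    def test_matches_sum_diagonal_oracle(self, rng):
        """Agreement with the independent constant-(i+j) grouping oracle."""
        for _ in range(100):
            pt = random_pair_table(rng, int(rng.integers(5, 200)))
            assert sorted(h.pairs for h in enumerate_helices(pt)) == \
                oracle_helices(pt)


class TestComposition:
    def test_uniform_gc_run(self):
        pt = parse_dot_bracket("(((((((((...)))))))))")
        seq = "G" * 9 + "AAA" + "C" * 9
        helix, = enumerate_helices(pt)
        runs = composition_subruns(helix, seq)
        assert [(cls, sub.length_bp) for cls, sub in runs] == [("GC", 9)]

    def test_mixed_runs_partition(self):
        #     GC GC AU GC pairs
        pt = parse_dot_bracket("((((....))))")
        seq = "GGAG" + "AAUU" + "CUCC"
        helix, = enumerate_helices(pt)
        runs = composition_subruns(helix, seq)
        assert [(cls, sub.length_bp) for cls, sub in runs] == \
            [("GC", 2), ("AU", 1), ("GC", 1)]

    def test_non_complementary_pair_rejected(self):
        pt = parse_dot_bracket("(..)")
        with pytest.raises(ValueError, match=r"\(1,4\)"):
            composition_subruns(enumerate_helices(pt)[0], "AGGG")

    def test_wobble_class(self):
        assert pair_class("G", "U") == "GU"
        with pytest.raises(ValueError):
            pair_class("A", "G")

    def test_random_runs_sum_to_helix_length(self, rng):
        """Sub-runs re-derived from per-pair tagging partition the helix."""
        for _ in range(50):
            pt = random_stacked_table(rng, int(rng.integers(20, 150)))
            seq = compatible_sequence(pt, rng)
            for helix in enumerate_helices(pt):
                runs = composition_subruns(helix, seq)
                assert sum(sub.length_bp for _, sub in runs) == helix.length_bp
                tags = [pair_class(seq[i - 1], seq[j - 1])
                        for i, j in helix.pairs]
                flat = [cls for cls, sub in runs for _ in sub.pairs]
                assert flat == tags
                # maximality: adjacent sub-runs differ in class
                classes = [cls for cls, _ in runs]
                assert all(a != b for a, b in zip(classes, classes[1:]))


class TestGeometry:
    def test_hairpin_loop_distance(self):
        helix, = enumerate_helices(parse_dot_bracket("((((((((....))))))))"))
        assert helix.innermost == (8, 13)
        assert strand_distance(helix) == 4

    def test_long_range_distance(self):
        helix = Helix(tuple((1 + m, 100 - m) for m in range(8)))
        assert strand_distance(helix) == 84

    def test_linker_fully_unpaired(self):
        pt = parse_dot_bracket("((((....))))")
        helix, = enumerate_helices(pt)
        assert linker_paired_count(helix, pt) == 0

    def test_linker_with_internal_hairpin(self):
        # outer 2-bp helix; linker holds an 8-bp hairpin => 16 paired nt
        db = "((" + "." * 5 + "((((((((...))))))))" + "." * 5 + "))"
        pt = parse_dot_bracket(db)
        outer = enumerate_helices(pt)[0]
        assert outer.pairs[0] == (1, len(db))
        assert linker_paired_count(outer, pt) == 16

    def test_linker_counts_partners_outside(self):
        # position inside the linker paired to one beyond the 3' strand
        pt = PairTable.from_pairs(30, [(1, 20), (2, 19), (5, 28)])
        outer = enumerate_helices(pt)[0]
        assert outer.innermost == (2, 19)
        assert linker_paired_count(outer, pt) == 1


class TestSelect:
    def _planted_structure(self, dist, linker_pairs=10, length_bp=9):
        """Window-local structure: GC duplex + mixed linker hairpin."""
        n = 2 * length_bp + dist + 20
        pairs = [(1 + m, length_bp + dist + length_bp - m) for m in
                 range(length_bp)]
        h5 = length_bp + 5
        hp = [(h5 + m, h5 + 2 * linker_pairs + 2 - m)
              for m in range(linker_pairs)]
        seq = ["A"] * n
        for i, j in pairs:
            seq[i - 1], seq[j - 1] = "G", "C"
        for k, (i, j) in enumerate(hp):
            seq[i - 1], seq[j - 1] = ("G", "C") if k % 2 else ("A", "U")
        pt = PairTable.from_pairs(n, pairs + hp)
        return StructureRecord(pair_table=pt), "".join(seq)

    def test_planted_gc_duplex_selected(self):
        struct, seq = self._planted_structure(dist=100)
        motifs = select_motifs(struct, seq,
                               HelixCriteria(composition_class="GC"))
        assert len(motifs) == 1
        m = motifs[0]
        assert (m.motif_class, m.length_bp) == ("GC", 9)
        assert m.strand_distance == 100 and m.linker_paired == 20

    def test_close_strands_excluded_then_captured_as_stem(self):
        struct, seq = self._planted_structure(dist=30, linker_pairs=5)
        assert select_motifs(struct, seq,
                             HelixCriteria(composition_class="GC")) == []
        stems = select_motifs(
            struct, seq,
            HelixCriteria(composition_class="GC", hairpin_mode=True))
        assert [m.motif_class for m in stems] == ["GC_stem"]

    def test_short_duplex_excluded_by_length(self):
        struct, seq = self._planted_structure(dist=100, length_bp=7)
        assert select_motifs(struct, seq,
                             HelixCriteria(composition_class="GC")) == []

    def test_subrun_uses_its_own_innermost_pair(self):
        """An AU pair splitting a GC helix yields GC sub-runs whose distance
        is measured from the sub-run's own innermost pair."""
        length = 17  # 8 GC + 1 AU + 8 GC
        dist = 50
        pairs = [(1 + m, 2 * length + dist - m) for m in range(length)]
        n = 2 * length + dist + 4
        seq = ["A"] * n
        for k, (i, j) in enumerate(pairs):
            seq[i - 1], seq[j - 1] = ("A", "U") if k == 8 else ("G", "C")
        # give the linker 16 paired nt
        hp = [(length + 3 + m, length + 22 - m) for m in range(8)]
        for k, (i, j) in enumerate(hp):
            seq[i - 1], seq[j - 1] = ("G", "C") if k % 2 else ("A", "U")
        struct = StructureRecord(pair_table=PairTable.from_pairs(n, pairs + hp))
        motifs = select_motifs(struct, "".join(seq),
                               HelixCriteria(composition_class="GC"))
        # outer GC sub-run: innermost pair is its 8th pair, distance is large;
        # inner GC sub-run: innermost pair hugs the centre, distance = 50
        assert len(motifs) == 2
        dists = sorted(m.strand_distance for m in motifs)
        assert dists == [50, 50 + 2 * 9]

    def test_monotonicity_in_thresholds(self, rng):
        """Raising any threshold never increases the number of motifs."""
        for _ in range(20):
            pt = random_stacked_table(rng, 150, n_helices=8)
            seq = compatible_sequence(pt, rng)
            struct = StructureRecord(pair_table=pt)
            base = HelixCriteria(min_len_bp=2, min_strand_distance=5,
                                 min_linker_paired=0)
            n0 = len(select_motifs(struct, seq, base))
            for tighter in [
                HelixCriteria(min_len_bp=3, min_strand_distance=5,
                              min_linker_paired=0),
                HelixCriteria(min_len_bp=2, min_strand_distance=10,
                              min_linker_paired=0),
                HelixCriteria(min_len_bp=2, min_strand_distance=5,
                              min_linker_paired=2),
            ]:
                assert len(select_motifs(struct, seq, tighter)) <= n0

    def test_class_exclusivity(self, rng):
        """No sub-run is selected as both GC and AU."""
        for _ in range(20):
            pt = random_stacked_table(rng, 120, n_helices=6)
            seq = compatible_sequence(pt, rng)
            struct = StructureRecord(pair_table=pt)
            loose = dict(min_len_bp=1, min_strand_distance=0,
                         min_linker_paired=0)
            gc = {m.pairs for m in select_motifs(
                struct, seq, HelixCriteria(composition_class="GC", **loose))}
            au = {m.pairs for m in select_motifs(
                struct, seq, HelixCriteria(composition_class="AU", **loose))}
            assert gc.isdisjoint(au)

    @pytest.mark.parametrize("comp_class", ["any", "GC", "AU"])
    def test_oracle_equivalence(self, rng, comp_class):
        """Selection agrees with the brute-force oracle on random tables."""
        for _ in range(100):
            pt = random_stacked_table(rng, int(rng.integers(20, 200)),
                                      n_helices=6)
            seq = compatible_sequence(pt, rng)
            struct = StructureRecord(pair_table=pt)
            crit = HelixCriteria(min_len_bp=3, min_strand_distance=8,
                                 min_linker_paired=2,
                                 composition_class=comp_class)
            ours = sorted(m.pairs for m in select_motifs(struct, seq, crit))
            oracle = oracle_select(pt, seq, min_bp=3, min_dist=8,
                                   min_linker=2, comp_class=comp_class)
            assert ours == oracle
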