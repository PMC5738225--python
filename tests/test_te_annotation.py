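import numpy as np
import pytest

from repeatscape import te_annotation as ta
from repeatscape._seq import revcomp
from repeatscape.io_formats import TELibraryEntry

from .oracles import best_ungapped_local, merge_bridge_fixpoint


def _random_seq(n, seed=0):
    r = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in r.integers(0, 4, size=n))


_FLIP = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _mutate_evenly(seq, n_mut):
    """Deterministically mutate n_mut positions, evenly spread."""
    out = list(seq)
    for k in range(n_mut):
        i = k * len(seq) // n_mut
        out[i] = _FLIP[out[i]]
    return "".join(out)


def _mutate_grouped(seq, n_mut, group=3):
    """Mutate n_mut positions in groups of adjacent substitutions, evenly
    spread. Keeps exact-seed words between groups (a word-size-limited
    aligner needs intact k-mers) while holding every ~50 bp window well below
    100% identity."""
    out = list(seq)
    n_groups = max(1, n_mut // group)
    for g in range(n_groups):
        start = g * len(seq) // n_groups
        for j in range(min(group, len(seq) - start)):
            out[start + j] = _FLIP[out[start + j]]
    return "".join(out)


class TestSegmentGenome:
    def test_exact_tiling(self):
        segs = ta.segment_genome({"c1": "A" * 540})
        assert segs == [("c1", 0, 180), ("c1", 180, 360), ("c1", 360, 540)]

    def test_final_partial_segment_retained(self):
        segs = ta.segment_genome({"c1": "A" * 500})
        assert [e - s for _, s, e in segs] == [180, 180, 140]

    def test_empty_assembly(self):
        assert ta.segment_genome({}) == []

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            ta.segment_genome({"c1": "ACGT"}, segment_length=10)


class TestSearchSegments:
    @pytest.fixture(scope="class")
    @staticmethod
    def family():
        return TELibraryEntry("RLG_simQ", _random_seq(1000, seed=3))

    def test_exact_slice_hits_full_segment(self, family):
        genome = {"c1": family.sequence[200:380]}
        (hit,) = ta.search_segments(genome, [family])
        assert hit.identity == 100.0
        assert (hit.start, hit.end) == (0, 180)
        assert (hit.lib_start, hit.lib_end) == (200, 380)
        assert hit.strand == "+"

    def test_pure_n_segment_no_hits(self, family):
        assert ta.search_segments({"c1": "N" * 180}, [family]) == []

    def test_identity_threshold_boundary(self, family):
        seg = _mutate_grouped(family.sequence[100:280], 27)  # 85% identity
        genome = {"c1": seg}
        assert ta.search_segments(genome, [family], min_identity=90) == []
        hits = ta.search_segments(genome, [family], min_identity=80)
        assert len(hits) == 1
        # verify against the quadratic oracle (max-scoring span may trim a
        # boundary mutation group, so identity sits a little above 85%)
        _, length, ident = best_ungapped_local(seg, family.sequence)
        assert 80.0 < ident < 90.0
        assert hits[0].identity == pytest.approx(ident, abs=1.0)

    def test_minus_strand_hit_maps_to_forward_consensus(self, family):
        genome = {"c1": revcomp(family.sequence[300:480])}
        (hit,) = ta.search_segments(genome, [family])
        assert hit.strand == "-"
        assert (hit.lib_start, hit.lib_end) == (300, 480)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            ta.search_segments({"c1": "ACGT" * 50}, [])

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_quadratic_oracle(self, seed):
        """Same top family and identity within 1 point on small instances."""
        rng = np.random.default_rng(seed)
        libs = [TELibraryEntry(f"RLG_sim{i}", _random_seq(400, seed=100 + seed * 7 + i))
                for i in range(3)]
        src = libs[seed % 3]
        frag = src.sequence[50:350]
        frag = _mutate_grouped(frag, int(rng.integers(0, 40)))
        hits = ta.search_segments({"c1": frag}, libs,
                                  segment_length=len(frag), min_identity=60)
        by_score = {}
        for lib in libs:
            s_f = best_ungapped_local(frag, lib.sequence)
            s_r = best_ungapped_local(frag, revcomp(lib.sequence))
            by_score[lib.name] = max(s_f, s_r)
        oracle_best = max(by_score, key=lambda k: by_score[k])
        assert hits, "aligner found nothing where oracle scores exist"
        top = max(hits, key=lambda h: (h.end - h.start, h.identity))
        assert top.family == oracle_best
        assert top.identity == pytest.approx(by_score[oracle_best][2], abs=1.0)


def _hit(start, end, family="RLG_simA", strand="+", identity=90.0, chrom="c1",
         lib_start=0, lib_end=0):
    return ta.SegmentHit(chrom, start // 180, start, end, family, strand,
                        identity, lib_start, lib_end)


class TestMergeAndBridge:
    def test_gap_99_bridged(self):
        anns = ta.merge_and_bridge([_hit(100, 280), _hit(379, 559)])
        assert [(a.start, a.end) for a in anns] == [(100, 559)]

    def test_gap_100_not_bridged(self):
        anns = ta.merge_and_bridge([_hit(100, 280), _hit(380, 560)])
        assert [(a.start, a.end) for a in anns] == [(100, 280), (380, 560)]

    def test_opposite_strands_not_bridged(self):
        anns = ta.merge_and_bridge([_hit(100, 280), _hit(379, 559, strand="-")])
        assert len(anns) == 2

    def test_intervening_family_blocks_bridging(self):
        other = _hit(300, 350, family="DTT_simB")
        anns = ta.merge_and_bridge([_hit(100, 280), other, _hit(379, 559)])
        fams = sorted((a.family, a.start, a.end) for a in anns)
        assert ("RLG_simA", 100, 280) in fams and ("RLG_simA", 379, 559) in fams

    def test_extension_to_assembly_gap(self):
        anns = ta.merge_and_bridge([_hit(100, 280)],
                                   assembly_gaps={"c1": [(340, 400)]})
        assert anns[0].end == 340  # 60 bp away < 80

    def test_no_extension_beyond_80(self):
        anns = ta.merge_and_bridge([_hit(100, 280)],
                                   assembly_gaps={"c1": [(361, 400)]})
        assert anns[0].end == 280

    def test_extension_on_left_side(self):
        anns = ta.merge_and_bridge([_hit(500, 700)],
                                   assembly_gaps={"c1": [(400, 450)]})
        assert anns[0].start == 450

    def test_best_identity_recorded(self):
        anns = ta.merge_and_bridge([_hit(0, 100, identity=85.0),
                                    _hit(150, 250, identity=95.0)])
        assert anns[0].identity == 95.0

    def test_consensus_span_accumulated(self):
        anns = ta.merge_and_bridge([_hit(0, 100, lib_start=0, lib_end=100),
                                    _hit(150, 250, lib_start=160, lib_end=260)])
        assert (anns[0].lib_min, anns[0].lib_max) == (0, 260)

    @staticmethod
    def _random_hits(rng, n):
        hits = []
        for _ in range(n):
            s = int(rng.integers(0, 600))
            e = s + int(rng.integers(1, 150))
            hits.append(_hit(s, e,
                             family=rng.choice(["RLG_a", "RLC_b", "DTT_c"]),
                             strand=rng.choice(["+", "-"]),
                             identity=float(rng.integers(80, 101))))
        return hits

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_fixpoint_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hits = self._random_hits(rng, int(rng.integers(1, 11)))
        got = sorted((a.start, a.end, a.family, a.strand, a.identity)
                     for a in ta.merge_and_bridge(hits))
        assert got == merge_bridge_fixpoint(hits)

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(1000 + seed)
        hits = self._random_hits(rng, 10)
        once = ta.merge_and_bridge(hits)
        twice = ta.merge_and_bridge(once)
        assert [(a.start, a.end, a.family, a.strand) for a in once] == \
               [(a.start, a.end, a.family, a.strand) for a in twice]

    @pytest.mark.parametrize("seed", range(10))
    def test_no_same_family_strand_overlap(self, seed):
        rng = np.random.default_rng(2000 + seed)
        anns = ta.merge_and_bridge(self._random_hits(rng, 10))
        seen = {}
        for a in sorted(anns, key=lambda a: a.start):
            key = (a.chromosome, a.family, a.strand)
            if key in seen:
                assert a.start >= seen[key]
            seen[key] = a.end


class TestDetectFullLength:
    def _ann(self, lib_min, lib_max, strand="+"):
        return ta.MergedAnnotation("c1", 0, 1000, "RLG_simA", "Gypsy", strand,
                                   95.0, lib_min=lib_min, lib_max=lib_max)

    def test_full_copy_both_flags(self):
        (a,) = ta.detect_full_length([self._ann(0, 1000)], {"RLG_simA": 1000})
        assert a.five_prime_intact and a.three_prime_intact

    def test_truncated_five_prime(self):
        (a,) = ta.detect_full_length([self._ann(500, 1000)], {"RLG_simA": 1000})
        assert a.five_prime_intact is False and a.three_prime_intact is True

    def test_minus_strand_full_copy(self):
        (a,) = ta.detect_full_length([self._ann(0, 1000, strand="-")],
                                     {"RLG_simA": 1000})
        assert a.complete

    def test_tolerance_window(self):
        (a,) = ta.detect_full_length([self._ann(20, 985)], {"RLG_simA": 1000},
                                     end_tolerance=20)
        assert a.five_prime_intact and a.three_prime_intact

    def test_without_support_flags_unknown(self):
        (a,) = ta.detect_full_length([self._ann(-1, -1)], {"RLG_simA": 1000})
        assert a.five_prime_intact is None and a.three_prime_intact is None


class TestAssignFamily8080:
    @pytest.fixture(scope="class")
    @staticmethod
    def library():
        return [TELibraryEntry("RLG_simA", _random_seq(800, seed=21)),
                TELibraryEntry("RLC_simB", _random_seq(800, seed=22))]

    def test_exact_copy(self, library):
        assert ta.assign_family_80_80(library[0].sequence, library) == "RLG_simA"

    def test_half_identity_unassigned(self, library):
        seq = _mutate_evenly(library[0].sequence, 400)
        assert ta.assign_family_80_80(seq, library) == "unassigned"

    def test_85_percent_over_85_length_assigned(self, library):
        frag = library[1].sequence[: int(0.85 * 800)]
        seq = _mutate_grouped(frag, int(0.15 * len(frag)))
        _, _, ident = best_ungapped_local(seq, library[1].sequence)
        assert ident > 80.0  # oracle confirms the construction
        assert ta.assign_family_80_80(seq, library) == "RLC_simB"

    def test_below_80_length_unassigned(self, library):
        assert ta.assign_family_80_80(library[0].sequence[:600], library) == \
            "RLG_simA"  # 75% of consensus but 100% of the (shorter) query
        short = library[0].sequence[:100]
        mutated = _mutate_evenly(short, 25)
        assert ta.assign_family_80_80(mutated, library) == "unassigned"

    def test_empty_sequence_rejected(self, library):
        with pytest.raises(ValueError):
            ta.assign_family_80_80("", library)


class TestBuildConsensus:
    MASTER = _random_seq(120, seed=33)

    def test_majority_recovers_master(self):
        copies = []
        for i in range(3):
            c = list(self.MASTER)
            c[10 + i * 30] = {"A": "C", "C": "G", "G": "T", "T": "A"}[c[10 + i * 30]]
            copies.append("".join(c))
        build = ta.build_consensus(copies)
        assert build.consensus == self.MASTER
        assert build.n_copies == 3

    def test_two_copies_refused(self):
        with pytest.raises(ValueError, match="at least 3"):
            ta.build_consensus([self.MASTER, self.MASTER])

    def test_identical_copies(self):
        build = ta.build_consensus([self.MASTER] * 5)
        assert build.consensus == self.MASTER
        assert np.all(build.majority_fraction == 1.0)

    def test_no_gap_characters_in_consensus(self):
        copies = [self.MASTER, self.MASTER, self.MASTER[:100]]
        try:
            build = ta.build_consensus(copies)
        except RuntimeError:
            pytest.skip("mafft unavailable")
        assert "-" not in build.consensus
        assert len(build.consensus) <= build.n_columns

    def test_tie_broken_by_global_frequency_then_alphabet(self):
        copies = ["AAAT", "AAAG", "CAAA", "GAAA"]
        build = ta.build_consensus(copies, min_copies=3)
        # first column ties A/C/G... global frequency favours A
        assert build.consensus[0] == "A"


class TestClassifyAutonomy:
    @staticmethod
    def _orf_sequence(n_codons=900, seed=44):
        rng = np.random.default_rng(seed)
        codons = [c for c in
                  ("".join(x) for x in __import__("itertools").product("ACGT", repeat=3))
                  if c not in ("TAA", "TAG", "TGA")]
        body = "".join(codons[i] for i in rng.integers(len(codons), size=n_codons - 1))
        return "CC" + "ATG" + body + "TAA" + "GG"

    def test_long_orf_autonomous(self):
        assert ta.classify_autonomy(self._orf_sequence(900)) == "autonomous"

    def test_stops_inserted_make_non_autonomous(self):
        seq = self._orf_sequence(900)
        broken = list(seq)
        # break the ORF into < 300-codon pieces with in-frame stops
        for codon_i in (220, 450, 680):
            pos = 2 + 3 * codon_i
            broken[pos:pos + 3] = "TGA"
        assert ta.classify_autonomy("".join(broken)) == "non-autonomous"

    def test_all_n_non_autonomous(self):
        assert ta.classify_autonomy("N" * 3000) == "non-autonomous"

    def test_minus_strand_orf_detected(self):
        assert ta.classify_autonomy(revcomp(self._orf_sequence(400))) == \
            "autonomous"

    def test_threshold_configurable(self):
        seq = self._orf_sequence(200)
        assert ta.classify_autonomy(seq) == "non-autonomous"
        assert ta.classify_autonomy(seq, min_orf_codons=150) == "autonomous"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ta.classify_autonomy("")
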