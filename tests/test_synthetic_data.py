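import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repeatscape import synthetic_data as sd
from repeatscape import te_annotation as ta
from repeatscape._seq import revcomp
from repeatscape.io_formats import TELibraryEntry


class TestGenerateLibrary:
    def test_deterministic_under_seed(self):
        a = sd.generate_te_library(3, length_range=(200, 600), seed=1)
        b = sd.generate_te_library(3, length_range=(200, 600), seed=1)
        assert [(e.name, e.sequence) for e in a] == \
               [(e.name, e.sequence) for e in b]

    def test_requested_superfamily_and_length(self):
        (e,) = sd.generate_te_library(1, length_range=(150, 150),
                                      superfamily_mix=["DTT"], seed=2)
        assert e.name.startswith("DTT_")
        assert e.length == 150

    def test_mix_mapping(self):
        lib = sd.generate_te_library(3, length_range=(200, 400),
                                     superfamily_mix={"RLG": 2, "DHH": 1},
                                     seed=3)
        assert sorted(e.code for e in lib) == ["DHH", "RLG", "RLG"]

    def test_families_distinct_under_80_80(self, small_library):
        for i, e in enumerate(small_library):
            others = small_library[:i] + small_library[i + 1:]
            assert ta.assign_family_80_80(e.sequence, others) == "unassigned"

    def test_autonomy_flags_consistent(self):
        lib = sd.generate_te_library(6, length_range=(1200, 2500), seed=4,
                                     autonomous_fraction=0.7)
        for e in lib:
            expected = "autonomous" if e.autonomous else "non-autonomous"
            assert ta.classify_autonomy(e.sequence) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sd.generate_te_library(0)
        with pytest.raises(ValueError):
            sd.generate_te_library(2, superfamily_mix={"RLG": 1}, seed=0)
        with pytest.raises(ValueError):
            sd.generate_te_library(1, superfamily_mix=["ZZZ"], seed=0)


def _uniform_spec(entry, n, **kw):
    return sd.FamilySpec(entry=entry, copy_number=n, niche="uniform", **kw)


class TestSimulateGenome:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_sim():
        lib = sd.generate_te_library(2, length_range=(200, 500),
                                     superfamily_mix=["RLG", "DTT"], seed=7)
        specs = [_uniform_spec(lib[0], 40, divergence=0.02),
                 _uniform_spec(lib[1], 40, truncation_prob=0.5)]
        assembly, truth = sd.simulate_genome(
            {"c1": 1_000_000, "c2": 800_000}, sd.GeneSpec(n_genes=20),
            specs, seed=8)
        return lib, specs, assembly, truth

    def test_deterministic(self, small_sim):
        lib, specs, assembly, truth = small_sim
        assembly2, truth2 = sd.simulate_genome(
            {"c1": 1_000_000, "c2": 800_000}, sd.GeneSpec(n_genes=20),
            specs, seed=8)
        assert assembly2.sequences == assembly.sequences
        assert truth2.annotations == truth.annotations
        assert truth2.genes == truth.genes

    def test_truth_within_bounds(self, small_sim):
        _, _, assembly, truth = small_sim
        for a in truth.annotations:
            assert 0 <= a.start < a.end <= assembly.lengths[a.chromosome]

    def test_planted_content_matches_truth(self, small_sim):
        """Non-truncated, non-diverged copies are byte-identical to the
        consensus at their recorded interval (strand-aware)."""
        lib, _, assembly, truth = small_sim
        cons = {e.name: e.sequence for e in lib}
        checked = 0
        for a in truth.annotations:
            if not a.complete or a.identity < 100.0:
                continue
            got = assembly.sequences[a.chromosome][a.start:a.end]
            want = cons[a.family] if a.strand == "+" else revcomp(cons[a.family])
            assert got == want
            checked += 1
        assert checked > 10

    def test_genes_do_not_overlap_tes(self, small_sim):
        _, _, _, truth = small_sim
        for g in truth.genes:
            for a in truth.annotations:
                if a.chromosome == g.chromosome:
                    assert a.end <= g.start or a.start >= g.end

    def test_precondition_on_total_bp(self, entry_factory):
        e = entry_factory(length=5000)
        with pytest.raises(ValueError, match="exceed"):
            sd.simulate_genome({"c1": 50_000},
                               sd.GeneSpec(n_genes=1),
                               [_uniform_spec(e, 100)], seed=0)

    def test_uniform_niche_positions_ks(self):
        """KS test of uniform-niche copy positions against uniform."""
        e = TELibraryEntry("RSX_simU", "ACGT" * 25)  # 100 bp
        _, truth = sd.simulate_genome(
            {"c1": 10_000_000}, sd.GeneSpec(n_genes=5),
            [_uniform_spec(e, 1000)], seed=9)
        mids = np.array([a.midpoint for a in truth.annotations])
        assert len(mids) == 1000
        _, p = stats.kstest(mids / 10_000_000, "uniform")
        assert p > 0.01

    def test_ta_motif_flanks_by_construction(self):
        motif = sd.TargetSiteMotif(left="T", right="A")
        e = TELibraryEntry("DTT_simM", "GGCC" * 30)
        asm, truth = sd.simulate_genome(
            {"c1": 2_000_000}, sd.GeneSpec(n_genes=5),
            [sd.FamilySpec(entry=e, copy_number=100, motif=motif)], seed=10)
        n_checked = 0
        for a, fb in zip(truth.annotations, truth.fallback):
            if fb:
                continue
            seq = asm.sequences[a.chromosome]
            if a.strand == "+":
                left, right = seq[a.start - 1], seq[a.end]
            else:
                left, right = revcomp(seq[a.end]), revcomp(seq[a.start - 1])
            assert (left, right) == ("T", "A")
            n_checked += 1
        assert n_checked >= 90  # T..A point matches are abundant

    def test_distal_niche_enriched_toward_telomeres(self):
        e = TELibraryEntry("RLC_simD", "ACGT" * 50)
        _, truth = sd.simulate_genome(
            {"c1": 5_000_000}, sd.GeneSpec(n_genes=5),
            [sd.FamilySpec(entry=e, copy_number=400, niche="distal",
                           concentration=4.0)], seed=11)
        c = truth.centromeres["c1"]
        mids = np.array([a.midpoint for a in truth.annotations])
        # arm-relative position: 0 at centromere, 1 at telomere
        t = np.where(mids < c, (c - mids) / c, (mids - c) / (5_000_000 - c))
        assert np.median(t) > 0.65

    def test_tss_distance_preference(self):
        e = TELibraryEntry("DTT_simT", "TTAA" * 40)
        asm, truth = sd.simulate_genome(
            {"c1": 4_000_000}, sd.GeneSpec(n_genes=60),
            [sd.FamilySpec(entry=e, copy_number=100,
                           tss_distance=(1500, 0.3))], seed=12)
        dists = []
        gene_tss = {(g.chromosome, g.id): g for g in truth.genes}
        for a in truth.annotations:
            best = min(abs(a.end - g.tss) if g.strand == "+"
                       else abs(a.start - g.tss)
                       for g in truth.genes if g.chromosome == a.chromosome)
            dists.append(best)
        assert 500 < np.median(dists) < 4000


class TestSimulateMethylome:
    @pytest.fixture(scope="class")
    @staticmethod
    def flat_sim():
        e = TELibraryEntry("RLG_simZ", "ACGT" * 100)
        assembly, truth = sd.simulate_genome(
            {"c1": 300_000}, sd.GeneSpec(n_genes=3),
            [_uniform_spec(e, 10)], seed=13)
        return assembly, truth

    def test_zero_depth_gives_zero_totals(self, flat_sim):
        assembly, truth = flat_sim
        spec = sd.MethylomeSpec(depth_mean=0.0)
        calls = sd.simulate_methylome(assembly, truth.genes, truth, spec, seed=1)
        assert (calls["total"] == 0).all()

    def test_baseline_recovery_far_from_genes(self, flat_sim):
        """Windowed CG level converges to the configured baseline away from
        genes (binomial concentration at high depth)."""
        assembly, truth = flat_sim
        spec = sd.MethylomeSpec(depth_mean=40.0)
        calls = sd.simulate_methylome(assembly, truth.genes, truth, spec, seed=2)
        far = calls[calls["context"] == "CG"].copy()
        # keep sites > tss_dip_width away from every TSS
        for g in truth.genes:
            far = far[(far["position"] - g.tss).abs() > spec.tss_dip_width]
        level = far["methylated"].sum() / far["total"].sum()
        assert level == pytest.approx(spec.baseline["CG"], abs=0.01)

    def test_contexts_match_trinucleotides(self, flat_sim):
        assembly, truth = flat_sim
        spec = sd.MethylomeSpec()
        calls = sd.simulate_methylome(assembly, truth.genes, truth, spec, seed=3)
        seq = assembly.sequences["c1"]
        sample = calls[calls["strand"] == "+"].sample(200, random_state=0)
        for r in sample.itertuples():
            assert seq[r.position] == "C"
            if r.context == "CG":
                assert seq[r.position + 1] == "G"
            elif r.context == "CHG":
                assert seq[r.position + 1] != "G" and seq[r.position + 2] == "G"
        minus = calls[calls["strand"] == "-"].sample(100, random_state=0)
        for r in minus.itertuples():
            assert seq[r.position] == "G"

    def test_deterministic(self, flat_sim):
        assembly, truth = flat_sim
        spec = sd.MethylomeSpec()
        a = sd.simulate_methylome(assembly, truth.genes, truth, spec, seed=4)
        b = sd.simulate_methylome(assembly, truth.genes, truth, spec, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestSpecs:
    def test_family_spec_validation(self, entry_factory):
        e = entry_factory()
        with pytest.raises(ValueError):
            sd.FamilySpec(entry=e, copy_number=-1)
        with pytest.raises(ValueError):
            sd.FamilySpec(entry=e, copy_number=1, niche="nowhere")
        with pytest.raises(ValueError):
            sd.FamilySpec(entry=e, copy_number=1, truncation_prob=1.5)

    def test_motif_window_capped(self):
        with pytest.raises(ValueError, match="30"):
            sd.TargetSiteMotif(left="N" * 31, right="A")

    def test_methylome_spec_validation(self):
        with pytest.raises(ValueError):
            sd.MethylomeSpec(baseline={"CG": 1.2, "CHG": 0.5, "CHH": 0.1})
        with pytest.raises(ValueError):
            sd.MethylomeSpec(promoter_te_cg_chg_factor=0.0)


class TestWriteSimulation:
    def test_files_written_and_readable(self, tmp_path, small_library):
        from repeatscape import io_formats as iof
        specs = [_uniform_spec(small_library[0], 5)]
        assembly, truth = sd.simulate_genome(
            {"c1": 200_000}, sd.GeneSpec(n_genes=2), specs, seed=20)
        sd.write_simulation(tmp_path, assembly, truth, small_library)
        back = iof.read_fasta(tmp_path / "genome.fa")
        assert back.sequences == assembly.sequences
        tes = iof.read_gff3_te(tmp_path / "truth_te.gff3")
        assert [(t.chromosome, t.start, t.end, t.family) for t in tes] == \
               [(t.chromosome, t.start, t.end, t.family)
                for t in truth.annotations]
        genes = iof.read_gff3_genes(tmp_path / "genes.gff3")
        assert genes == truth.genes
        assert iof.read_centromeres(tmp_path / "centromeres.tsv") == \
            truth.centromeres
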