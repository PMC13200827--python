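import numpy as np
import pandas as pd
import pytest

from gradescape.clinical import who_grade
from gradescape.cnv import call_gene_cnv
from gradescape.errors import SizingError
from gradescape.signatures import cosine_similarity
from gradescape.spectrum import PYRIMIDINE_CONTEXTS, build_spectrum, context_channel, revcomp
from gradescape.synthetic import (
    CohortConfig,
    SyntheticGenome,
    make_reference,
    read_exon_bed,
    simulate_cohort,
    simulate_depths,
    simulate_snvs,
    write_cohort,
)


class TestMakeReference:
    def test_deterministic_given_seed(self, tmp_path):
        g1 = make_reference(seed=1, n_chroms=2, chrom_length=50_000, n_genes=100)
        g2 = make_reference(seed=1, n_chroms=2, chrom_length=50_000, n_genes=100)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        g1.write_fasta(p1)
        g2.write_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()
        b1, b2 = tmp_path / "a.bed", tmp_path / "b.bed"
        g1.write_bed(b1)
        g2.write_bed(b2)
        assert b1.read_bytes() == b2.read_bytes()

    def test_bed_round_trip(self, genome, tmp_path):
        path = tmp_path / "exons.bed"
        genome.write_bed(path)
        back = read_exon_bed(path)
        orig = genome.exons.sort_values(["chrom", "start"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            back[["gene", "chrom", "start", "end", "exon"]].reset_index(drop=True), orig
        )

    def test_all_contexts_present(self, genome):
        index = genome.context_index()
        assert all(index[c] for c in PYRIMIDINE_CONTEXTS)

    def test_forced_exon_count(self):
        g = make_reference(seed=3, n_chroms=1, chrom_length=30_000, n_genes=20,
                           exons_per_gene=(3, 3))
        assert (g.exons.groupby("gene").size() == 3).all()

    def test_impossible_geometry_rejected(self):
        with pytest.raises(SizingError):
            make_reference(seed=1, n_chroms=1, chrom_length=1000, n_genes=50,
                           exons_per_gene=(6, 6))

    def test_exons_within_bounds_and_nonoverlapping(self, genome):
        for chrom, sub in genome.exons.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"] >= 0).all()
            assert (sub["end"] <= len(genome[chrom])).all()
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()


class TestSimulateSnvs:
    def test_zero_mutations(self, genome, sigs):
        assert simulate_snvs(genome, {"S1": 1.0}, 0, sigs, seed=1) == []

    def test_placement_matches_assigned_channel(self, genome, sigs):
        """Every variant's genomic trinucleotide (pyrimidine-normalized)
        classifies into a channel of the generating distribution."""
        vs = simulate_snvs(genome, {"S2": 1.0}, 500, sigs, seed=4)
        spec_counts = np.zeros(96, dtype=int)
        for v in vs:
            seq = genome[v.chrom]
            tri = seq[v.pos - 2 : v.pos + 1]
            assert tri[1] == v.ref  # ref allele taken from the reference strand
            spec_counts[context_channel(tri, v.ref, v.alt)] += 1
        # spectrum rebuilt from placement equals spectrum counted by build_spectrum
        rebuilt = build_spectrum(vs, genome)
        assert np.array_equal(rebuilt.counts, spec_counts)

    def test_single_signature_spectrum_converges(self, genome, sigs):
        vs = simulate_snvs(genome, {"S1": 1.0}, 50_000, sigs, seed=5)
        spec = build_spectrum(vs, genome)
        assert cosine_similarity(spec.counts, sigs.matrix[:, 0]) >= 0.99

    def test_multinomial_l1_concentration(self, genome, sigs):
        """Empirical spectrum concentrates on n*p: the L1 distance stays below
        sqrt(K*n), the standard mean-L1 bound for a K-channel multinomial
        (E||phat - p||_1 <= sqrt(K/n), K = 96)."""
        mixture = {"S1": 0.5, "S3": 0.5}
        p = sigs.columns(["S1", "S3"]) @ np.array([0.5, 0.5])
        n = 10_000
        for seed in range(10):
            vs = simulate_snvs(genome, mixture, n, sigs, seed=seed)
            spec = build_spectrum(vs, genome)
            assert np.abs(spec.counts - n * p).sum() < np.sqrt(96 * n)

    def test_unknown_signature_rejected(self, genome, sigs):
        with pytest.raises(ValueError):
            simulate_snvs(genome, {"NOPE": 1.0}, 10, sigs, seed=1)


class TestSimulateDepths:
    def test_planted_gain_doubles_expected_depth(self, genome):
        table = simulate_depths(genome, {"G0001": 4.0}, mean_depth=100.0, seed=9)
        df = table.depths
        planted = df[df["gene"] == "G0001"]["depth"].mean()
        rest = df[df["gene"] != "G0001"]["depth"].mean()
        assert planted == pytest.approx(200.0, rel=0.15)
        assert rest == pytest.approx(100.0, rel=0.05)

    def test_no_planting_all_diploid(self, genome):
        table = simulate_depths(genome, {}, mean_depth=80.0, seed=9)
        assert table.depths["depth"].mean() == pytest.approx(80.0, rel=0.05)

    def test_deterministic(self, genome):
        t1 = simulate_depths(genome, {"G0002": 1.0}, 100.0, seed=11)
        t2 = simulate_depths(genome, {"G0002": 1.0}, 100.0, seed=11)
        pd.testing.assert_frame_equal(t1.depths, t2.depths)


@pytest.fixture(scope="module")
def bundle(genome, sigs):
    return simulate_cohort(CohortConfig(seed=42), genome, sigs)


class TestSimulateCohort:
    def test_cohort_structure(self, bundle):
        clin = bundle.clinical
        assert len(clin) == 24
        assert clin["grade"].value_counts().to_dict() == {"G3": 12, "G1": 6, "G2": 6}

    def test_burden_ordered_by_grade(self, bundle):
        counts = pd.Series([v.sample for v in bundle.variants]).value_counts()
        grade = bundle.clinical.set_index("sample")["grade"]
        means = counts.groupby(grade).mean()
        assert means["G1"] < means["G2"] < means["G3"]

    def test_grading_consistency(self, bundle):
        """who_grade on the generated Ki-67/mitoses reproduces every label."""
        for row in bundle.clinical.itertuples(index=False):
            assert who_grade(row.mitoses, row.ki67) == row.grade

    def test_planted_cnvs_recorded_and_multi_exon(self, genome, bundle):
        exon_counts = genome.exons.groupby("gene").size()
        assert bundle.truth["planted_cnvs"]
        for sample, gene, cn in bundle.truth["planted_cnvs"]:
            assert cn in (1.0, 4.0)
            assert exon_counts[gene] >= 3

    def test_vaf_medians_near_targets(self, bundle):
        df = pd.DataFrame(
            {
                "sample": [v.sample for v in bundle.variants],
                "vtype": [v.vtype for v in bundle.variants],
                "vaf": [v.vaf for v in bundle.variants],
            }
        )
        grade = bundle.clinical.set_index("sample")["grade"]
        snv = df[df["vtype"] == "SNV"]
        med = snv.groupby(snv["sample"].map(grade))["vaf"].median()
        for g, target in zip(("G1", "G2", "G3"), (0.128, 0.153, 0.190)):
            assert med[g] == pytest.approx(target, abs=0.03)

    def test_deterministic_given_config(self, genome, sigs, bundle):
        again = simulate_cohort(CohortConfig(seed=42), genome, sigs)
        assert [(v.chrom, v.pos, v.ref, v.alt) for v in again.variants] == [
            (v.chrom, v.pos, v.ref, v.alt) for v in bundle.variants
        ]
        pd.testing.assert_frame_equal(again.clinical, bundle.clinical)

    def test_planted_gains_recovered_by_caller(self, genome, bundle):
        calls = {(c.sample, c.gene): c.status for c in call_gene_cnv(bundle.depths)}
        gains = [(s, g) for s, g, cn in bundle.truth["planted_cnvs"] if cn == 4.0]
        recalled = sum(calls[k] == "gain" for k in gains)
        assert recalled / len(gains) >= 0.95

    def test_write_cohort_round_trip(self, genome, bundle, tmp_path):
        from gradescape.cnv import ExonDepthTable
        from gradescape.variants import read_variant_tsv

        paths = write_cohort(bundle, genome, tmp_path)
        back = read_variant_tsv(paths["variants"])
        assert back == bundle.variants
        table = ExonDepthTable.from_tsv(paths["depths"])
        pd.testing.assert_frame_equal(table.depths, bundle.depths.depths)
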