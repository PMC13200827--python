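import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gradescape.errors import AlleleError, ContextError
from gradescape.spectrum import (
    CHANNEL_LABELS,
    SNV_CLASSES,
    Spectrum96,
    build_spectrum,
    context_channel,
    effect_tally,
    hypermutation_scan,
    revcomp,
    snv_class,
    titv,
)
from gradescape.variants import Variant


def mk(chrom="chr1", pos=100, ref="A", alt="T", **kw):
    return Variant(sample="S", chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


class TestSnvClass:
    @pytest.mark.parametrize(
        "ref,alt,cls",
        [("C", "T", "C>T"), ("G", "A", "C>T"), ("A", "C", "T>G"),
         ("T", "A", "T>A"), ("G", "T", "C>A"), ("A", "G", "T>C")],
    )
    def test_pyrimidine_normalization(self, ref, alt, cls):
        assert snv_class(ref, alt) == cls

    def test_rejects_bad_alleles(self):
        with pytest.raises(AlleleError):
            snv_class("N", "A")
        with pytest.raises(AlleleError):
            snv_class("C", "C")


class TestContextChannel:
    def test_first_and_last_channels(self):
        assert context_channel("ACA", "C", "A") == 0
        assert context_channel("TTT", "T", "G") == 95

    def test_purine_context_flank_swap(self):
        # revcomp(TGA) = TCA, so G>A in TGA is T[C>T]A
        assert CHANNEL_LABELS[context_channel("TGA", "G", "A")] == "T[C>T]A"

    def test_middle_base_mismatch(self):
        with pytest.raises(ContextError):
            context_channel("ACA", "T", "G")

    def test_every_channel_reachable_and_labels_consistent(self):
        for i, label in enumerate(CHANNEL_LABELS):
            five, cls, three = label[0], label[2:5], label[6]
            ref, alt = cls.split(">")
            assert context_channel(five + ref + three, ref, alt) == i


class TestBuildSpectrum:
    def test_empty_input(self, genome):
        assert build_spectrum([], genome).total == 0

    def test_single_known_context(self):
        genome = {"chr1": "AACAAT"}
        spec = build_spectrum([mk(pos=3, ref="C", alt="T")], genome)
        assert spec.total == 1
        assert spec.counts[context_channel("ACA", "C", "T")] == 1

    def test_edge_snvs_counted_not_classified(self):
        genome = {"chr1": "ACGT"}
        spec = build_spectrum([mk(pos=1, ref="A", alt="T"), mk(pos=4, ref="T", alt="A")], genome)
        assert spec.total == 0 and spec.skipped_edge == 2

    def test_conservation_and_permutation_invariance(self, genome, rng):
        chrom = "chr1"
        seq = genome[chrom]
        variants = []
        for pos0 in rng.integers(0, len(seq), size=500):
            ref = seq[pos0]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            variants.append(mk(chrom=chrom, pos=int(pos0) + 1, ref=ref, alt=str(alt)))
        spec = build_spectrum(variants, genome)
        assert spec.total + spec.skipped_edge == len(variants)
        shuffled = list(variants)
        rng.shuffle(shuffled)
        assert np.array_equal(build_spectrum(shuffled, genome).counts, spec.counts)

    def test_collapse_matches_direct_class_counts(self, genome, rng):
        seq = genome["chr1"]
        variants = []
        for pos0 in rng.integers(1, len(seq) - 1, size=300):
            ref = seq[pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variants.append(mk(pos=int(pos0) + 1, ref=ref, alt=alt))
        spec = build_spectrum(variants, genome)
        direct = {cls: 0 for cls in SNV_CLASSES}
        for v in variants:
            direct[snv_class(v.ref, v.alt)] += 1
        assert spec.collapse6() == direct

    def test_strand_complement_invariance(self, genome, rng):
        """Spectrum is identical on the reverse-complemented genome with mirrored loci."""
        seq = genome["chr1"]
        variants = []
        for pos0 in rng.integers(1, len(seq) - 1, size=200):
            ref = seq[pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variants.append(mk(pos=int(pos0) + 1, ref=ref, alt=alt))
        mirrored_genome = {"chr1": revcomp(seq)}
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        mirrored = [
            mk(pos=len(seq) - v.pos + 1, ref=comp[v.ref], alt=comp[v.alt]) for v in variants
        ]
        a = build_spectrum(variants, {"chr1": seq})
        b = build_spectrum(mirrored, mirrored_genome)
        assert np.array_equal(a.counts, b.counts)


class TestTiTv:
    def test_worked_example(self):
        vs = [mk(ref="C", alt="T"), mk(ref="T", alt="C"), mk(ref="C", alt="A")]
        assert titv(vs) == (2, 1, 2.0)

    def test_all_transversions(self):
        vs = [mk(pos=i + 1, ref="C", alt="G") for i in range(5)]
        ti, tv, ratio = titv(vs)
        assert (ti, tv, ratio) == (0, 5, 0.0)

    def test_no_transversions_reports_infinity(self):
        ti, tv, ratio = titv([mk(ref="C", alt="T")])
        assert ti == 1 and tv == 0 and ratio == float("inf")

    def test_uniform_classes_give_half(self, rng):
        # 2 of the 6 classes are transitions, so uniform classes => ratio ~ 1/2
        pyr = {"C": "AGT", "T": "ACG"}
        vs = []
        for i in range(6000):
            ref = str(rng.choice(["C", "T"]))
            alt = str(rng.choice(list(pyr[ref])))
            vs.append(mk(pos=i + 1, ref=ref, alt=alt))
        _, _, ratio = titv(vs)
        assert ratio == pytest.approx(0.5, abs=0.05)


class TestEffectTally:
    def test_known_counts_and_canonical_keys(self):
        vs = [mk(pos=i + 1, effect="nonsynonymous SNV") for i in range(3)]
        vs.append(mk(pos=9, effect="stopgain"))
        tally = effect_tally(vs)
        assert tally["nonsynonymous SNV"] == 3 and tally["stopgain"] == 1
        assert sum(tally.values()) == 4 and len(tally) == 10

    def test_unknown_effect_pooled_with_warning(self):
        with pytest.warns(UserWarning, match="weird"):
            tally = effect_tally([mk(effect="weird")])
        assert tally["other"] == 1


class TestHypermutationScan:
    def test_concentrated_mutations_rank_first(self, genome):
        vs = [mk(pos=1500 + i, ref=genome["chr1"][1499 + i], alt="T" if genome["chr1"][1499 + i] != "T" else "A")
              for i in range(30)]
        regions = hypermutation_scan(vs, genome, window=5000)
        assert regions[0].chrom == "chr1" and regions[0].start == 1
        assert regions[0].count == 30

    def test_window_larger_than_chromosome_clamps(self, genome):
        regions = hypermutation_scan([], genome, window=10_000_000)
        assert len(regions) == len(genome)
        for r in regions:
            assert r.end == len(genome[r.chrom])

    def test_tiling_covers_chromosomes_without_overlap(self, genome):
        regions = hypermutation_scan([], genome, window=7000)
        by_chrom = {}
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in by_chrom.items():
            assert rs[0].start == 1 and rs[-1].end == len(genome[chrom])
            for a, b in zip(rs, rs[1:]):
                assert b.start == a.end + 1

    def test_uniform_placement_is_not_flagged(self, genome, rng):
        """Max/median density stays modest for uniform mutations (order statistics)."""
        seq = genome["chr1"]
        vs = [mk(pos=int(p) + 1, ref=seq[p], alt="A" if seq[p] != "A" else "C")
              for p in rng.integers(1, len(seq) - 1, size=1000)]
        regions = [r for r in hypermutation_scan(vs, genome, window=5000) if r.chrom == "chr1"]
        dens = np.array([r.per_mb for r in regions])
        assert dens.max() / np.median(dens) < 3
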