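"""Synthetic cohort generation with known ground truth.

Every downstream stage of the pipeline is exercised against cohorts whose
generative parameters are known exactly: a random reference genome with an
exon model, per-sample SNV spectra drawn from known signature mixtures and
placed at genomic sites with matching trinucleotide context, exon read
depths drawn Poisson around planted copy numbers, grade-consistent Ki-67 and
mitotic counts, Beta-distributed VAFs, and exponential progression times
with administrative censoring.

The defaults emulate a 24-sample tumor cohort split 6/6/12 across grades
G1/G2/G3, with mutation burden increasing with grade, a transition-rich
mixture in G1 shifting toward C>T dominance and more transversions in G3,
grade-wise VAF medians near 13/15/19% for SNVs and ~10-11% for indels, and
survival worsening with grade.  None of this models raw reads, tumor purity
or FFPE artifacts beyond the signature mixtures themselves.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cnv import ExonDepthTable
from .errors import ContextUnavailableError, SizingError
from .spectrum import (
    CHANNEL_LABELS,
    PYRIMIDINE_CONTEXTS,
    SNV_CLASSES,
    revcomp,
)
from .signatures import ReferenceSignatures
from .variants import Variant, write_vcf

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SyntheticGenome:
    """Random reference sequences plus a non-overlapping exon model.

    Exon coordinates are 0-based half-open.  The object behaves as a mapping
    from chromosome name to sequence so spectrum/context code can consume it
    directly.
    """

    chroms: dict[str, str]
    exons: pd.DataFrame  # columns: gene, chrom, start, end, exon (0-based index)

    def __post_init__(self) -> None:
        for name, seq in self.chroms.items():
            if set(seq) - set(_BASES):
                raise ValueError(f"chromosome {name} contains non-ACGT characters")
        for row in self.exons.itertuples(index=False):
            if not (0 <= row.start < row.end <= len(self.chroms[row.chrom])):
                raise ValueError(f"exon {row.gene}/{row.exon} outside chromosome {row.chrom}")
        self._context_index: dict[str, list[tuple[str, int]]] | None = None
        self._gene_lookup: dict[str, tuple[list[int], list[int], list[str]]] | None = None

    # mapping protocol over chromosome sequences
    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def __getitem__(self, chrom: str) -> str:
        return self.chroms[chrom]

    def __iter__(self):
        return iter(self.chroms)

    def __len__(self) -> int:
        return len(self.chroms)

    def genes(self) -> list[str]:
        return sorted(self.exons["gene"].unique())

    def context_index(self) -> dict[str, list[tuple[str, int]]]:
        """Positions (chrom, 0-based) of every pyrimidine-centric 3-mer.

        Purine-centred sites are indexed under the reverse complement of
        their context, i.e. by the pyrimidine strand.
        """
        if self._context_index is None:
            index: dict[str, list[tuple[str, int]]] = {c: [] for c in PYRIMIDINE_CONTEXTS}
            for chrom, seq in self.chroms.items():
                for i in range(1, len(seq) - 1):
                    tri = seq[i - 1 : i + 2]
                    key = tri if tri[1] in "CT" else revcomp(tri)
                    index[key].append((chrom, i))
            self._context_index = index
        return self._context_index

    def gene_at(self, chrom: str, pos0: int) -> str | None:
        """Gene whose exon covers a 0-based position, else None."""
        if self._gene_lookup is None:
            lookup: dict[str, tuple[list[int], list[int], list[str]]] = {}
            for c, sub in self.exons.groupby("chrom"):
                sub = sub.sort_values("start")
                lookup[str(c)] = (
                    list(sub["start"]),
                    list(sub["end"]),
                    list(sub["gene"]),
                )
            self._gene_lookup = lookup
        if chrom not in self._gene_lookup:
            return None
        starts, ends, names = self._gene_lookup[chrom]
        i = bisect_right(starts, pos0) - 1
        if i >= 0 and pos0 < ends[i]:
            return names[i]
        return None

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_bed(self, path: str | Path) -> None:
        df = self.exons.sort_values(["chrom", "start"])
        df[["chrom", "start", "end", "gene", "exon"]].to_csv(
            path, sep="\t", index=False, header=False
        )


def read_exon_bed(path: str | Path) -> pd.DataFrame:
    """Read an exon model BED (chrom, start, end, gene, exon index)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene", "exon"]
    )
    return df[["gene", "chrom", "start", "end", "exon"]]


def make_reference(
    seed: int,
    n_chroms: int = 2,
    chrom_length: int = 50_000,
    n_genes: int = 100,
    exons_per_gene: tuple[int, int] = (1, 6),
    exon_length: int = 120,
    gap: int = 40,
) -> SyntheticGenome:
    """Deterministic random genome with a tiling exon model.

    Genes are laid out left to right, split round-robin across chromosomes;
    each gene receives a uniform number of exons in ``exons_per_gene``
    (inclusive), each ``exon_length`` bp, separated by ``gap`` bp.  Sequences
    are redrawn (bounded retries) until all 32 pyrimidine-centric
    trinucleotide contexts occur, which is essentially certain for
    chromosomes of 10 kb or more.
    """
    if chrom_length < 1000:
        raise SizingError(f"chrom_length must be >= 1000, got {chrom_length}")
    if n_genes < 1:
        raise SizingError("need at least one gene")
    lo, hi = exons_per_gene
    if not 1 <= lo <= hi:
        raise SizingError(f"bad exons_per_gene range {exons_per_gene}")
    rng = np.random.default_rng(seed)

    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    exon_counts = rng.integers(lo, hi + 1, size=n_genes)
    cursors = {c: gap for c in chrom_names}
    rows = []
    for g in range(n_genes):
        chrom = chrom_names[g % n_chroms]
        k = int(exon_counts[g])
        need = k * (exon_length + gap) + gap
        if cursors[chrom] + need > chrom_length:
            raise SizingError(
                f"{n_genes} genes x up to {hi} exons do not fit on "
                f"{n_chroms} chromosome(s) of {chrom_length} bp"
            )
        gene = f"G{g + 1:04d}"
        for e in range(k):
            start = cursors[chrom]
            rows.append({"gene": gene, "chrom": chrom, "start": start, "end": start + exon_length, "exon": e})
            cursors[chrom] = start + exon_length + gap
        cursors[chrom] += gap
    exons = pd.DataFrame(rows)

    for _attempt in range(100):
        chroms = {
            name: "".join(rng.choice(list(_BASES), size=chrom_length))
            for name in chrom_names
        }
        genome = SyntheticGenome(chroms=chroms, exons=exons)
        if chrom_length < 10_000:
            return genome
        if all(genome.context_index()[c] for c in PYRIMIDINE_CONTEXTS):
            return genome
    raise SizingError("could not realize all 32 trinucleotide contexts")  # pragma: no cover


def _channel_parts(channel: int) -> tuple[str, str, str, str]:
    """(context, pyrimidine ref, pyrimidine alt, label) of a channel index."""
    cls = SNV_CLASSES[channel // 16]
    five = _BASES[(channel % 16) // 4]
    three = _BASES[channel % 4]
    ref, alt = cls.split(">")
    return five + ref + three, ref, alt, CHANNEL_LABELS[channel]


def simulate_snvs(
    genome: SyntheticGenome,
    mixture: Mapping[str, float],
    n_mutations: int,
    signatures: ReferenceSignatures,
    seed: int,
    sample: str = "S1",
) -> list[Variant]:
    """Draw SNVs from a signature mixture and place them in the genome.

    Channel counts are multinomial with probabilities ``p = sum_k w_k sig_k``;
    each mutation is placed at a site chosen uniformly (with replacement)
    among the genomic positions whose pyrimidine-normalized trinucleotide
    matches the channel.  At purine-strand sites ref/alt are complemented so
    the reported alleles are on the reference strand.  Gene annotations are
    attached where the site falls in an exon.
    """
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    unknown = set(mixture) - set(signatures.ids)
    if unknown:
        raise ValueError(f"mixture references unknown signatures {sorted(unknown)}")
    weights = np.array([float(w) for w in mixture.values()])
    if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must be non-negative and sum to 1")
    if n_mutations == 0:
        return []
    p = signatures.columns(list(mixture)) @ weights
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_mutations, p / p.sum())
    index = genome.context_index()
    out: list[Variant] = []
    for channel in np.nonzero(counts)[0]:
        context, pyr_ref, pyr_alt, label = _channel_parts(int(channel))
        sites = index[context]
        if not sites:
            raise ContextUnavailableError(
                f"context {context} (channel {label}) absent from genome"
            )
        picks = rng.integers(0, len(sites), size=int(counts[channel]))
        for j in picks:
            chrom, pos0 = sites[int(j)]
            base = genome.chroms[chrom][pos0]
            if base in "CT":
                ref, alt = pyr_ref, pyr_alt
            else:
                ref, alt = _COMP[pyr_ref], _COMP[pyr_alt]
            out.append(
                Variant(
                    sample=sample,
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref=ref,
                    alt=alt,
                    gene=genome.gene_at(chrom, pos0),
                )
            )
    return out


def simulate_depths(
    genome: SyntheticGenome,
    planted: Mapping[str, float],
    mean_depth: float,
    seed: int,
    sample: str = "S1",
) -> ExonDepthTable:
    """Per-exon mean depths Poisson(mean_depth x CN/2) for one sample.

    ``planted`` maps gene symbol to true copy number; all other genes are
    diploid.  The table's per-sample mean depth is the empirical mean over
    all exons.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    for gene, cn in planted.items():
        if cn < 0:
            raise ValueError(f"planted copy number for {gene} is negative")
    rng = np.random.default_rng(seed)
    rows = []
    for row in genome.exons.sort_values(["gene", "exon"]).itertuples(index=False):
        cn = float(planted.get(row.gene, 2.0))
        rows.append(
            {
                "sample": sample,
                "gene": row.gene,
                "exon": int(row.exon),
                "depth": int(rng.poisson(mean_depth * cn / 2.0)),
            }
        )
    return ExonDepthTable(pd.DataFrame(rows))


_SNV_EFFECTS = ("nonsynonymous SNV", "synonymous SNV", "stopgain", "splicing", "stoploss")
_SNV_EFFECT_P = (0.60, 0.25, 0.06, 0.08, 0.01)


def _default_mixtures() -> dict[str, dict[str, float]]:
    # Toy-signature mixtures chosen so G1 is transition (T>C)-led and G3 is
    # C>T-led with a C>A transversion component, mirroring the qualitative
    # grade shift the pipeline is meant to resolve.
    return {
        "G1": {"S3": 0.5, "S1": 0.3, "S5": 0.2},
        "G2": {"S1": 0.4, "S3": 0.3, "S5": 0.3},
        "G3": {"S1": 0.5, "S2": 0.3, "S5": 0.2},
    }


@dataclass
class CohortConfig:
    """Generative parameters of a synthetic graded cohort.

    Defaults: 6/6/12 samples in G1/G2/G3; mean somatic SNV burdens 50/150/600
    rising with grade; per-grade toy-signature mixtures; three CN=4 gains and
    three CN=1 losses planted per sample among multi-exon genes; Beta VAFs
    with grade medians 12.8/15.3/19.0% (SNVs) and 10.2/11.4/10.8% (indels);
    exponential progression hazards 0.01/0.02/0.04 per month censored at 60
    months; 100x mean depth.
    """

    samples_per_grade: tuple[int, int, int] = (6, 6, 12)
    grade_mean_snvs: tuple[float, float, float] = (50.0, 150.0, 600.0)
    grade_mixtures: dict[str, dict[str, float]] = field(default_factory=_default_mixtures)
    planted_cnvs: list[tuple[str, str, float]] | None = None
    n_gains_per_sample: int = 3
    n_losses_per_sample: int = 3
    snv_vaf_medians: tuple[float, float, float] = (0.128, 0.153, 0.190)
    indel_vaf_medians: tuple[float, float, float] = (0.102, 0.114, 0.108)
    vaf_concentration: float = 25.0
    indel_burden_fraction: float = 0.15
    germline_leak_rate: float = 0.10
    hazards: tuple[float, float, float] = (0.01, 0.02, 0.04)
    censor_horizon: float = 60.0
    mean_depth: float = 100.0
    p_n0: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.samples_per_grade):
            raise ValueError("sample counts must be non-negative")
        if any(m <= 0 for m in self.grade_mean_snvs):
            raise ValueError("grade mean SNV counts must be positive")
        for grade, mix in self.grade_mixtures.items():
            w = np.array(list(mix.values()))
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"mixture for {grade} must be non-negative and sum to 1")
        if self.planted_cnvs is not None:
            for _, gene, cn in self.planted_cnvs:
                if cn < 0:
                    raise ValueError(f"true copy number for {gene} must be >= 0")
        if any(h <= 0 for h in self.hazards):
            raise ValueError("hazards must be positive")


@dataclass
class CohortBundle:
    """A generated cohort plus its generative truth."""

    variants: list[Variant]
    depths: ExonDepthTable
    clinical: pd.DataFrame
    truth: dict


_GRADE_BOXES = {
    # (ki67 lo, ki67 hi, mitoses lo, mitoses hi) consistent with each WHO grade
    "G1": (0.2, 2.8, 0.0, 1.8),
    "G2": (3.0, 20.0, 2.0, 20.0),
    "G3": (20.5, 85.0, 20.5, 55.0),
}


def _beta_params(median: float, concentration: float) -> tuple[float, float]:
    return median * concentration, (1.0 - median) * concentration


def _simulate_indels(
    genome: SyntheticGenome, n: int, rng: np.random.Generator, sample: str
) -> list[Variant]:
    out = []
    chroms = list(genome.chroms)
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        seq = genome.chroms[chrom]
        pos0 = int(rng.integers(1, len(seq) - 5))
        if rng.random() < 0.5:  # deletion of 1-3 bp
            dlen = int(rng.integers(1, 4))
            ref, alt = seq[pos0 : pos0 + 1 + dlen], seq[pos0]
            eff_kind = "deletion"
        else:  # insertion of 1-3 bp
            ins = "".join(rng.choice(list(_BASES), size=int(rng.integers(1, 4))))
            ref, alt = seq[pos0], seq[pos0] + ins
            eff_kind = "insertion"
        frameshift = (abs(len(ref) - len(alt)) % 3) != 0
        effect = f"{'frameshift' if frameshift else 'nonframeshift'} {eff_kind}"
        out.append(
            Variant(
                sample=sample,
                chrom=chrom,
                pos=pos0 + 1,
                ref=ref,
                alt=alt,
                gene=genome.gene_at(chrom, pos0),
                effect=effect,
            )
        )
    return out


def simulate_cohort(
    config: CohortConfig,
    genome: SyntheticGenome,
    signatures: ReferenceSignatures,
) -> CohortBundle:
    """Generate a full cohort: variants, exon depths and a clinical table.

    Per-sample SNV counts are Poisson around the grade mean; spectra follow
    the grade's signature mixture; VAFs are Beta with grade-specific medians;
    a ``germline_leak_rate`` fraction of variants carries a common population
    AF (so the 1% filter has work to do); Ki-67 and mitotic counts are drawn
    inside the assigned grade's WHO box; progression times are exponential
    with the grade hazard, administratively censored at the horizon.
    """
    rng = np.random.default_rng(config.seed)
    grades = ["G1", "G2", "G3"]
    samples: list[tuple[str, str]] = []
    for grade, n in zip(grades, config.samples_per_grade):
        samples += [(f"{grade}_{i + 1:02d}", grade) for i in range(n)]

    multi_exon = sorted(
        g for g, sub in genome.exons.groupby("gene") if len(sub) >= 3
    )
    planted: list[tuple[str, str, float]]
    if config.planted_cnvs is not None:
        planted = list(config.planted_cnvs)
    else:
        planted = []
        for sid, _grade in samples:
            chosen = rng.choice(
                multi_exon,
                size=min(config.n_gains_per_sample + config.n_losses_per_sample, len(multi_exon)),
                replace=False,
            )
            for j, gene in enumerate(chosen):
                cn = 4.0 if j < config.n_gains_per_sample else 1.0
                planted.append((sid, str(gene), cn))
    planted_by_sample: dict[str, dict[str, float]] = {}
    for sid, gene, cn in planted:
        planted_by_sample.setdefault(sid, {})[gene] = cn

    grade_idx = {g: i for i, g in enumerate(grades)}
    variants: list[Variant] = []
    depth_frames = []
    clin_rows = []
    for sid, grade in samples:
        gi = grade_idx[grade]
        n_snv = int(rng.poisson(config.grade_mean_snvs[gi]))
        vs = simulate_snvs(
            genome,
            config.grade_mixtures[grade],
            n_snv,
            signatures,
            seed=int(rng.integers(0, 2**31)),
            sample=sid,
        )
        n_indel = int(rng.poisson(config.indel_burden_fraction * config.grade_mean_snvs[gi]))
        vs += _simulate_indels(genome, n_indel, rng, sid)
        a_s, b_s = _beta_params(config.snv_vaf_medians[gi], config.vaf_concentration)
        a_i, b_i = _beta_params(config.indel_vaf_medians[gi], config.vaf_concentration)
        for v in vs:
            if v.is_snv:
                v.vaf = float(np.clip(rng.beta(a_s, b_s), 1e-4, 1.0))
                v.effect = str(rng.choice(_SNV_EFFECTS, p=_SNV_EFFECT_P))
            else:
                v.vaf = float(np.clip(rng.beta(a_i, b_i), 1e-4, 1.0))
            u = rng.random()
            if u < config.germline_leak_rate:
                v.pop_afs = {"ExAC": float(rng.uniform(0.01, 0.5))}
            elif u < config.germline_leak_rate + 0.10:
                v.pop_afs = {"dbSNP": float(rng.uniform(1e-5, 0.005))}
        variants += vs

        table = simulate_depths(
            genome,
            planted_by_sample.get(sid, {}),
            config.mean_depth,
            seed=int(rng.integers(0, 2**31)),
            sample=sid,
        )
        depth_frames.append(table.depths)

        ki_lo, ki_hi, mit_lo, mit_hi = _GRADE_BOXES[grade]
        hazard = config.hazards[gi]
        t = float(rng.exponential(1.0 / hazard))
        event, time = (1, t) if t <= config.censor_horizon else (0, config.censor_horizon)
        clin_rows.append(
            {
                "sample": sid,
                "grade": grade,
                "n_stage": "N0" if rng.random() < config.p_n0 else "N+",
                "ki67": round(float(rng.uniform(ki_lo, ki_hi)), 2),
                "mitoses": round(float(rng.uniform(mit_lo, mit_hi)), 1),
                "pfs_months": round(max(time, 0.1), 2),
                "event": event,
            }
        )

    depths = ExonDepthTable(pd.concat(depth_frames, ignore_index=True))
    clinical = pd.DataFrame(clin_rows)
    truth = {
        "mixtures": config.grade_mixtures,
        "planted_cnvs": [[s, g, cn] for s, g, cn in planted],
        "hazards": dict(zip(grades, config.hazards)),
        "grade_mean_snvs": dict(zip(grades, config.grade_mean_snvs)),
    }
    return CohortBundle(variants=variants, depths=depths, clinical=clinical, truth=truth)


def write_cohort(
    bundle: CohortBundle, genome: SyntheticGenome, outdir: str | Path
) -> dict[str, str]:
    """Write the cohort to disk (FASTA, BED, per-sample VCFs, TSVs, truth JSON)."""
    from .variants import write_variant_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome.write_fasta(out / "genome.fa")
    genome.write_bed(out / "exons.bed")
    write_variant_tsv(bundle.variants, out / "variants.tsv")
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    by_sample: dict[str, list[Variant]] = {}
    for v in bundle.variants:
        by_sample.setdefault(v.sample, []).append(v)
    for sid, vs in sorted(by_sample.items()):
        write_vcf(sorted(vs, key=lambda v: (v.chrom, v.pos)), vcf_dir / f"{sid}.vcf")
    bundle.depths.to_tsv(out / "depths.tsv")
    bundle.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(bundle.truth, indent=2, sort_keys=True))
    return {
        "genome": str(out / "genome.fa"),
        "exons": str(out / "exons.bed"),
        "variants": str(out / "variants.tsv"),
        "depths": str(out / "depths.tsv"),
        "clinical": str(out / "clinical.tsv"),
        "truth": str(out / "truth.json"),
    }
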