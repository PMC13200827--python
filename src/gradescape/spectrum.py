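"""SNV substitution classes, the 96-channel trinucleotide spectrum, TiTv and
hypermutation scans.

Substitutions are recorded pyrimidine-centric: a change observed at a purine
reference base (A or G) is reverse-complemented, flanks included, before
classification, giving the six classes C>A, C>G, C>T, T>A, T>C, T>G.  The 96
channels refine each class by the 5' and 3' flanking bases of the (possibly
strand-flipped) context, in the conventional ordering used by published
signature matrices: classes in the order above, then the 5' base, then the 3'
base, each cycling through A, C, G, T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlleleError, ContextError, CoordinateError
from .variants import Variant

SNV_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITIONS: frozenset[str] = frozenset({"C>T", "T>C"})

EFFECT_CLASSES: tuple[str, ...] = (
    "frameshift deletion",
    "frameshift insertion",
    "nonframeshift deletion",
    "nonframeshift insertion",
    "synonymous SNV",
    "nonsynonymous SNV",
    "stopgain",
    "stoploss",
    "splicing",
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def snv_class(ref: str, alt: str) -> str:
    """Pyrimidine-centric substitution class of a single-base change."""
    if ref not in _COMP or alt not in _COMP:
        raise AlleleError(f"alleles must be single A/C/G/T bases, got {ref!r}>{alt!r}")
    if ref == alt:
        raise AlleleError(f"ref and alt are both {ref!r}")
    if ref in "AG":
        ref, alt = _COMP[ref], _COMP[alt]
    return f"{ref}>{alt}"


def _channel_index(cls: str, five: str, three: str) -> int:
    return SNV_CLASSES.index(cls) * 16 + _BASES.index(five) * 4 + _BASES.index(three)


#: Channel labels "A[C>A]A" ... "T[T>G]T" in canonical order.
CHANNEL_LABELS: tuple[str, ...] = tuple(
    f"{five}[{cls}]{three}"
    for cls in SNV_CLASSES
    for five in _BASES
    for three in _BASES
)

#: The 32 pyrimidine-centric trinucleotide contexts, in channel order within a class.
PYRIMIDINE_CONTEXTS: tuple[str, ...] = tuple(
    f"{five}{mid}{three}" for mid in "CT" for five in _BASES for three in _BASES
)


def context_channel(trinucleotide: str, ref: str, alt: str) -> int:
    """Channel index (0-95) of a substitution in its trinucleotide context.

    The middle base of ``trinucleotide`` must equal ``ref``.  Purine-reference
    contexts are reverse-complemented, which swaps the flanks.
    """
    tri = trinucleotide.upper()
    if len(tri) != 3 or set(tri) - set(_BASES):
        raise ContextError(f"need a 3-mer of A/C/G/T, got {trinucleotide!r}")
    if tri[1] != ref:
        raise ContextError(f"context {tri} middle base != ref {ref!r}")
    cls = snv_class(ref, alt)
    if ref in "AG":
        tri = revcomp(tri)
    return _channel_index(cls, tri[0], tri[2])


@dataclass
class Spectrum96:
    """Counts over the 96 substitution channels.

    ``skipped_edge`` counts SNVs at chromosome ends whose flanking base does
    not exist; conservation holds as ``counts.sum() + skipped_edge == number
    of input SNVs``.
    """

    counts: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.int64))
    skipped_edge: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("channel counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def collapse6(self) -> dict[str, int]:
        """Collapse over flanking context to the six substitution classes."""
        return {
            cls: int(self.counts[i * 16 : (i + 1) * 16].sum())
            for i, cls in enumerate(SNV_CLASSES)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": CHANNEL_LABELS, "count": self.counts})


def _fetch(genome: Mapping[str, object], chrom: str, start0: int, end0: int) -> str:
    """Slice [start0, end0) from a chrom sequence (dict of str or pyfaidx.Fasta)."""
    if chrom not in genome:
        raise CoordinateError(f"chromosome {chrom!r} not in genome")
    seq = genome[chrom][start0:end0]
    return str(seq).upper()


def build_spectrum(variants: Iterable[Variant], genome: Mapping[str, object]) -> Spectrum96:
    """Count SNVs into the 96 channels using reference-genome context.

    Non-SNVs are ignored.  SNVs at a chromosome edge (no 5' or 3' flank) are
    skipped and tallied in ``skipped_edge``.  A locus outside the genome, or a
    reference allele that disagrees with the genome, is an error.
    """
    counts = np.zeros(96, dtype=np.int64)
    skipped = 0
    for v in variants:
        if not v.is_snv:
            continue
        if chrom_len := _chrom_length(genome, v.chrom):
            if v.pos > chrom_len:
                raise CoordinateError(f"{v.chrom}:{v.pos} beyond chromosome end ({chrom_len})")
        if v.pos == 1 or (chrom_len and v.pos == chrom_len):
            skipped += 1
            continue
        tri = _fetch(genome, v.chrom, v.pos - 2, v.pos + 1)
        if len(tri) < 3:
            skipped += 1
            continue
        counts[context_channel(tri, v.ref, v.alt)] += 1
    return Spectrum96(counts=counts, skipped_edge=skipped)


def _chrom_length(genome: Mapping[str, object], chrom: str) -> int:
    if chrom not in genome:
        raise CoordinateError(f"chromosome {chrom!r} not in genome")
    return len(genome[chrom])


def titv(variants: Iterable[Variant]) -> tuple[int, int, float]:
    """Transition / transversion counts and their ratio.

    Transitions are the C>T and T>C classes (equivalently C:G>T:A and T:A>C:G);
    the other four classes are transversions.  With zero transversions the
    ratio is reported as ``math.inf``.
    """
    ti = tv = 0
    for v in variants:
        if not v.is_snv:
            continue
        if snv_class(v.ref, v.alt) in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if ti + tv == 0:
        raise ValueError("no SNVs: TiTv undefined")
    return ti, tv, (ti / tv if tv else math.inf)


def effect_tally(variants: Iterable[Variant]) -> dict[str, int]:
    """Tally variants over the nine canonical effect classes.

    Unrecognized effect strings are pooled under ``"other"`` with a warning;
    all nine canonical keys are always present.
    """
    import warnings

    tally = {cls: 0 for cls in EFFECT_CLASSES}
    tally["other"] = 0
    unknown: set[str] = set()
    for v in variants:
        if v.effect is None:
            continue
        if v.effect in tally:
            tally[v.effect] += 1
        else:
            tally["other"] += 1
            unknown.add(v.effect)
    if unknown:
        warnings.warn(f"unrecognized effect classes pooled as 'other': {sorted(unknown)}")
    return tally


@dataclass(frozen=True)
class RegionDensity:
    """Mutation count and per-Mb density of one tiling window (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    count: int
    per_mb: float


def hypermutation_scan(
    variants: Sequence[Variant],
    genome: Mapping[str, object],
    window: int = 1_000_000,
) -> list[RegionDensity]:
    """Rank fixed tiling windows by mutation density to localize hypermutation.

    Chromosomes are tiled with non-overlapping windows of ``window`` bp (the
    final window is clamped to the chromosome end; a window longer than the
    chromosome degenerates to one whole-chromosome window).  Output is sorted
    by density descending, ties by (chrom, start).
    """
    if window < 1000:
        raise ValueError(f"window must be >= 1000 bp, got {window}")
    counts: dict[tuple[str, int], int] = {}
    for v in variants:
        _chrom = v.chrom
        length = _chrom_length(genome, _chrom)
        if v.pos > length:
            raise CoordinateError(f"{_chrom}:{v.pos} beyond chromosome end ({length})")
        counts[(_chrom, (v.pos - 1) // window)] = counts.get((_chrom, (v.pos - 1) // window), 0) + 1
    out = []
    for chrom in genome:
        length = _chrom_length(genome, chrom)
        for w in range((length + window - 1) // window):
            start = w * window + 1
            end = min((w + 1) * window, length)
            n = counts.get((chrom, w), 0)
            out.append(
                RegionDensity(chrom, start, end, n, n / ((end - start + 1) / 1e6))
            )
    out.sort(key=lambda r: (-r.per_mb, r.chrom, r.start))
    return out


def chromosome_totals(variants: Iterable[Variant]) -> pd.Series:
    """Raw mutation counts per chromosome (descending)."""
    ser = pd.Series([v.chrom for v in variants], dtype="object")
    if ser.empty:
        return pd.Series(dtype="int64")
    return ser.value_counts()
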