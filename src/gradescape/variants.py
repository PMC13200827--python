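"""Variant containers, VCF/TSV round-trip I/O, germline AF filtering and VAF summaries.

In a tumor-only design no matched normal is available, so candidate somatic
calls are depleted of germline polymorphisms by removing any variant whose
allele frequency in a population database (dbSNP, ExAC, Exome Variant Server,
1000 Genomes, ...) reaches a threshold, conventionally 1%.  Variants absent
from every database are retained: absence of evidence of commonness is not
evidence of a germline origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GradescapeError

_BASES = frozenset("ACGT")

#: Canonical population database labels used by the default VCF INFO mapping.
DEFAULT_AF_KEYS: dict[str, str] = {
    "dbSNP": "AF_DBSNP",
    "ExAC": "AF_EXAC",
    "EVS": "AF_EVS",
    "1000G": "AF_1KG",
}


@dataclass
class Variant:
    """One somatic call for one sample.

    Coordinates are 1-based as in VCF.  ``pop_afs`` maps a population
    database name to the allele frequency recorded there; an empty map means
    the variant was found in no database.
    """

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    effect: str | None = None
    vaf: float | None = None
    pop_afs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - _BASES:
                raise ValueError(f"allele {allele!r} is not a non-empty A/C/G/T string")
        if len(self.ref) == len(self.alt):
            if len(self.ref) != 1:
                raise ValueError(
                    f"equal-length multi-base substitution {self.ref}>{self.alt} unsupported"
                )
            if self.ref == self.alt:
                raise ValueError("ref and alt are identical")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")

    @property
    def vtype(self) -> str:
        """``SNV``, ``insertion`` or ``deletion``."""
        if len(self.ref) == len(self.alt):
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class InfoKeyConfig:
    """Names of the VCF INFO keys carrying annotations.

    ``pop_afs`` maps the database label used internally to the INFO key
    holding that database's allele frequency.
    """

    gene: str = "GENE"
    effect: str = "EFFECT"
    vaf: str = "VAF"
    pop_afs: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_AF_KEYS))


@dataclass(frozen=True)
class VafSummary:
    """Median and percentile band of VAFs for one (group, variant-type) cell.

    All values are percentages.
    """

    group: str
    vtype: str
    median: float
    lower: float
    upper: float
    n: int


class VcfParseError(GradescapeError, ValueError):
    pass


def read_vcf(path: str | Path, sample: str, keys: InfoKeyConfig | None = None) -> list[Variant]:
    """Read a VCF v4.2 file into a variant list for one sample.

    Multi-allelic records are split into one :class:`Variant` per ALT allele;
    shared INFO annotations are duplicated onto each allele.  INFO keys not
    named in ``keys`` are ignored.
    """
    from cyvcf2 import VCF

    keys = keys or InfoKeyConfig()
    out: list[Variant] = []
    reader = VCF(str(path))
    try:
        for i, rec in enumerate(reader, start=1):
            info = dict(rec.INFO)
            gene = info.get(keys.gene)
            effect = info.get(keys.effect)
            vaf = info.get(keys.vaf)
            afs = {
                db: float(info[key]) for db, key in keys.pop_afs.items() if key in info
            }
            for alt in rec.ALT:
                try:
                    out.append(
                        Variant(
                            sample=sample,
                            chrom=rec.CHROM,
                            pos=rec.POS,
                            ref=rec.REF,
                            alt=alt,
                            gene=str(gene) if gene is not None else None,
                            effect=str(effect) if effect is not None else None,
                            vaf=float(vaf) if vaf is not None else None,
                            pop_afs=dict(afs),
                        )
                    )
                except ValueError as exc:
                    raise VcfParseError(f"record {i} ({rec.CHROM}:{rec.POS}): {exc}") from exc
    finally:
        reader.close()
    return out


def write_vcf(variants: Sequence[Variant], path: str | Path, keys: InfoKeyConfig | None = None) -> None:
    """Write variants as a minimal VCF v4.2 file readable by :func:`read_vcf`."""
    keys = keys or InfoKeyConfig()
    lines = ["##fileformat=VCFv4.2"]
    lines.append(f'##INFO=<ID={keys.gene},Number=1,Type=String,Description="Gene symbol">')
    lines.append(f'##INFO=<ID={keys.effect},Number=1,Type=String,Description="Effect class">')
    lines.append(f'##INFO=<ID={keys.vaf},Number=1,Type=Float,Description="Variant allele frequency">')
    for db, key in keys.pop_afs.items():
        lines.append(f'##INFO=<ID={key},Number=1,Type=Float,Description="{db} allele frequency">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in variants:
        info = []
        if v.gene is not None:
            info.append(f"{keys.gene}={v.gene}")
        if v.effect is not None:
            info.append(f"{keys.effect}={v.effect.replace(' ', '_')}")
        if v.vaf is not None:
            info.append(f"{keys.vaf}={v.vaf:.6g}")
        for db, key in keys.pop_afs.items():
            if db in v.pop_afs:
                info.append(f"{key}={v.pop_afs[db]:.6g}")
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{';'.join(info) or '.'}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# Effects are written to VCF with underscores (INFO values cannot hold spaces);
# TSV keeps the spaced form used throughout the package.
def _unescape_effect(effect: str | None) -> str | None:
    return effect.replace("_", " ") if effect is not None else None


def variants_to_frame(variants: Iterable[Variant]) -> pd.DataFrame:
    """Tabulate variants, one row each, AFs in ``af_<db>`` columns."""
    rows = []
    for v in variants:
        row: dict[str, object] = {
            "sample": v.sample,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "vtype": v.vtype,
            "gene": v.gene,
            "effect": v.effect,
            "vaf": v.vaf,
        }
        for db, af in v.pop_afs.items():
            row[f"af_{db}"] = af
        rows.append(row)
    base_cols = ["sample", "chrom", "pos", "ref", "alt", "vtype", "gene", "effect", "vaf"]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=base_cols)
    af_cols = sorted(c for c in df.columns if c.startswith("af_"))
    return df[base_cols + af_cols]


def frame_to_variants(df: pd.DataFrame) -> list[Variant]:
    af_cols = [c for c in df.columns if c.startswith("af_")]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        afs = {
            c[3:]: float(d[c]) for c in af_cols if pd.notna(d[c])
        }
        out.append(
            Variant(
                sample=str(d["sample"]),
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref=str(d["ref"]),
                alt=str(d["alt"]),
                gene=None if pd.isna(d.get("gene")) else str(d["gene"]),
                effect=None if pd.isna(d.get("effect")) else str(d["effect"]),
                vaf=None if pd.isna(d.get("vaf")) else float(d["vaf"]),
                pop_afs=afs,
            )
        )
    return out


def write_variant_tsv(variants: Iterable[Variant], path: str | Path) -> None:
    # %.17g keeps float fields exact across a write/read cycle
    variants_to_frame(variants).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_variant_tsv(path: str | Path) -> list[Variant]:
    return frame_to_variants(pd.read_csv(path, sep="\t", float_precision="round_trip"))


def population_filter(
    variants: Sequence[Variant], threshold: float = 0.01
) -> tuple[list[Variant], list[Variant]]:
    """Partition variants into (kept, removed) by the population-AF rule.

    A variant is removed iff **any** recorded population allele frequency is
    ``>= threshold``; variants with no recorded AF are kept.  Input order is
    preserved in both outputs, so ``kept + removed`` is a permutation of the
    input and re-filtering ``kept`` removes nothing (idempotence).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept, removed = [], []
    for v in variants:
        (removed if any(af >= threshold for af in v.pop_afs.values()) else kept).append(v)
    return kept, removed


def vaf_summary(
    variants: Sequence[Variant],
    groups: Mapping[str, str],
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> list[VafSummary]:
    """Summarize VAF distributions per (group, variant type), in percent.

    ``groups`` maps sample id to a group label (e.g. tumor grade).  The
    median is the standard midpoint median and the band bounds are linearly
    interpolated percentiles.  A (group, vtype) cell with no VAF-bearing
    variant is omitted with a warning.
    """
    lo_q, hi_q = percentiles
    if not 0.0 <= lo_q <= hi_q <= 100.0:
        raise ValueError("percentiles must satisfy 0 <= lower <= upper <= 100")
    cells: dict[tuple[str, str], list[float]] = {}
    missing: set[tuple[str, str]] = set()
    for v in variants:
        group = groups.get(v.sample)
        if group is None:
            continue
        key = (group, v.vtype)
        if v.vaf is None:
            missing.add(key)
            continue
        cells.setdefault(key, []).append(v.vaf)
    for key in sorted(missing - set(cells)):
        warnings.warn(f"no VAFs recorded for group={key[0]} vtype={key[1]}; cell omitted")
    out = []
    for (group, vtype), vafs in sorted(cells.items()):
        arr = np.asarray(vafs) * 100.0
        out.append(
            VafSummary(
                group=group,
                vtype=vtype,
                median=float(np.median(arr)),
                lower=float(np.percentile(arr, lo_q)),
                upper=float(np.percentile(arr, hi_q)),
                n=len(vafs),
            )
        )
    return out
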