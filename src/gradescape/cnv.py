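"""Gene-level copy-number calls from normalized exon read depth.

Each exon's mean depth is converted to a copy-number estimate against a
diploid baseline, ``CN = 2 · depth / sample_mean_depth``.  A gene is called a
gain only if *every* exon has CN > 2.8, a loss only if every exon has
CN < 1.2 (strict inequalities), and only genes with more than two exons are
evaluated — requiring all exons of a multi-exon gene to agree suppresses
single-exon depth noise.  No GC or mappability correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GAIN_THRESHOLD = 2.8
LOSS_THRESHOLD = 1.2
MIN_EXONS = 3

DEPTH_COLUMNS = ("sample", "gene", "exon", "depth")


@dataclass
class ExonDepthTable:
    """Per-sample, per-gene ordered exon mean depths.

    ``depths`` has columns (sample, gene, exon, depth) with ``exon`` the
    0-based exon index within its gene.  ``sample_means`` records each
    sample's mean depth over all its exons; if not supplied it is computed
    empirically.
    """

    depths: pd.DataFrame
    sample_means: dict[str, float] | None = None

    def __post_init__(self) -> None:
        missing = set(DEPTH_COLUMNS) - set(self.depths.columns)
        if missing:
            raise ValueError(f"depth table missing columns {sorted(missing)}")
        if (self.depths["depth"] < 0).any():
            raise ValueError("exon depths must be non-negative")
        if self.sample_means is None:
            self.sample_means = (
                self.depths.groupby("sample")["depth"].mean().astype(float).to_dict()
            )
        for s, m in self.sample_means.items():
            if m <= 0:
                raise ValueError(f"sample {s!r} has non-positive mean depth {m}")

    def samples(self) -> list[str]:
        return sorted(self.depths["sample"].unique())

    def to_tsv(self, path) -> None:
        self.depths.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ExonDepthTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class CnvCall:
    sample: str
    gene: str
    status: str  # gain | loss | neutral | not_evaluable
    copy_numbers: tuple[float, ...]


def exon_copy_number(depths: Sequence[float], sample_mean_depth: float) -> np.ndarray:
    """Copy-number estimates ``2 · depth_i / sample_mean_depth`` per exon."""
    if sample_mean_depth <= 0:
        raise ValueError(f"sample mean depth must be positive, got {sample_mean_depth}")
    arr = np.asarray(depths, dtype=float)
    if (arr < 0).any():
        raise ValueError("exon depths must be non-negative")
    return 2.0 * arr / sample_mean_depth


def call_gene_cnv(
    table: ExonDepthTable,
    gain: float = GAIN_THRESHOLD,
    loss: float = LOSS_THRESHOLD,
    min_exons: int = MIN_EXONS,
    mean_scope: str = "sample",
) -> list[CnvCall]:
    """Call gain/loss/neutral per (sample, gene) from exon copy numbers.

    Genes with fewer than ``min_exons`` exons are ``not_evaluable``.  A gain
    requires every exon CN strictly above ``gain``; a loss requires every
    exon CN strictly below ``loss``.  ``mean_scope`` selects whether depths
    are normalized by the per-sample mean (default) or the cohort-wide mean.
    """
    if mean_scope not in ("sample", "cohort"):
        raise ValueError(f"mean_scope must be 'sample' or 'cohort', got {mean_scope!r}")
    cohort_mean = float(table.depths["depth"].mean()) if mean_scope == "cohort" else None
    calls: list[CnvCall] = []
    for (sample, gene), sub in table.depths.groupby(["sample", "gene"], sort=True):
        mean = cohort_mean if cohort_mean is not None else table.sample_means[sample]
        cn = exon_copy_number(sub.sort_values("exon")["depth"].to_numpy(), mean)
        if len(cn) < min_exons:
            status = "not_evaluable"
        elif np.all(cn > gain):
            status = "gain"
        elif np.all(cn < loss):
            status = "loss"
        else:
            status = "neutral"
        calls.append(CnvCall(str(sample), str(gene), status, tuple(float(c) for c in cn)))
    return calls


def calls_to_frame(calls: Sequence[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "gene": [c.gene for c in calls],
            "status": [c.status for c in calls],
            "copy_numbers": [",".join(f"{x:.4g}" for x in c.copy_numbers) for c in calls],
        }
    )


@dataclass
class GradeOverlap:
    """Per-group gene sets for one CNV direction and their pairwise overlaps."""

    direction: str
    per_group: dict[str, set[str]]
    shared: dict[tuple[str, str], set[str]]
    specific: dict[tuple[str, str], set[str]]  # (a, b) -> genes in a but not b

    def counts(self) -> pd.DataFrame:
        rows = []
        for (a, b), genes in sorted(self.shared.items()):
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "a_total": len(self.per_group[a]),
                    "b_total": len(self.per_group[b]),
                    "shared": len(genes),
                    "a_specific": len(self.specific[(a, b)]),
                    "b_specific": len(self.specific[(b, a)]),
                }
            )
        return pd.DataFrame(rows)


def grade_cnv_overlap(
    calls_by_group: Mapping[str, Sequence[CnvCall]],
    direction: str,
    min_samples: int = 1,
) -> GradeOverlap:
    """Cross-group overlap of genes carrying a gain (or loss) call.

    A gene belongs to a group's set iff it is called with ``direction`` in at
    least ``min_samples`` samples of the group.  For every group pair the
    intersection (shared) and both set differences (specific) are reported.
    """
    if direction not in ("gain", "loss"):
        raise ValueError(f"direction must be 'gain' or 'loss', got {direction!r}")
    if len(calls_by_group) < 2:
        raise ValueError("need at least two groups to compare")
    per_group: dict[str, set[str]] = {}
    for group, calls in calls_by_group.items():
        hits: dict[str, set[str]] = {}
        for c in calls:
            if c.status == direction:
                hits.setdefault(c.gene, set()).add(c.sample)
        per_group[group] = {g for g, samples in hits.items() if len(samples) >= min_samples}
    shared: dict[tuple[str, str], set[str]] = {}
    specific: dict[tuple[str, str], set[str]] = {}
    for a, b in combinations(sorted(per_group), 2):
        shared[(a, b)] = per_group[a] & per_group[b]
        specific[(a, b)] = per_group[a] - per_group[b]
        specific[(b, a)] = per_group[b] - per_group[a]
    return GradeOverlap(direction, per_group, shared, specific)
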