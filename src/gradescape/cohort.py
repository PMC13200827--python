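"""Sample-by-gene incidence matrices and grade/stage-stratified gene-set logic.

The cohort view of a mutation study is a binary incidence matrix (did sample
``i`` carry at least one qualifying variant of gene ``j``) annotated with
clinical grade and nodal-stage labels.  On top of it sit per-gene mutation
frequencies, "present in one grade and absent in the other" comparisons, and
an export ordered for oncoprint-style display.  Significance modelling of
mutation frequencies (MutSigCV-style background models) is out of scope: the
frequency table is the deliverable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import GradescapeError
from .variants import Variant

GRADES = ("G1", "G2", "G3")
#: Nodal stage labels; N+ pools N1 and N2.
N_STAGES = ("N0", "N+")

CLINICAL_COLUMNS = ("sample", "grade", "n_stage", "ki67", "mitoses", "pfs_months", "event")


class CohortConsistencyError(GradescapeError, ValueError):
    pass


@dataclass
class CohortMatrix:
    """Binary sample x gene incidence with clinical labels.

    ``incidence`` is a 0/1 DataFrame (rows: samples, columns: genes);
    ``counts`` holds the raw per-cell variant counts; ``cell_variants`` keeps
    the variant objects behind each nonzero cell; ``dropped_no_gene`` counts
    variants excluded for lacking a gene annotation.
    """

    incidence: pd.DataFrame
    counts: pd.DataFrame
    clinical: pd.DataFrame
    cell_variants: dict[tuple[str, str], list[Variant]] = field(default_factory=dict)
    dropped_no_gene: int = 0

    @property
    def samples(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def genes(self) -> list[str]:
        return list(self.incidence.columns)

    def grade_of(self) -> pd.Series:
        return self.clinical.set_index("sample").loc[self.samples, "grade"]

    def burden(self) -> pd.Series:
        """Per-sample total qualifying variant count."""
        return self.counts.sum(axis=1)

    def samples_in_grade(self, grade: str) -> list[str]:
        g = self.grade_of()
        return [s for s in self.samples if g[s] == grade]

    def mask_genes(self, genes: Iterable[str]) -> "CohortMatrix":
        """Restrict to a user-supplied gene universe (e.g. a cancer-gene list)."""
        keep = [g for g in self.genes if g in set(genes)]
        return CohortMatrix(
            incidence=self.incidence[keep],
            counts=self.counts[keep],
            clinical=self.clinical,
            cell_variants={k: v for k, v in self.cell_variants.items() if k[1] in set(keep)},
            dropped_no_gene=self.dropped_no_gene,
        )


def incidence_matrix(variants: Sequence[Variant], clinical: pd.DataFrame) -> CohortMatrix:
    """Build the cohort matrix from variants and a clinical table.

    Every variant's sample must appear in the clinical table; variants with
    no gene annotation are dropped and tallied.  Samples with no variants
    keep all-zero rows (they still enter frequency denominators).
    """
    if "sample" not in clinical.columns or "grade" not in clinical.columns:
        raise ValueError("clinical table needs at least 'sample' and 'grade' columns")
    samples = [str(s) for s in clinical["sample"]]
    known = set(samples)
    cell_variants: dict[tuple[str, str], list[Variant]] = {}
    dropped = 0
    for v in variants:
        if v.sample not in known:
            raise CohortConsistencyError(f"variant sample {v.sample!r} not in clinical table")
        if v.gene is None:
            dropped += 1
            continue
        cell_variants.setdefault((v.sample, v.gene), []).append(v)
    genes = sorted({g for _, g in cell_variants})
    counts = pd.DataFrame(0, index=samples, columns=genes, dtype=int)
    for (s, g), vs in cell_variants.items():
        counts.loc[s, g] = len(vs)
    return CohortMatrix(
        incidence=(counts > 0).astype(int),
        counts=counts,
        clinical=clinical.reset_index(drop=True),
        cell_variants=cell_variants,
        dropped_no_gene=dropped,
    )


def gene_frequency(matrix: CohortMatrix, by_grade: bool = False) -> pd.DataFrame:
    """Per-gene mutation frequency, overall and optionally per grade.

    Frequency is mutated samples / group size.  Sorted by overall frequency
    descending, ties by gene symbol.
    """
    if not matrix.samples:
        raise ValueError("cohort has no samples")
    n = len(matrix.samples)
    mutated = matrix.incidence.sum(axis=0)
    df = pd.DataFrame(
        {
            "gene": mutated.index,
            "n_mutated": mutated.to_numpy(),
            "n_samples": n,
            "frequency": mutated.to_numpy() / n,
        }
    )
    if by_grade:
        grades = matrix.grade_of()
        for grade in sorted(grades.unique()):
            members = [s for s in matrix.samples if grades[s] == grade]
            sub = matrix.incidence.loc[members].sum(axis=0)
            df[f"freq_{grade}"] = (sub / len(members)).to_numpy()
    return df.sort_values(["frequency", "gene"], ascending=[False, True]).reset_index(drop=True)


def _freq_in(matrix: CohortMatrix, samples: Sequence[str]) -> pd.Series:
    return matrix.incidence.loc[list(samples)].mean(axis=0)


def group_specific_genes(
    matrix: CohortMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_freq_b: float = 1.0,
    min_freq_a: float | None = None,
) -> tuple[set[str], set[str], set[str]]:
    """(shared, A-specific, B-specific) gene sets for two disjoint sample groups.

    A gene is B-specific if its frequency in B is at least ``min_freq_b`` and
    exactly 0 in A; symmetrically for A (``min_freq_a`` defaults to
    ``min_freq_b``).  Shared genes have frequency > 0 in both groups.  The
    default threshold of 1.0 targets grade-exclusive genes present in every
    sample of the positive grade.
    """
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if set(a) & set(b):
        raise ValueError("groups must be disjoint")
    if min_freq_a is None:
        min_freq_a = min_freq_b
    fa, fb = _freq_in(matrix, a), _freq_in(matrix, b)
    shared = set(fa.index[(fa > 0) & (fb > 0)])
    a_specific = set(fa.index[(fa >= min_freq_a) & (fb == 0)])
    b_specific = set(fb.index[(fb >= min_freq_b) & (fa == 0)])
    return shared, a_specific, b_specific


def stage_specific_genes(
    matrix: CohortMatrix, grade: str, min_freq: float | None = None
) -> tuple[set[str], set[str], set[str]]:
    """Within one grade, genes mutated only in N0 versus only in N+ samples.

    Returns (shared, N0-specific, N+-specific).  By default specificity is
    presence-based (any frequency > 0 in the positive stage and 0 in the
    other); pass ``min_freq`` to require a minimum prevalence.
    """
    clin = matrix.clinical.set_index("sample")
    if "n_stage" not in clin.columns:
        raise ValueError("clinical table has no 'n_stage' column")
    members = matrix.samples_in_grade(grade)
    stages = clin.loc[members, "n_stage"]
    if stages.isna().any():
        raise ValueError(f"missing N-stage labels for grade {grade} samples")
    n0 = [s for s in members if stages[s] == "N0"]
    nplus = [s for s in members if stages[s] != "N0"]
    threshold = min_freq if min_freq is not None else 1e-12
    return group_specific_genes(matrix, n0, nplus, min_freq_b=threshold)


def oncoprint_export(matrix: CohortMatrix, top_n: int) -> tuple[pd.DataFrame, dict]:
    """Gene x sample 0/1 table ordered for oncoprint-style display.

    Genes are ordered by mutation frequency descending (ties alphabetical);
    samples by grade then descending burden.  Returns the table and a memo
    of the sort keys used.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    freq = gene_frequency(matrix)
    genes = list(freq["gene"].head(top_n))
    grades = matrix.grade_of()
    burden = matrix.burden()
    samples = sorted(matrix.samples, key=lambda s: (grades[s], -burden[s], s))
    table = matrix.incidence.loc[samples, genes].T
    memo = {
        "gene_order": "frequency desc, ties alphabetical",
        "sample_order": "grade asc, burden desc, sample id",
        "top_n": top_n,
    }
    return table, memo


def read_gene_list(path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    for line in open(path):
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.split()[0])
    if not out:
        warnings.warn(f"gene list {path} is empty")
    return out
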