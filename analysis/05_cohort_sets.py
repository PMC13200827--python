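"""Sample-by-gene incidence, mutation frequencies and grade/stage set logic.

Builds the cohort matrix from the filtered variants, ranks genes by
mutation frequency, and lists genes private to one grade or nodal stage.
"""

import json
from pathlib import Path

import pandas as pd

from gradescape.cohort import incidence_matrix, stage_specific_genes
from gradescape.pipeline import RunConfig, run_pipeline
from gradescape.variants import read_variant_tsv

BASE = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    inputs = BASE / "inputs"
    manifest = run_pipeline(
        RunConfig(
            outdir=str(BASE / "cohort"),
            variants=str(inputs / "variants.tsv"),
            clinical=str(inputs / "clinical.tsv"),
            stages=("filter", "cohort"),
        )
    )
    c = manifest["stages"]["cohort"]
    freq = pd.read_csv(BASE / "cohort" / "gene_frequency.tsv", sep="\t")
    print(f"{c['samples']} samples x {c['genes']} genes; top mutated genes:")
    print(freq.head(5).to_string(index=False))

    specific = json.loads((BASE / "cohort" / "grade_specific_genes.json").read_text())
    for row in specific:
        print(f"{row['comparison']}: shared {row['shared']} genes; "
              + "; ".join(f"{k} {len(v)}" for k, v in row.items()
                          if k.endswith("_specific")))

    kept = read_variant_tsv(BASE / "cohort" / "variants_kept.tsv")
    clinical = pd.read_csv(inputs / "clinical.tsv", sep="\t")
    matrix = incidence_matrix(kept, clinical)
    for grade in ("G2", "G3"):
        shared, n0_only, nplus_only = stage_specific_genes(matrix, grade)
        print(f"{grade}: {len(n0_only)} genes only in N0, {len(nplus_only)} only in N+")


if __name__ == "__main__":
    main()
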