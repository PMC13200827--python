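"""Generate the synthetic graded cohort every later step analyzes.

Writes a 24-sample cohort (grades 6/6/12) with known signature mixtures,
planted copy-number events and grade-dependent survival under
results/cohort/inputs/: genome FASTA, exon BED, variant TSV + per-sample
VCFs, exon-depth TSV, clinical TSV and the generative truth JSON.
"""

import json
from pathlib import Path

from gradescape.signatures import toy_signatures
from gradescape.synthetic import CohortConfig, make_reference, simulate_cohort, write_cohort

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort" / "inputs"


def main() -> None:
    genome = make_reference(seed=SEED, n_chroms=2, chrom_length=50_000, n_genes=100)
    sigs = toy_signatures()
    config = CohortConfig(seed=SEED)
    bundle = simulate_cohort(config, genome, sigs)
    paths = write_cohort(bundle, genome, OUT)
    sigs.to_tsv(OUT / "signatures.tsv")

    n_by_grade = bundle.clinical.groupby("grade")["sample"].count().to_dict()
    print(f"cohort: {len(bundle.clinical)} samples {n_by_grade}")
    print(f"variants: {len(bundle.variants)} (burdens rise with grade by construction)")
    print(f"planted CNVs: {len(bundle.truth['planted_cnvs'])} (CN=4 gains and CN=1 losses)")
    print("inputs written to", OUT)
    print(json.dumps(paths, indent=2))


if __name__ == "__main__":
    main()
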