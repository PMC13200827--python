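"""Germline filtering and mutation-spectrum profiling of the synthetic cohort.

Applies the 1% population-AF filter, builds the 6-class and 96-channel
spectra, and reports TiTv by grade and the top hypermutation window.
Requires analysis/01_simulate_cohort.py to have run.
"""

from pathlib import Path

import pandas as pd

from gradescape.pipeline import RunConfig, run_pipeline
from gradescape.spectrum import titv
from gradescape.variants import read_variant_tsv

BASE = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    inputs = BASE / "inputs"
    manifest = run_pipeline(
        RunConfig(
            outdir=str(BASE / "spectrum"),
            variants=str(inputs / "variants.tsv"),
            genome=str(inputs / "genome.fa"),
            clinical=str(inputs / "clinical.tsv"),
            window=10_000,
            stages=("filter", "spectrum"),
        )
    )
    f = manifest["stages"]["filter"]
    print(f"filter: {f['removed']}/{f['input']} variants removed as likely germline (AF >= 1%)")
    s = manifest["stages"]["spectrum"]
    print(f"spectrum: {s['snvs']} SNVs, cohort TiTv = {s['titv']['ratio']:.2f}")

    kept = read_variant_tsv(BASE / "spectrum" / "variants_kept.tsv")
    clinical = pd.read_csv(inputs / "clinical.tsv", sep="\t")
    grade_of = dict(zip(clinical["sample"], clinical["grade"]))
    for grade in ("G1", "G2", "G3"):
        sub = [v for v in kept if grade_of[v.sample] == grade and v.is_snv]
        ti, tv, ratio = titv(sub)
        print(f"  {grade}: TiTv {ratio:.2f} ({ti} transitions / {tv} transversions)")
    top = s["top_region"]
    print(f"densest window: {top['chrom']}:{top['start']}-{top['end']} "
          f"({top['count']} mutations, {top['per_mb']:.0f}/Mb)")


if __name__ == "__main__":
    main()
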