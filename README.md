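# gradescape

Grade-stratified somatic mutation profiling for tumor-only whole-exome
cohorts — the analysis toolchain for small graded tumor series (the
motivating case is a 24-sample G1/G2/G3 neuroendocrine tumor cohort):

- **Germline filtering** — tumor-only calls are depleted of polymorphisms by
  removing any variant with a population allele frequency ≥ 1% in any
  database (dbSNP/ExAC/EVS/1000G-style annotations).
- **Mutation spectra** — six pyrimidine-centric substitution classes and the
  96 trinucleotide channels, TiTv ratios, effect-class tallies, VAF
  summaries and tiling-window hypermutation scans.
- **Signature refitting** — non-negative least-squares exposures over a
  COSMIC-layout reference matrix `s ≈ M_S e`, with the contributing subset
  `S` chosen by greedy forward search under the BIC and reconstruction
  scored by cosine similarity.
- **CNV calling** — gene-level gains/losses from normalized exon depth
  (`CN = 2·depth/mean`), gain iff every exon CN > 2.8, loss iff every exon
  CN < 1.2, genes with ≤ 2 exons not evaluable; cross-grade overlap sets.
- **Cohort matrices** — sample × gene incidence, mutation frequencies by
  grade, grade- and nodal-stage-specific gene sets, oncoprint export.
- **Clinical** — IHC scoring (intensity × positive-area), WHO grading from
  mitoses and Ki-67 with higher-grade discordance resolution, Kaplan-Meier
  curves and the log-rank test.
- **Enrichment** — hypergeometric over-representation against GMT pathway
  collections with Benjamini-Hochberg adjustment, and per-pathway mutation
  coverage.

Because raw data for such cohorts are rarely shareable, the package includes
a first-class synthetic cohort generator (`gradescape.synthetic`) with known
signature mixtures, planted copy-number events, grade-consistent pathology
and grade-dependent survival, so every stage is testable end to end.
See `docs/methods.md` for the models and their assumptions.

## Worked example

One command simulates a default cohort (24 samples, grades 6/6/12) and runs
every stage:

```sh
gradescape demo --seed 7 --out demo_run
```

or, stepwise, the narrative drivers under `analysis/` (each writes its tables
under `results/cohort/`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_filter_and_spectrum.py
python analysis/03_signature_decomposition.py
```

Step 02 prints, for seed 7:

```
filter: 976/9802 variants removed as likely germline (AF >= 1%)
spectrum: 7635 SNVs, cohort TiTv = 1.00
  G1: TiTv 2.03 (181 transitions / 89 transversions)
  G2: TiTv 1.70 (507 transitions / 298 transversions)
  G3: TiTv 0.91 (3127 transitions / 3433 transversions)
```

— the 1% filter strips the planted germline leak-through, and the TiTv ratio
falls monotonically with grade because the generator shifts the signature
mixture from transition-led (G1) to transversion-rich (G3). Step 03 then
recovers those mixtures from the spectra alone:

```
G1: selected ['S3', 'S1', 'S5'] cosine 0.955 exposures {'S3': 150, 'S1': 97, 'S5': 34}  (true mixture {'S1': 0.3, 'S3': 0.5, 'S5': 0.2})
G3: selected ['S1', 'S2', 'S5'] cosine 0.997 exposures {'S1': 3285, 'S2': 1980, 'S5': 1283}  (true mixture {'S1': 0.5, 'S2': 0.3, 'S5': 0.2})
```

with exposures proportional to the generating weights. Step 06 closes the
loop clinically: re-grading every sample from its Ki-67/mitotic counts
reproduces the assigned grade (100% concordance) and survival separates by
grade (log-rank chi² 11.17, df 2, p 0.0038 on this seed).

The same stages run on real inputs via subcommands
(`gradescape filter|spectrum|signatures|cnv|cohort|survival|enrich`), each a
thin wrapper over the library; pass `--sig-matrix` a COSMIC-layout TSV and
`--gmt` your pathway collection.

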