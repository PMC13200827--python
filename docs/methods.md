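# Methods

`gradescape` re-implements, as a tested pipeline over synthetic cohorts, the
analysis stages of a grade-stratified somatic-profiling study of a tumor-only
whole-exome cohort (the motivating setting is a 24-patient colorectal
neuroendocrine tumor series graded G1/G2/G3). The raw patient data behind such
studies are typically not shareable, so the package pairs every analysis stage
with a synthetic-data generator whose ground truth is known, and all
quantitative claims in the test suite are about the method's behavior on that
generator — not about any patient cohort.

## Germline filtering (tumor-only)

Without a matched normal, candidate somatic calls are depleted of germline
polymorphisms by population allele frequency: a variant is removed iff **any**
recorded database AF (dbSNP, ExAC, EVS, 1000G, ...) is `>= 0.01`. Variants
absent from all databases are kept. Choices made here: the combination rule
across databases ("any db over threshold removes") is the conservative
tumor-only convention; the comparison is `>=`; the filter runs before all
downstream stages. The filter is order-preserving and idempotent.

## Mutation spectra

SNVs are classified pyrimidine-centrically: substitutions at purine reference
bases are reverse-complemented (flanks included) into the six classes C>A,
C>G, C>T, T>A, T>C, T>G. The 96-channel spectrum refines each class by the 5'
and 3' flanking reference bases in the conventional signature-matrix order
(class, then 5' base, then 3' base, each cycling A, C, G, T), so published
96-row signature files align row-for-row. Flanks are read from the reference
genome at the variant site. SNVs at a chromosome edge lack a flank; they are
skipped and counted, so `sum(channels) + skipped = n_SNVs` holds exactly.
Transitions are the C>T and T>C classes; TiTv with zero transversions is
reported as infinity rather than an error. Hypermutation is localized with
fixed non-overlapping tiling windows (default 1 Mb; final window clamped to
the chromosome end) ranked by mutations per Mb; raw counts are reported next
to densities because window densities are not depth-normalized.

## Signature refitting with BIC model selection

An observed spectrum `s` (96 counts) is modelled as `s ≈ M_S e` with `M_S`
the column-stochastic reference matrix restricted to a signature subset `S`
and `e >= 0` the exposures (mutations attributed). Exposures are fitted by
non-negative least squares (active-set NNLS via `scipy.optimize.nnls`; the
KKT conditions are property-tested). Subsets are grown greedily: starting
empty, each step adds the signature minimizing the BIC, stopping when no
addition lowers it or `max_k` is reached; ties break by signature id, making
the search deterministic, and the full search trace is returned for audit.
Exhaustive enumeration over 2^K subsets is intentionally avoided.

Two BIC forms are provided:

- **Gaussian (default):** `BIC = n ln(max(RSS, 1e-12)/n) + (k+1) ln n` with
  `n = 96` channels; the `+1` counts the residual variance.
- **Multinomial (`bic_mode="multinomial"`):** each mutation is an observation
  from the reconstructed channel distribution,
  `BIC = -2 ln L + k ln N`, `N` = mutation total. Its magnitude scales with
  the mutation count rather than the channel count (tens of thousands for a
  typical exome cohort), which matches the scale of BIC values printed by
  web refitting tools; neither form claims to replicate any specific tool's
  constant.

Reconstruction quality is the cosine similarity between `s` and `M_S e`.
A bundled synthetic reference of five well-separated signatures (`S1`-`S5`,
each concentrating ~70% of its mass on one substitution class, spread within
class by a fixed Dirichlet draw; pairwise cosines 0.11-0.53) supports tests
and demos; real analyses should load a COSMIC-layout TSV.

Measured behavior on the generator: spectra of 20,000 mutations from a
0.6/0.3/0.1 three-signature mixture recover the exact support in ~95% of
seeds with normalized-exposure L1 error ≤ 0.05 when the support is correct;
exposure error decreases monotonically with mutation count (tested at 10^3,
10^4, 10^5).

## Exon-depth CNV calling

Per-exon copy number is estimated against a diploid baseline,
`CN_i = 2 d_i / m`, where `d_i` is the exon's mean depth and `m` the sample's
mean depth over all exons (a cohort-wide mean is available as an option). A
gene is a **gain** iff *every* exon has `CN > 2.8`, a **loss** iff every exon
has `CN < 1.2` (strict inequalities — CN exactly at a threshold never
triggers a call), and only genes with ≥ 3 exons are evaluable; zero-depth
exons count as evaluable (CN 0 supports loss). Grade-level comparison pools
each grade's gain (or loss) genes over its samples (membership needs ≥ 1
sample by default; `min_samples` generalizes) and reports pairwise
intersections and differences. No GC or mappability correction is applied —
a known limitation.

Under the synthetic depth model (below) at 100× with 3-6 exons per gene,
planted CN=4 gains are recovered with recall ~1.0 and diploid genes are
miscalled at < 0.1%. Planted CN=1 losses, however, are recovered at only
~0.75-0.85: a single-copy loss leaves exon depths ~ Poisson(50), for which
`P(CN < 1.2)` per exon is only ~0.92-0.94, and the every-exon rule compounds
this across 3-6 exons. This is a property of the strict all-exon rule at this
depth and noise level, not an implementation artifact; detecting single-copy
losses reliably at 100× would need either a less extreme threshold, a
per-gene aggregate statistic, or lower-variance depth summaries.

## Cohort matrices and set logic

The cohort view is a binary sample × gene incidence matrix (cell = 1 iff ≥ 1
qualifying variant) with raw counts and per-cell variant references kept
alongside; variants lacking a gene annotation are dropped and tallied.
Per-gene frequency is mutated samples / group size, overall and per grade.
"Grade-specific" genes require full prevalence (frequency ≥ 1.0, i.e. every
sample) in the positive grade and absence in the other — configurable via
`min_freq` — while nodal-stage comparisons (N0 vs N+, pooling N1/N2) default
to presence-based specificity. Mutation-significance modelling (MutSigCV-style
background rates) is out of scope; the frequency table stands in. The
oncoprint export orders genes by frequency (ties alphabetical) and samples by
grade then burden.

## IHC scoring, WHO grading, survival

IHC total score = staining intensity (0-3) × positive-area score (1-4);
total > 0 is positive expression. The positive-area bins are quartiles
(≤25 → 1, ≤50 → 2, ≤75 → 3, else 4); quartiles are a stated package choice
(the underlying convention varies between laboratories) and the bins are a
parameter. WHO grade derives independently from the mitotic count (<2 → G1,
2-20 → G2, >20 → G3 per 10 HPF; boundaries closed into G2) and the Ki-67
index (<3% → G1, 3-20% → G2, >20% → G3) and resolves discordance by the
higher grade, so grading is monotone in both inputs.

Survival uses the Kaplan-Meier product-limit estimator and the log-rank test
(lifelines; ties handled by the hypergeometric variance), df = groups − 1.
The two-group hazard ratio is reported as `(O_1/E_1)/(O_2/E_2)` from the
log-rank observed/expected table — an estimator choice, not a
proportional-hazards fit. Calibration on equal-hazard exponential two-arm
simulations (n = 50/arm) keeps the type-I error within [0.03, 0.07] at
α = 0.05, with power > 0.8 at hazard ratio 3 (n = 100/arm).

## Over-representation analysis

For each pathway in a GMT collection, `p = P(X >= overlap)` under the
hypergeometric null (population = gene universe, successes = pathway,
draws = query ∩ universe), one-sided by design; Benjamini-Hochberg adjustment
across the tested pathways. The default universe is the union of the
collection's genes; a cohort-derived universe is a flag. The p-values are
tested against exhaustive enumeration of all draws for universes ≤ 12 genes.
Pathway mutation coverage reports `|pathway ∩ mutated| / |pathway|` per
pathway.

## The synthetic cohort generator

The generator produces complete, deterministic cohorts from a seed:

- **Genome/exon model** — uniform-random A/C/G/T chromosomes (default 2 × 50
  kb) with a left-to-right exon layout (default 100 genes, 1-6 exons of 120
  bp); sequences are redrawn until all 32 pyrimidine-centric trinucleotide
  contexts occur (essentially certain ≥ 10 kb).
- **SNVs** — channel counts are multinomial with `p = Σ w_k sig_k`; each
  mutation is placed uniformly among genome sites whose pyrimidine-normalized
  trinucleotide matches its channel (no replication-timing or expression
  covariates), with ref/alt complemented at purine-strand sites. The
  empirical spectrum therefore concentrates on `n p` at the √n scale; the
  property test asserts the standard multinomial mean-L1 bound
  `‖counts − np‖₁ < √(96 n)`.
- **Cohort structure** — 6/6/12 samples in G1/G2/G3 with Poisson per-sample
  SNV counts around grade means 50/150/600 (burden rising with grade), indel
  counts at 15% of the SNV mean, and grade signature mixtures
  G1 = {S3 0.5, S1 0.3, S5 0.2}, G2 = {S1 0.4, S3 0.3, S5 0.3},
  G3 = {S1 0.5, S2 0.3, S5 0.2} — chosen so G1 is transition (T>C)-led and
  G3 is C>T-led with more transversions, the qualitative grade shift the
  spectrum stage is meant to resolve.
- **VAFs** — Beta(mκ, (1−m)κ) with κ = 25 and grade medians 12.8/15.3/19.0%
  (SNVs) and 10.2/11.4/10.8% (indels), i.e. modest right-skewed somatic VAF
  distributions shifting up with grade.
- **Germline leak** — 10% of variants carry a common population AF
  (U(0.01, 0.5)) and another 10% a rare one (U(10⁻⁵, 0.005)), so the 1%
  filter removes ~10% and keeps the rest.
- **Depths** — exon depth ~ Poisson(mean_depth · CN/2) at 100×, with three
  CN=4 and three CN=1 genes planted per sample among multi-exon genes.
- **Clinical** — Ki-67 and mitotic counts drawn uniformly inside the assigned
  grade's WHO box (so re-grading reproduces the label for 100% of samples);
  exponential progression times with grade hazards 0.01/0.02/0.04 per month
  and administrative censoring at 60 months; nodal stage N0 with
  probability 0.4.

What the generator does **not** emulate: raw reads and alignment artifacts,
tumor purity and subclonal structure, FFPE deamination damage beyond the
signature mixtures, GC/mappability depth waves, correlated exon noise, and
linkage between mutations and clinical covariates beyond grade. Passing tests
therefore demonstrate correctness of the computations and calibrated behavior
under a clean generative model, not robustness to real-exome artifacts.

## Numerical and engineering choices

- All randomness flows through `numpy.random.default_rng` seeds carried in
  configs; reruns are byte-identical, and the run manifest records every
  threshold and seed (no timestamps).
- NNLS RSS is squared residual norm from the active-set solver; BIC guards
  `RSS = 0` with ε = 1e-12. Degenerate inputs raise typed errors
  (all-zero spectrum, zero vector in cosine, no events in log-rank, empty
  ORA universe).
- Variant TSVs are written with `%.17g` floats and read with round-trip
  float parsing, so write→read is exact on all fields.
- Problem sizes in tests and the acceptance script (e.g. 20k-mutation
  spectra, 50 recovery seeds, 20 CNV cohorts of 1000 genes, 500-2000
  log-rank replicates) are chosen so the whole suite completes in a few
  minutes on one CPU while leaving the measured proportions' Monte-Carlo
  error well inside the asserted margins.

## Known limitations

- The CNV caller's all-exon rule is insensitive to single-copy losses at
  100× (see above) and performs no segmentation or purity/ploidy correction.
- The Gaussian BIC treats channel counts as homoscedastic; the multinomial
  alternative is better-founded for large mutation counts but neither
  reproduces any external tool's exact constant.
- ORA results depend strongly on the chosen universe; both options are
  explicit, and no attempt is made to model inter-gene correlation.
- The hazard ratio is the O/E form, which approximates a Cox estimate only
  under proportional hazards and moderate censoring.
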