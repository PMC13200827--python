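"""End-to-end orchestration of the profiling stages over a shared config.

Stages run in a fixed order — filter, spectrum, signatures, cnv, cohort,
clinical, enrichment — each reading the standard on-disk formats (variant
TSV/VCF, FASTA, BED, depth and clinical TSVs, signature-matrix TSV, GMT) and
writing TSV/JSON outputs plus a machine-readable manifest recording every
threshold and seed.  Reruns with the same config are byte-identical: nothing
time- or host-dependent enters the outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import clinical as clin
from . import cnv as cnvmod
from . import cohort as cohortmod
from . import enrichment as enrich
from . import signatures as sigmod
from . import spectrum as specmod
from .errors import ConfigError
from .synthetic import read_exon_bed
from .variants import (
    population_filter,
    read_variant_tsv,
    vaf_summary,
    variants_to_frame,
    write_variant_tsv,
)

ALL_STAGES = ("filter", "spectrum", "signatures", "cnv", "cohort", "clinical", "enrichment")


@dataclass
class RunConfig:
    """Paths, thresholds and seed for one pipeline run.

    Threshold defaults follow the conventions used throughout the package:
    1% population-AF germline cutoff, CNV gain/loss at copy number 2.8/1.2
    with at least 3 exons, 1 Mb hypermutation windows.
    """

    outdir: str
    variants: str | None = None
    genome: str | None = None
    exons: str | None = None
    depths: str | None = None
    clinical: str | None = None
    signature_matrix: str | None = None  # None -> built-in toy reference
    gmt: str | None = None
    max_af: float = 0.01
    cnv_gain: float = 2.8
    cnv_loss: float = 1.2
    min_exons: int = 3
    window: int = 1_000_000
    max_k: int = 5
    bic_mode: str = "gaussian"
    min_freq_specific: float = 1.0
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        if self.cnv_gain <= self.cnv_loss:
            raise ConfigError("cnv_gain must exceed cnv_loss")
        if not 0 < self.max_af <= 1:
            raise ConfigError("max_af must be in (0, 1]")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")


_REQUIRES = {
    "filter": ("variants",),
    "spectrum": ("variants", "genome"),
    "signatures": ("variants", "genome"),
    "cnv": ("depths",),
    "cohort": ("variants", "clinical"),
    "clinical": ("clinical",),
    "enrichment": ("variants", "clinical", "gmt"),
}


def _load_genome(path: str) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(path)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and return the run manifest.

    A missing input for a requested stage raises :class:`ConfigError` naming
    the field.  The manifest (also written to ``manifest.json``) records the
    parameters, per-stage outputs and headline counts.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for stage in config.stages:
        for fieldname in _REQUIRES[stage]:
            if getattr(config, fieldname) is None:
                raise ConfigError(f"stage {stage!r} requires config field {fieldname!r}")

    manifest: dict = {
        "parameters": {
            "max_af": config.max_af,
            "cnv_gain": config.cnv_gain,
            "cnv_loss": config.cnv_loss,
            "min_exons": config.min_exons,
            "window": config.window,
            "max_k": config.max_k,
            "bic_mode": config.bic_mode,
            "min_freq_specific": config.min_freq_specific,
            "seed": config.seed,
        },
        "stages": {},
    }

    variants = read_variant_tsv(config.variants) if config.variants else []
    clinical_df = pd.read_csv(config.clinical, sep="\t") if config.clinical else None
    genome = _load_genome(config.genome) if config.genome else None
    grade_of = (
        dict(zip(clinical_df["sample"].astype(str), clinical_df["grade"].astype(str)))
        if clinical_df is not None
        else {}
    )

    kept = variants
    if "filter" in config.stages:
        kept, removed = population_filter(variants, config.max_af)
        write_variant_tsv(kept, out / "variants_kept.tsv")
        write_variant_tsv(removed, out / "variants_removed.tsv")
        manifest["stages"]["filter"] = {
            "input": len(variants),
            "kept": len(kept),
            "removed": len(removed),
            "outputs": ["variants_kept.tsv", "variants_removed.tsv"],
        }

    cohort_spectrum = None
    if "spectrum" in config.stages:
        assert genome is not None
        spec = specmod.build_spectrum(kept, genome)
        cohort_spectrum = spec
        spec.to_frame().to_csv(out / "spectrum96.tsv", sep="\t", index=False)
        six = spec.collapse6()
        pd.DataFrame(
            {"class": list(six), "count": list(six.values())}
        ).to_csv(out / "classes6.tsv", sep="\t", index=False)
        ti, tv, ratio = specmod.titv([v for v in kept if v.is_snv])
        tally = specmod.effect_tally(kept)
        regions = specmod.hypermutation_scan(kept, genome, config.window)
        pd.DataFrame([r.__dict__ for r in regions]).to_csv(
            out / "hypermutation.tsv", sep="\t", index=False
        )
        summaries = vaf_summary(kept, grade_of) if grade_of else []
        pd.DataFrame([s.__dict__ for s in summaries]).to_csv(
            out / "vaf_summary.tsv", sep="\t", index=False
        )
        manifest["stages"]["spectrum"] = {
            "snvs": spec.total,
            "skipped_edge": spec.skipped_edge,
            "titv": {"ti": ti, "tv": tv, "ratio": ratio},
            "effects": tally,
            "top_region": regions[0].__dict__ if regions else None,
            "outputs": ["spectrum96.tsv", "classes6.tsv", "hypermutation.tsv", "vaf_summary.tsv"],
        }

    if "signatures" in config.stages:
        sigs = (
            sigmod.ReferenceSignatures.from_tsv(config.signature_matrix)
            if config.signature_matrix
            else sigmod.toy_signatures()
        )
        if cohort_spectrum is None:
            assert genome is not None
            cohort_spectrum = specmod.build_spectrum(kept, genome)
        max_k = min(config.max_k, sigs.k)
        decomp = sigmod.forward_select(cohort_spectrum, sigs, max_k, config.bic_mode)
        report = {"cohort": decomp.to_dict()}
        for grade in sorted(set(grade_of.values())):
            sub = [v for v in kept if grade_of.get(v.sample) == grade]
            gspec = specmod.build_spectrum(sub, genome)
            if gspec.total > 0:
                report[grade] = sigmod.forward_select(gspec, sigs, max_k, config.bic_mode).to_dict()
        (out / "signatures.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest["stages"]["signatures"] = {
            "selected": decomp.selected,
            "cosine": decomp.cosine,
            "bic": decomp.bic,
            "outputs": ["signatures.json"],
        }

    calls = None
    if "cnv" in config.stages:
        table = cnvmod.ExonDepthTable.from_tsv(config.depths)
        calls = cnvmod.call_gene_cnv(
            table, config.cnv_gain, config.cnv_loss, config.min_exons
        )
        cnvmod.calls_to_frame(calls).to_csv(out / "cnv_calls.tsv", sep="\t", index=False)
        overlap_counts = []
        if grade_of:
            by_grade: dict[str, list] = {}
            for c in calls:
                g = grade_of.get(c.sample)
                if g is not None:
                    by_grade.setdefault(g, []).append(c)
            if len(by_grade) >= 2:
                for direction in ("gain", "loss"):
                    ov = cnvmod.grade_cnv_overlap(by_grade, direction)
                    df = ov.counts()
                    df.insert(0, "direction", direction)
                    overlap_counts.append(df)
        if overlap_counts:
            pd.concat(overlap_counts, ignore_index=True).to_csv(
                out / "cnv_overlap.tsv", sep="\t", index=False
            )
        status = pd.Series([c.status for c in calls]).value_counts().to_dict()
        manifest["stages"]["cnv"] = {
            "calls": {k: int(v) for k, v in sorted(status.items())},
            "outputs": ["cnv_calls.tsv"] + (["cnv_overlap.tsv"] if overlap_counts else []),
        }

    matrix = None
    if "cohort" in config.stages:
        assert clinical_df is not None
        matrix = cohortmod.incidence_matrix(kept, clinical_df)
        freq = cohortmod.gene_frequency(matrix, by_grade=True)
        freq.to_csv(out / "gene_frequency.tsv", sep="\t", index=False)
        specific_rows = []
        grades_present = sorted(set(grade_of.values()))
        for a, b in zip(grades_present, grades_present[1:]):
            sa = matrix.samples_in_grade(a)
            sb = matrix.samples_in_grade(b)
            if sa and sb:
                shared, a_spec, b_spec = cohortmod.group_specific_genes(
                    matrix, sa, sb, config.min_freq_specific
                )
                specific_rows.append(
                    {
                        "comparison": f"{a}_vs_{b}",
                        "shared": len(shared),
                        f"{a}_specific": sorted(a_spec),
                        f"{b}_specific": sorted(b_spec),
                    }
                )
        (out / "grade_specific_genes.json").write_text(
            json.dumps(specific_rows, indent=2, sort_keys=True)
        )
        export, memo = cohortmod.oncoprint_export(matrix, top_n=min(25, len(matrix.genes)) or 1)
        export.to_csv(out / "oncoprint.tsv", sep="\t")
        manifest["stages"]["cohort"] = {
            "samples": len(matrix.samples),
            "genes": len(matrix.genes),
            "dropped_no_gene": matrix.dropped_no_gene,
            "top_gene": freq.iloc[0]["gene"] if not freq.empty else None,
            "oncoprint_memo": memo,
            "outputs": ["gene_frequency.tsv", "grade_specific_genes.json", "oncoprint.tsv"],
        }

    if "clinical" in config.stages:
        assert clinical_df is not None
        df = clinical_df
        concordant = None
        if {"ki67", "mitoses"} <= set(df.columns):
            assigned = [clin.who_grade(m, k) for m, k in zip(df["mitoses"], df["ki67"])]
            concordant = float((pd.Series(assigned).to_numpy() == df["grade"].to_numpy()).mean())
        records = [
            clin.SurvivalRecord(time=float(r.pfs_months), event=int(r.event), group=str(r.grade))
            for r in df.itertuples(index=False)
        ]
        km_frames = []
        for grade in sorted({r.group for r in records}):
            sub = [r for r in records if r.group == grade]
            km = clin.km_estimate(sub)
            km.insert(0, "group", grade)
            km_frames.append(km)
        pd.concat(km_frames, ignore_index=True).to_csv(out / "km.tsv", sep="\t", index=False)
        chi2, dof, p = clin.logrank_test(records)
        (out / "survival.json").write_text(
            json.dumps(
                {"chi_square": chi2, "df": dof, "p": p, "who_grade_concordance": concordant},
                indent=2,
                sort_keys=True,
            )
        )
        manifest["stages"]["clinical"] = {
            "logrank_p": p,
            "who_grade_concordance": concordant,
            "outputs": ["km.tsv", "survival.json"],
        }

    if "enrichment" in config.stages:
        db = enrich.PathwayDB.from_gmt(config.gmt)
        if matrix is None:
            assert clinical_df is not None
            matrix = cohortmod.incidence_matrix(kept, clinical_df)
        mutated = {g for g in matrix.genes if matrix.incidence[g].sum() > 0}
        ora = enrich.hypergeom_ora(mutated, db)
        ora.to_csv(out / "ora.tsv", sep="\t", index=False)
        cov = enrich.pathway_mutation_coverage(mutated, db)
        cov.to_csv(out / "pathway_coverage.tsv", sep="\t", index=False)
        manifest["stages"]["enrichment"] = {
            "pathways": len(db.pathways),
            "query": len(mutated),
            "top_pathway": ora.iloc[0]["pathway"] if not ora.empty else None,
            "outputs": ["ora.tsv", "pathway_coverage.tsv"],
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_synthetic_demo(seed: int, outdir: str | Path, **config_overrides) -> dict:
    """Generate a default synthetic cohort and run the full pipeline on it.

    Returns the pipeline manifest; all inputs and outputs land under
    ``outdir`` (``inputs/`` and ``results/``).
    """
    from .signatures import toy_signatures
    from .synthetic import CohortConfig, make_reference, simulate_cohort, write_cohort
    from .enrichment import write_gmt

    outdir = Path(outdir)
    genome = make_reference(seed=seed, n_chroms=2, chrom_length=50_000, n_genes=100)
    sigs = toy_signatures()
    bundle = simulate_cohort(CohortConfig(seed=seed), genome, sigs)
    paths = write_cohort(bundle, genome, outdir / "inputs")
    sigs.to_tsv(outdir / "inputs" / "signatures.tsv")
    # demo pathway collection over the synthetic gene universe
    genes = genome.genes()
    pathways = {f"PW{i + 1:02d}": set(genes[i * 10 : (i + 1) * 10]) for i in range(10)}
    write_gmt(pathways, outdir / "inputs" / "pathways.gmt")
    config = RunConfig(
        outdir=str(outdir / "results"),
        variants=paths["variants"],
        genome=paths["genome"],
        exons=paths["exons"],
        depths=paths["depths"],
        clinical=paths["clinical"],
        signature_matrix=str(outdir / "inputs" / "signatures.tsv"),
        gmt=str(outdir / "inputs" / "pathways.gmt"),
        seed=seed,
        **config_overrides,
    )
    return run_pipeline(config)
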