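"""End-to-end orchestration: variants → statistics → window scan → linkage
fine-mapping → candidate genes, with a reproducible manifest.

Two entry points:

* :func:`run_full_pipeline` — file-based: reads VCF/GFF3/FASTA/TSV paths
  from a :class:`PipelineConfig`, writes every intermediate table to the
  output directory plus a JSON manifest (parameters, seeds, input
  checksums, per-stage row counts).  Rerunning with the same config and
  seed reproduces byte-identical TSVs.
* :func:`analyze_study` — in-memory: the same analysis chain on objects,
  used by simulation studies that do not need to round-trip through disk.

All randomness (null band, permutations) derives from the single master
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from bsaqtl import genes as genes_mod
from bsaqtl import linkage as linkage_mod
from bsaqtl import sim as sim_mod
from bsaqtl import stats as stats_mod
from bsaqtl import variants as variants_mod
from bsaqtl import windows as windows_mod
from bsaqtl._util import require

DEPTH_GRID = tuple(range(10, 201, 10))


@dataclass
class PipelineConfig:
    """Paths and stage parameters with study-standard defaults."""

    vcf: str = ""
    gff3: str = ""
    fasta: str = ""
    phenotype: str = ""
    genotype: str = ""
    outdir: str = "bsaqtl_out"
    window: int = 2_000_000
    step: int = 20_000
    min_snps: int = 10
    level: float = 0.99
    bulk_size: int = 30
    min_depth: int = 10
    delta_min: float = 0.48
    n_markers: int = 27
    n_perm: int = 1000
    alpha: float = 0.01
    lod_min: float = 3.0
    ed_exponent: int = 1
    null_reps: int = 5000
    grid_step_cm: float = 0.5
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Parse a plain ``key = value`` configuration file."""
        kwargs = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {int: int, float: float, str: str, "int": int, "float": float, "str": str}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in fields:
                    raise ValueError(f"unknown configuration key {key!r}")
                kwargs[key] = casts[fields[key]](value)
        return cls(**kwargs)


def _nearest_depth_classes(depths: Sequence[float]) -> list[int]:
    classes = {int(np.clip(round(d / 10.0) * 10, DEPTH_GRID[0], DEPTH_GRID[-1])) for d in depths}
    return sorted(classes)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def analyze_study(
    variants: Sequence[variants_mod.Variant],
    phenotypes: Mapping[str, float] | pd.Series,
    gene_models: Sequence[genes_mod.GeneModel],
    reference,
    genotype_lookup: Callable[[str, Sequence[int]], tuple[list[str], np.ndarray]],
    chrom_lengths: Mapping[str, int],
    config: PipelineConfig | None = None,
    band: windows_mod.ConfidenceBand | None = None,
) -> dict:
    """Run the analysis chain on in-memory objects; returns a result dict.

    ``genotype_lookup(chrom, positions)`` must return the line ids and an
    (n_lines, n_positions) matrix of tolerant-allele dosages {0,1,2} at the
    requested marker sites.  A precomputed null ``band`` (same bulk size and
    depth regime) may be supplied to avoid re-simulating it.
    """
    cfg = config or PipelineConfig()
    report: dict = {"counts": {"input": len(variants)}}

    kept = variants_mod.filter_parent_polymorphic(variants)
    report["counts"]["parent_polymorphic"] = len(kept)
    kept = variants_mod.depth_filter(kept, cfg.min_depth)
    report["counts"]["depth_pass"] = len(kept)

    site_stats = stats_mod.compute_site_stats(kept, ed_exponent=cfg.ed_exponent)
    report["site_stats"] = site_stats
    report["counts"]["stats_sites"] = len(site_stats)

    profile = windows_mod.window_profile(
        site_stats, cfg.window, cfg.step, cfg.min_snps, chrom_lengths=chrom_lengths
    )
    report["profile"] = profile
    if band is None:
        classes = _nearest_depth_classes(profile["mean_depth"]) if not profile.empty else [50]
        band = windows_mod.simulate_null_thresholds(
            cfg.bulk_size,
            depth=float(np.mean(classes)),
            n_rep=cfg.null_reps,
            depth_classes=classes,
            ed_exponent=cfg.ed_exponent,
            seed=cfg.seed,
        )
    report["band"] = band

    regions = windows_mod.call_regions(profile, band, level=cfg.level)
    calls = windows_mod.intersect_methods(regions)
    report["regions"] = regions
    report["calls"] = calls
    report["primary_call"] = None
    report["qtl_report"] = pd.DataFrame()
    report["candidates"] = pd.DataFrame()
    report["fine_interval"] = None
    if not calls:
        return report

    # primary call: strongest Δ peak among the four-method intersections
    primary = max(calls, key=lambda c: abs(c.peaks.get("delta", (0.0, 0, 0, 0))[0]))
    report["primary_call"] = primary

    in_iv = site_stats[
        (site_stats["chrom"] == primary.chrom)
        & (site_stats["pos"] >= primary.start)
        & (site_stats["pos"] <= primary.end)
    ]
    effects = genes_mod.classify_variants(in_iv, gene_models, reference)
    report["effects"] = effects
    markers = linkage_mod.select_fine_markers(
        in_iv, effects, primary.chrom, primary.start, primary.end,
        delta_min=cfg.delta_min, n_markers=cfg.n_markers,
    )
    report["markers"] = markers
    if len(markers) < 2:
        return report

    line_ids, codes = genotype_lookup(primary.chrom, markers["pos"].tolist())
    geno = linkage_mod.MarkerGenotypes(
        line_ids=list(line_ids),
        marker_ids=[f"{primary.chrom}:{p}" for p in markers["pos"]],
        chrom=primary.chrom,
        positions_bp=markers["pos"].to_numpy(),
        codes=codes,
    )
    gmap = linkage_mod.estimate_map(geno)
    scan = linkage_mod.interval_mapping(geno, phenotypes, gmap, step_cm=cfg.grid_step_cm)
    threshold = linkage_mod.permutation_threshold(
        geno, phenotypes, gmap, n_perm=cfg.n_perm, alpha=cfg.alpha,
        step_cm=cfg.grid_step_cm, seed=cfg.seed,
    )
    qtl_report = linkage_mod.call_qtl(scan, threshold, lod_min=cfg.lod_min)
    report.update(geno=geno, gmap=gmap, scan=scan, permutation_lod=threshold, qtl_report=qtl_report)

    sig = qtl_report[qtl_report["significant"]]
    if sig.empty:
        return report
    top = sig.iloc[0]
    fine_start = int(round(gmap.bp_of_cm(top["left_ci"])))
    fine_end = int(round(gmap.bp_of_cm(top["right_ci"])))
    report["fine_interval"] = (primary.chrom, fine_start, fine_end)
    report["fine_genes"] = genes_mod.genes_in_interval(gene_models, primary.chrom, fine_start, fine_end)
    report["candidates"] = genes_mod.filter_candidate_snps(
        site_stats, effects, primary.chrom, fine_start, fine_end, delta_min=cfg.delta_min
    )
    return report


def simulate_study(config: sim_mod.SimConfig) -> dict:
    """Generate a complete in-silico study bundle from one SimConfig."""
    pop = sim_mod.simulate_cross(config)
    phen = sim_mod.simulate_phenotypes(pop, config)
    bulks = sim_mod.select_bulks(phen, config.bulk_size)
    reference = sim_mod.emit_reference_annotation(config)
    variants = sim_mod.simulate_pool_reads(pop, bulks, config, reference)
    return dict(config=config, pop=pop, phen=phen, bulks=bulks, reference=reference, variants=variants)


def genotype_lookup_from_population(pop: sim_mod.PopulationData) -> Callable:
    """Marker-genotype accessor backed by simulated line genotypes."""

    def lookup(chrom: str, positions: Sequence[int]) -> tuple[list[str], np.ndarray]:
        ci = pop.chrom_names.index(chrom)
        cols = []
        for p in positions:
            hit = np.nonzero((pop.site_chrom == ci) & (pop.site_pos == p))[0]
            if hit.size == 0:
                raise KeyError(f"no genotyped site at {chrom}:{p}")
            cols.append(int(hit[0]))
        return list(pop.line_ids), pop.genotypes[:, cols]

    return lookup


def write_simulated_bundle(config: sim_mod.SimConfig, outdir: str) -> dict:
    """Simulate a study and write VCF, FASTA, GFF3, phenotype and genotype files."""
    os.makedirs(outdir, exist_ok=True)
    bundle = simulate_study(config)
    contigs = dict(zip(config.chrom_names, config.chrom_lengths))
    paths = {
        "vcf": os.path.join(outdir, "variants.vcf"),
        "fasta": os.path.join(outdir, "reference.fa"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "phenotype": os.path.join(outdir, "phenotypes.tsv"),
        "genotype": os.path.join(outdir, "genotypes.tsv"),
    }
    variants_mod.write_vcf(bundle["variants"], paths["vcf"], contigs=contigs)
    bundle["reference"].write_fasta(paths["fasta"])
    bundle["reference"].write_gff3(paths["gff3"])
    bundle["phen"].to_tsv(paths["phenotype"])
    pop = bundle["pop"]
    cols = [f"{n}:{p}" for n, p in zip(pop.site_chrom_names(), pop.site_pos)]
    geno_df = pd.DataFrame(pop.genotypes, index=pd.Index(pop.line_ids, name="line_id"), columns=cols)
    geno_df.to_csv(paths["genotype"], sep="\t")
    bundle["paths"] = paths
    return bundle


def run_full_pipeline(config: PipelineConfig) -> dict:
    """File-based pipeline: read inputs, analyse, write tables and manifest."""
    from pyfaidx import Fasta

    for key in ("vcf", "gff3", "fasta", "phenotype", "genotype"):
        path = getattr(config, key)
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"pipeline input {key!r} missing: {path!r}")
    os.makedirs(config.outdir, exist_ok=True)

    variants, skipped = variants_mod.read_variants(config.vcf)
    gene_models = genes_mod.read_gff3(config.gff3)
    fasta = Fasta(config.fasta)
    chrom_lengths = {name: len(rec) for name, rec in fasta.items()}
    phen_table = sim_mod.PhenotypeTable.from_tsv(config.phenotype)
    phen = pd.Series(phen_table.sr, index=phen_table.line_ids)
    geno_df = pd.read_csv(config.genotype, sep="\t", index_col="line_id")

    def lookup(chrom: str, positions: Sequence[int]) -> tuple[list[str], np.ndarray]:
        cols = [f"{chrom}:{p}" for p in positions]
        return geno_df.index.tolist(), geno_df[cols].to_numpy(dtype=np.int8)

    report = analyze_study(
        variants, phen, gene_models, fasta, lookup, chrom_lengths, config=config
    )
    report["counts"]["vcf_skipped"] = skipped

    out = lambda name: os.path.join(config.outdir, name)
    report["site_stats"].to_csv(out("site_stats.tsv"), sep="\t", index=False)
    report["profile"].to_csv(out("window_profile.tsv"), sep="\t", index=False)
    windows_mod.regions_to_frame(report["regions"]).to_csv(out("regions.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            dict(chrom=c.chrom, start=c.start, end=c.end, length_mb=c.length("Mb"), methods=",".join(c.methods))
            for c in report["calls"]
        ]
    ).to_csv(out("qtl_calls.tsv"), sep="\t", index=False)
    if "scan" in report:
        report["scan"].to_csv(out("linkage_scan.tsv"), sep="\t", index=False)
    report["qtl_report"].to_csv(out("qtl_report.tsv"), sep="\t", index=False)
    report["candidates"].to_csv(out("candidates.tsv"), sep="\t", index=False)

    manifest = dict(
        parameters={
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(PipelineConfig)
            if f.name != "outdir"
        },
        inputs={k: _sha256(getattr(config, k)) for k in ("vcf", "gff3", "fasta", "phenotype", "genotype")},
        counts=report["counts"],
        permutation_seed=config.seed,
        fine_interval=report.get("fine_interval"),
    )
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    report["manifest"] = manifest
    return report
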