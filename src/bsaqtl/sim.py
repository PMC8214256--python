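"""Synthetic F2:3 bulked-segregant study generator.

Emulates the statistical structure of a QTL-seq experiment on a biparental
rice cross: an F2 population from two inbred parents, a survival-rate
phenotype controlled by one planted QTL plus normal noise, extreme-tail
bulks, pooled short-read allele depths at each parent-polymorphic SNP, and
a seeded reference genome with protein-coding gene models so that coding
effects of the variants can be classified downstream.

Genotypes are coded as copies of the tolerant parent's allele (0/1/2).
Crossovers follow a Haldane (no-interference) process: per gamete the
crossover count is Poisson in the chromosome's map length and positions are
uniform, so recombination fractions follow Haldane's map function while the
linkage stage converts estimated fractions to centimorgans with Kosambi's
function, as is conventional for rice maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from bsaqtl._util import (
    STREAM_ALLELES,
    STREAM_CROSS,
    STREAM_PHENO,
    STREAM_READS,
    STREAM_REFERENCE,
    STREAM_SITES,
    ConfigError,
    require,
    stream_rng,
)
from bsaqtl.genes import NON_SYNONYMOUS, GeneModel, classify_variant_effect, write_gff3
from bsaqtl.variants import Variant

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated cross, phenotype, bulking and sequencing.

    Defaults follow the design of a large seedling cold-tolerance study:
    460 F2:3 lines, extreme bulks of 30 lines each, ~50x mean pooled and
    parental coverage, and one QTL explaining about a quarter of the
    survival-rate variance.  The genome itself (two 30-Mb chromosomes at
    one SNP per kb, ~4 cM/Mb) is a scaled-down but structurally faithful
    stand-in for a full rice genome.
    """

    chrom_lengths: tuple[int, ...] = (30_000_000, 30_000_000)
    recomb_rate: float = 4.0  # cM per Mb
    variant_density: float = 1.0  # polymorphic SNPs per kb
    n_lines: int = 460
    bulk_size: int = 30
    pool_depth: float = 50.0  # mean reads per bulk per site
    parent_depth: float = 50.0
    qtl_chrom: str = "chr1"
    qtl_pos: int = 15_000_000
    qtl_additive: float = 15.0  # SR units per tolerant-allele copy
    qtl_dominance: float = 0.0
    target_pve: float = 0.26  # fraction of line-level SR variance
    baseline_sr: float = 50.0  # population mean survival rate (%)
    residual_sd: float = 10.0  # line-level noise SD when no QTL variance
    replicates: int = 3
    gene_spacing: int = 12_000  # bp between gene starts in the annotation
    cds_length: int = 1_800
    seed: int = 0

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))

    def validate(self) -> None:
        require(len(self.chrom_lengths) >= 1, "at least one chromosome required")
        require(all(l > 0 for l in self.chrom_lengths), "chromosome lengths must be positive")
        require(self.variant_density > 0, "variant density must be positive")
        require(self.n_lines >= 2 * self.bulk_size > 0, "need N >= 2k > 0")
        require(self.pool_depth > 0 and self.parent_depth > 0, "depths must be positive")
        require(0 <= self.target_pve < 1, "target PVE must lie in [0, 1)")
        require(self.recomb_rate >= 0, "recombination rate must be >= 0")
        require(self.replicates >= 1, "replicates must be >= 1")
        if self.qtl_chrom not in self.chrom_names:
            raise ConfigError(f"QTL chromosome {self.qtl_chrom!r} not among {self.chrom_names}")
        length = self.chrom_lengths[self.chrom_names.index(self.qtl_chrom)]
        require(1 <= self.qtl_pos <= length, "QTL position outside its chromosome")


@dataclass
class PopulationData:
    """Per-line genotypes (copies of the tolerant allele) at every SNP site."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    site_chrom: np.ndarray  # per-site chromosome index
    site_pos: np.ndarray  # per-site 1-based bp, increasing within chromosome
    genotypes: np.ndarray  # (n_lines, n_sites) int8 in {0,1,2}
    line_ids: list[str]
    qtl_site: int  # column index of the causal site

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def site_chrom_names(self) -> np.ndarray:
        return np.asarray(self.chrom_names)[self.site_chrom]


@dataclass
class PhenotypeTable:
    """Line survival rates (%, 0-100), optionally with per-replicate values."""

    line_ids: list[str]
    sr: np.ndarray
    replicates: np.ndarray | None = None  # (n_lines, n_reps)

    def __post_init__(self) -> None:
        self.sr = np.asarray(self.sr, float)
        if not ((self.sr >= 0) & (self.sr <= 100)).all():
            raise ValueError("survival rates must lie in [0, 100]")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            ncol = 0 if self.replicates is None else self.replicates.shape[1]
            header = "line_id\tSR" + "".join(f"\trep{i + 1}" for i in range(ncol))
            fh.write(header + "\n")
            for i, lid in enumerate(self.line_ids):
                row = f"{lid}\t{self.sr[i]:.6g}"
                if self.replicates is not None:
                    row += "".join(f"\t{v:.6g}" for v in self.replicates[i])
                fh.write(row + "\n")

    @classmethod
    def from_tsv(cls, path: str) -> "PhenotypeTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        reps = [c for c in df.columns if c.startswith("rep")]
        return cls(
            line_ids=df["line_id"].astype(str).tolist(),
            sr=df["SR"].to_numpy(float),
            replicates=df[reps].to_numpy(float) if reps else None,
        )


@dataclass(frozen=True)
class BulkAssignment:
    """Index sets of the tolerant and sensitive extreme bulks."""

    tolerant: np.ndarray
    sensitive: np.ndarray
    tolerant_ids: tuple[str, ...]
    sensitive_ids: tuple[str, ...]


@dataclass
class Reference:
    """Seeded reference genome plus its gene annotation."""

    sequences: dict[str, str]
    genes: list[GeneModel]

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path: str) -> None:
        write_gff3(self.genes, path)


# ---------------------------------------------------------------------------
# cross and phenotype


def _site_positions(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Distinct sorted SNP positions per chromosome, with a site planted at the QTL."""
    chroms, positions = [], []
    for ci, length in enumerate(config.chrom_lengths):
        n = max(2, round(length / 1000 * config.variant_density))
        pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 8))
        while pos.size < n:
            extra = rng.integers(1, length + 1, size=n)
            pos = np.unique(np.concatenate([pos, extra]))
        if pos.size > n:
            pos = np.sort(rng.choice(pos, size=n, replace=False))
        if config.chrom_names[ci] == config.qtl_chrom and config.qtl_pos not in pos:
            pos = np.sort(np.append(pos, config.qtl_pos))
        chroms.append(np.full(pos.size, ci, dtype=np.int16))
        positions.append(pos.astype(np.int64))
    return np.concatenate(chroms), np.concatenate(positions)


def _gamete(pos: np.ndarray, length: int, map_len_morgans: float, rng: np.random.Generator) -> np.ndarray:
    start = int(rng.integers(2))
    n_xo = int(rng.poisson(map_len_morgans))
    if n_xo == 0:
        return np.full(pos.size, start, dtype=np.int8)
    xo = np.sort(rng.uniform(0, length, size=n_xo))
    return ((start + np.searchsorted(xo, pos)) % 2).astype(np.int8)


def simulate_cross(config: SimConfig) -> PopulationData:
    """Simulate N F2 lines as pairs of recombinant gametes from the F1.

    Each gamete receives Poisson-distributed crossovers uniformly placed
    along the chromosome; genotype frequencies converge to 1:2:1 at every
    site.  Fully deterministic under the config seed.
    """
    config.validate()
    site_rng = stream_rng(config.seed, STREAM_SITES)
    cross_rng = stream_rng(config.seed, STREAM_CROSS)
    site_chrom, site_pos = _site_positions(config, site_rng)
    n_sites = site_pos.size
    geno = np.empty((config.n_lines, n_sites), dtype=np.int8)
    for ci, length in enumerate(config.chrom_lengths):
        cols = np.nonzero(site_chrom == ci)[0]
        pos = site_pos[cols]
        map_len = length / 1e6 * config.recomb_rate / 100.0  # Morgans
        for line in range(config.n_lines):
            g = _gamete(pos, length, map_len, cross_rng) + _gamete(pos, length, map_len, cross_rng)
            geno[line, cols] = g
    qtl_cols = np.nonzero(
        (site_chrom == config.chrom_names.index(config.qtl_chrom)) & (site_pos == config.qtl_pos)
    )[0]
    width = len(str(config.n_lines))
    return PopulationData(
        chrom_names=config.chrom_names,
        chrom_lengths=tuple(config.chrom_lengths),
        site_chrom=site_chrom,
        site_pos=site_pos,
        genotypes=geno,
        line_ids=[f"L{i + 1:0{width}d}" for i in range(config.n_lines)],
        qtl_site=int(qtl_cols[0]),
    )


def qtl_variance(config: SimConfig) -> float:
    """Phenotypic variance contributed by the QTL under 1:2:1 segregation."""
    return config.qtl_additive**2 / 2.0 + config.qtl_dominance**2 / 4.0


def residual_sd_for_pve(config: SimConfig) -> float:
    """Line-level noise SD giving the target PVE in expectation (pre-truncation)."""
    v_qtl = qtl_variance(config)
    if v_qtl == 0 or config.target_pve == 0:
        return config.residual_sd
    return math.sqrt(v_qtl * (1.0 - config.target_pve) / config.target_pve)


def simulate_phenotypes(pop: PopulationData, config: SimConfig) -> PhenotypeTable:
    """Survival rates from the planted QTL plus normal noise.

    SR_i = μ + a·(g_i − 1) + d·1[g_i = 1] + ε_i with ε chosen so the QTL
    explains the target PVE at the line level (the mapped trait is the mean
    of ``replicates`` replicate measurements, each carrying √replicates times
    the line-level noise).  Values are truncated to [0, 100] after noise;
    the PVE target refers to the pre-truncation scale.
    """
    require(0 <= config.target_pve < 1, "target PVE must lie in [0, 1)")
    require(0 <= pop.qtl_site < pop.n_sites, "QTL site index out of range")
    rng = stream_rng(config.seed, STREAM_PHENO)
    g = pop.genotypes[:, pop.qtl_site].astype(float)
    genetic = (
        config.baseline_sr
        + config.qtl_additive * (g - 1.0)
        + config.qtl_dominance * (g == 1.0)
    )
    sd_line = residual_sd_for_pve(config)
    r = config.replicates
    reps = genetic[:, None] + rng.normal(0.0, sd_line * math.sqrt(r), size=(pop.n_lines, r))
    reps = np.clip(reps, 0.0, 100.0)
    sr = reps.mean(axis=1)
    return PhenotypeTable(line_ids=list(pop.line_ids), sr=sr, replicates=reps if r > 1 else None)


def select_bulks(phen: PhenotypeTable, k: int) -> BulkAssignment:
    """Extreme-tail bulks: k highest-SR lines (tolerant) and k lowest (sensitive).

    Ties are broken by ascending line id; the tolerant bulk is chosen first
    and the sensitive bulk from the remaining lines, so the two sets are
    disjoint even when every phenotype is identical.
    """
    n = len(phen.line_ids)
    require(n >= 2 * k > 0, f"need N >= 2k (N={n}, k={k})")
    order_idx = np.arange(n)
    # highest SR first, ties by ascending id
    top = sorted(order_idx, key=lambda i: (-phen.sr[i], phen.line_ids[i]))
    tolerant = np.array(sorted(top[:k]), dtype=int)
    remaining = [i for i in top[k:]]
    bottom = sorted(remaining, key=lambda i: (phen.sr[i], phen.line_ids[i]))
    sensitive = np.array(sorted(bottom[:k]), dtype=int)
    return BulkAssignment(
        tolerant=tolerant,
        sensitive=sensitive,
        tolerant_ids=tuple(phen.line_ids[i] for i in tolerant),
        sensitive_ids=tuple(phen.line_ids[i] for i in sensitive),
    )


# ---------------------------------------------------------------------------
# reference genome and annotation


def _build_genes(config: SimConfig, sequences: dict[str, bytearray]) -> list[GeneModel]:
    genes: list[GeneModel] = []
    cds_len = config.cds_length - config.cds_length % 3
    for ci, (chrom, length) in enumerate(zip(config.chrom_names, config.chrom_lengths)):
        i = 0
        start = 1_000
        while start + cds_len + 1_200 < length:
            gid = f"G{ci + 1:02d}g{i + 1:05d}"
            strand = "+" if i % 2 == 0 else "-"
            if i % 3 == 2:
                # two-exon gene with a 300-bp intron
                half = (cds_len // 2) - (cds_len // 2) % 3
                cds = (
                    (start + 300, start + 300 + half - 1),
                    (start + 300 + half + 300, start + 300 + cds_len + 300 - 1),
                )
                end = cds[-1][1] + 300
            else:
                cds = ((start + 300, start + 300 + cds_len - 1),)
                end = cds[-1][1] + 300
            genes.append(GeneModel(gid, chrom, strand, start, end, cds))
            i += 1
            start += config.gene_spacing
    return genes


def _plant_causal_codon(
    config: SimConfig, genes: list[GeneModel], sequences: dict[str, bytearray]
) -> GeneModel:
    """Guarantee a CDS over the QTL position with a codon every substitution
    of which can be non-synonymous, by writing a Glu (GAA) codon there."""
    covering = [
        g
        for g in genes
        if g.chrom == config.qtl_chrom and g.cds_offset(config.qtl_pos) is not None
    ]
    if not covering:
        # move the nearest gene so its first CDS segment covers the QTL site
        candidates = [g for g in genes if g.chrom == config.qtl_chrom]
        nearest = min(candidates, key=lambda g: abs(g.start - config.qtl_pos))
        cds_len = config.cds_length - config.cds_length % 3
        s = max(1, config.qtl_pos - cds_len // 2)
        moved = GeneModel(
            nearest.gene_id, nearest.chrom, nearest.strand, max(1, s - 300), s + cds_len + 299,
            ((s, s + cds_len - 1),),
        )
        genes[genes.index(nearest)] = moved
        covering = [moved]
    gene = covering[0]
    seq = sequences[gene.chrom]
    offset = gene.cds_offset(config.qtl_pos)
    within = offset % 3
    # genomic coordinates of the codon's three bases, in translation order
    cds_positions: list[int] = []
    for s, e in sorted(gene.cds):
        cds_positions.extend(range(s, e + 1))
    if gene.strand == "-":
        cds_positions = cds_positions[::-1]
    codon_positions = cds_positions[3 * (offset // 3) : 3 * (offset // 3) + 3]
    codon = b"GAA"
    comp = bytes.maketrans(b"ACGT", b"TGCA")
    for base, gpos in zip(codon, codon_positions):
        b = bytes([base])
        seq[gpos - 1] = (b.translate(comp) if gene.strand == "-" else b)[0]
    return gene


def emit_reference_annotation(config: SimConfig) -> Reference:
    """Seeded reference sequence and gene set; byte-identical per seed.

    Genes tile each chromosome on alternating strands (every third gene has
    two CDS exons); one gene's CDS is guaranteed to cover the QTL position
    and the codon there is set so that a non-synonymous causal SNP can be
    planted regardless of reading-frame offset.
    """
    config.validate()
    rng = stream_rng(config.seed, STREAM_REFERENCE)
    sequences: dict[str, bytearray] = {}
    for chrom, length in zip(config.chrom_names, config.chrom_lengths):
        idx = rng.integers(0, 4, size=length).astype(np.uint8)
        sequences[chrom] = bytearray(np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes())
    genes = _build_genes(config, sequences)
    _plant_causal_codon(config, genes, sequences)
    return Reference(
        sequences={c: s.decode("ascii") for c, s in sequences.items()},
        genes=genes,
    )


# ---------------------------------------------------------------------------
# pooled sequencing


def simulate_pool_reads(
    pop: PopulationData,
    bulks: BulkAssignment,
    config: SimConfig,
    reference: Reference | None = None,
) -> list[Variant]:
    """Pooled allele depths for both bulks plus homozygous parent records.

    Per site and bulk: depth ~ Poisson(mean pool depth), tolerant-allele
    reads ~ Binomial(depth, bulk tolerant-allele frequency).  REF is the
    reference base at the site; which parent carries REF is random per site,
    except at the causal site where the alternate allele is chosen to be
    non-synonymous in the planted gene.
    """
    if set(bulks.tolerant) & set(bulks.sensitive):
        raise ValueError("bulks must be disjoint")
    if reference is None:
        reference = emit_reference_annotation(config)
    rng = stream_rng(config.seed, STREAM_READS)
    allele_rng = stream_rng(config.seed, STREAM_ALLELES)

    n_sites = pop.n_sites
    p_t = pop.genotypes[bulks.tolerant].sum(axis=0) / (2.0 * len(bulks.tolerant))
    p_s = pop.genotypes[bulks.sensitive].sum(axis=0) / (2.0 * len(bulks.sensitive))

    depth_t = rng.poisson(config.pool_depth, size=n_sites)
    depth_s = rng.poisson(config.pool_depth, size=n_sites)
    tol_reads_t = rng.binomial(depth_t, p_t)
    tol_reads_s = rng.binomial(depth_s, p_s)
    pdep_t = rng.poisson(config.parent_depth, size=n_sites)
    pdep_s = rng.poisson(config.parent_depth, size=n_sites)
    tolerant_is_ref = allele_rng.random(n_sites) < 0.5
    alt_pick = allele_rng.integers(0, 3, size=n_sites)

    chrom_names = pop.site_chrom_names()
    variants: list[Variant] = []
    for j in range(n_sites):
        chrom = str(chrom_names[j])
        pos = int(pop.site_pos[j])
        ref_base = reference[chrom][pos - 1]
        others = [b for b in "ACGT" if b != ref_base]
        alt_base = others[alt_pick[j]]
        if j == pop.qtl_site:
            alt_base = _nonsynonymous_alt(config, reference, chrom, pos, ref_base) or alt_base
        t_ref = bool(tolerant_is_ref[j])
        # tolerant-first -> (ref, alt) orientation
        t_tol, t_oth = int(tol_reads_t[j]), int(depth_t[j] - tol_reads_t[j])
        s_tol, s_oth = int(tol_reads_s[j]), int(depth_s[j] - tol_reads_s[j])
        ad_bt = (t_tol, t_oth) if t_ref else (t_oth, t_tol)
        ad_bs = (s_tol, s_oth) if t_ref else (s_oth, s_tol)
        gt_t = (0, 0) if t_ref else (1, 1)
        gt_s = (1, 1) if t_ref else (0, 0)
        ad_pt = (int(pdep_t[j]), 0) if t_ref else (0, int(pdep_t[j]))
        ad_ps = (0, int(pdep_s[j])) if t_ref else (int(pdep_s[j]), 0)
        variants.append(
            Variant(
                chrom=chrom,
                pos=pos,
                ref=ref_base,
                alt=alt_base,
                gt_t=gt_t,
                gt_s=gt_s,
                ad_bt=ad_bt,
                ad_bs=ad_bs,
                ad_pt=ad_pt,
                ad_ps=ad_ps,
            )
        )
    return variants


def _nonsynonymous_alt(
    config: SimConfig, reference: Reference, chrom: str, pos: int, ref_base: str
) -> str | None:
    gene = next(
        (g for g in reference.genes if g.chrom == chrom and g.cds_offset(pos) is not None),
        None,
    )
    if gene is None:
        return None
    for alt in "ACGT":
        if alt == ref_base:
            continue
        eff = classify_variant_effect(chrom, pos, ref_base, alt, gene, reference)
        if eff.classification == NON_SYNONYMOUS:
            return alt
    return None


# ---------------------------------------------------------------------------
# phenotype summary


def phenotype_summary(values: PhenotypeTable | Sequence[float]) -> dict:
    """Mean, SD, range, sample skewness g1 and excess kurtosis g2.

    Skewness and kurtosis use the standard moment estimators
    (g1 = m3/m2^1.5, g2 = m4/m2^2 − 3); both are reported as NaN for a
    zero-variance sample, where they are undefined.
    """
    x = values.sr if isinstance(values, PhenotypeTable) else np.asarray(values, float)
    if x.size < 4:
        raise ValueError("need at least 4 values for the moment summary")
    out = dict(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        min=float(np.min(x)),
        max=float(np.max(x)),
    )
    if np.var(x) == 0:
        out["skewness"] = float("nan")
        out["kurtosis"] = float("nan")
    else:
        out["skewness"] = float(sps.skew(x, bias=True))
        out["kurtosis"] = float(sps.kurtosis(x, fisher=True, bias=True))
    return out
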