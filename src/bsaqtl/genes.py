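"""Candidate-gene analysis: interval queries, coding-effect classification,
haplotype--trait association and small reporting utilities.

Effect classification rebuilds the codon around a SNP from the reference
sequence and the gene's CDS segments (reverse-complemented for minus-strand
transcripts), substitutes the alternate allele and translates both codons
with the standard nuclear genetic code.  Stop-gain/stop-loss changes are
folded into the non-synonymous class with an explanatory note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats as sps

from bsaqtl._util import require

SYNONYMOUS = "synonymous"
NON_SYNONYMOUS = "non-synonymous"
NON_CODING = "non-coding"


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: span plus ordered CDS segments (1-based, closed)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        require(self.strand in "+-", f"{self.gene_id}: strand must be + or -")
        require(self.start <= self.end, f"{self.gene_id}: start > end")
        for s, e in self.cds:
            require(self.start <= s <= e <= self.end, f"{self.gene_id}: CDS outside gene span")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: total CDS length {self.cds_length} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS, in
        translation order, or None if the position is not coding."""
        segments = sorted(self.cds)
        offsets = []
        total = 0
        hit = None
        for s, e in segments:
            if s <= pos <= e:
                hit = total + (pos - s)
            offsets.append(total)
            total += e - s + 1
        if hit is None:
            return None
        if self.strand == "-":
            return total - 1 - hit
        return hit


@dataclass(frozen=True)
class VariantEffect:
    """Predicted coding consequence of a single-nucleotide variant."""

    gene_id: str | None
    classification: str
    ref_aa: str | None = None
    alt_aa: str | None = None
    codon_index: int | None = None
    strand: str | None = None
    note: str = ""

    @property
    def aa_change(self) -> str | None:
        """Table-style "before/after" amino-acid label, e.g. ``L/S``."""
        if self.ref_aa is None or self.alt_aa is None:
            return None
        return f"{self.ref_aa}/{self.alt_aa}"


# ---------------------------------------------------------------------------
# annotation I/O


def write_gff3(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tbsaqtl\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tbsaqtl\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
            )
            segments = sorted(g.cds, reverse=g.strand == "-")
            phase = 0
            for s, e in segments:
                fh.write(
                    f"{g.chrom}\tbsaqtl\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\tID={mrna}.cds;Parent={mrna}\n"
                )
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3


def read_gff3(path: str) -> list[GeneModel]:
    """Load gene models (gene + CDS features) from a GFF3 file via gffutils."""
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique", keep_order=True)
    out = []
    for gene in db.features_of_type("gene"):
        cds = tuple(sorted((c.start, c.end) for c in db.children(gene, featuretype="CDS")))
        out.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                cds=cds,
            )
        )
    out.sort(key=lambda g: (g.chrom, g.start))
    return out


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """1-based closed-interval fetch from a str mapping, pyfaidx Fasta, or
    any object exposing ``reference[chrom]`` sliceable content."""
    seq = reference[chrom]
    segment = seq[start - 1 : end]
    return segment if isinstance(segment, str) else str(segment)


# ---------------------------------------------------------------------------
# operations


def genes_in_interval(
    genes: Sequence[GeneModel], chrom: str, start: int, end: int
) -> list[GeneModel]:
    """Genes whose span overlaps the closed interval [start, end].

    Partial overlap counts.  Raises if the chromosome is absent from the
    annotation entirely.
    """
    known = {g.chrom for g in genes}
    if chrom not in known:
        raise ValueError(f"chromosome {chrom!r} not present in annotation (has {sorted(known)})")
    hits = [g for g in genes if g.chrom == chrom and g.start <= end and g.end >= start]
    hits.sort(key=lambda g: g.start)
    return hits


def classify_variant_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene: GeneModel,
    reference,
) -> VariantEffect:
    """Classify a SNP inside ``gene`` as synonymous / non-synonymous / non-coding.

    The reference base at ``pos`` must match ``ref``; a mismatch indicates an
    annotation/VCF inconsistency and raises.
    """
    if not gene.contains(pos):
        raise ValueError(f"{chrom}:{pos} outside gene {gene.gene_id} span")
    genome_base = _fetch(reference, chrom, pos, pos).upper()
    if genome_base != ref.upper():
        raise ValueError(f"reference mismatch at {chrom}:{pos}: FASTA has {genome_base}, VCF ref is {ref}")
    offset = gene.cds_offset(pos)
    if offset is None:
        return VariantEffect(gene.gene_id, NON_CODING, strand=gene.strand, note="intronic/UTR")
    if gene.cds_length % 3:
        raise ValueError(f"{gene.gene_id}: CDS length not divisible by 3")
    cds_seq = "".join(_fetch(reference, gene.chrom, s, e) for s, e in sorted(gene.cds)).upper()
    if gene.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        base_in_cds = str(Seq(alt.upper()).complement())
    else:
        base_in_cds = alt.upper()
    codon_index = offset // 3
    within = offset % 3
    codon = cds_seq[3 * codon_index : 3 * codon_index + 3]
    mutated = codon[:within] + base_in_cds + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutated).translate())
    note = ""
    if ref_aa == alt_aa:
        cls = SYNONYMOUS
    else:
        cls = NON_SYNONYMOUS
        if alt_aa == "*":
            note = "stop-gain"
        elif ref_aa == "*":
            note = "stop-loss"
    return VariantEffect(gene.gene_id, cls, ref_aa, alt_aa, codon_index, gene.strand, note)


def classify_variants(
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    reference,
) -> pd.DataFrame:
    """Classify every site in a (chrom, pos, ref, alt) table.

    Sites outside any gene are labelled non-coding ("intergenic").  Returns a
    frame with columns chrom, pos, gene_id, classification, aa_change, strand.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)
    rows = []
    for chrom, pos, ref, alt in zip(sites["chrom"], sites["pos"], sites["ref"], sites["alt"]):
        hit = None
        for g in by_chrom.get(chrom, ()):
            if g.start > pos:
                break
            if g.contains(pos):
                hit = g
                break
        if hit is None:
            eff = VariantEffect(None, NON_CODING, note="intergenic")
        else:
            eff = classify_variant_effect(chrom, int(pos), ref, alt, hit, reference)
        rows.append(
            dict(
                chrom=chrom,
                pos=int(pos),
                gene_id=eff.gene_id,
                classification=eff.classification,
                aa_change=eff.aa_change,
                strand=eff.strand,
                note=eff.note,
            )
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "classification", "aa_change", "strand", "note"])


def filter_candidate_snps(
    site_stats: pd.DataFrame,
    effects: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    delta_min: float = 0.48,
) -> pd.DataFrame:
    """Candidate table: non-synonymous SNPs in the interval with Δ > delta_min.

    Joins the coding-effect annotation with the four association statistics,
    mirroring the per-SNP candidate reporting of a fine-mapping study.
    """
    merged = site_stats.merge(effects, on=["chrom", "pos"], how="inner", suffixes=("", "_eff"))
    keep = (
        (merged["chrom"] == chrom)
        & (merged["pos"] >= start)
        & (merged["pos"] <= end)
        & (merged["classification"] == NON_SYNONYMOUS)
        & (merged["delta"] > delta_min)
    )
    cols = [c for c in ["chrom", "pos", "gene_id", "aa_change", "strand", "ref", "alt",
                        "delta", "g", "ed", "fisher_p"] if c in merged.columns]
    return merged.loc[keep, cols].sort_values("pos").reset_index(drop=True)


def haplotype_groups(
    alleles: pd.DataFrame,
    phenotypes: Mapping[str, float] | pd.Series,
    bulk_labels: Mapping[str, str] | pd.Series | None = None,
) -> dict:
    """Group lines by their allele tuple at the chosen SNPs and test the trait.

    ``alleles``: line-indexed frame, one column per SNP, values single bases.
    Returns a dict with a violin-ready ``summary`` frame (Hap labels assigned
    in descending group size), the Kruskal--Wallis statistic/p across groups,
    raw per-group values, and per-SNP bulk concordance when bulk labels are
    supplied (fraction of lines whose bulk matches the majority allele
    partition at that SNP).
    """
    require(alleles.shape[1] >= 1, "need at least one SNP")
    require(alleles.shape[0] >= 2, "need at least two lines")
    phen = pd.Series(phenotypes)
    lines = [l for l in alleles.index if l in phen.index]
    tuples = alleles.loc[lines].apply(tuple, axis=1)
    order = (
        tuples.value_counts()
        .sort_values(ascending=False)
        .index.tolist()
    )
    label_of = {t: f"Hap{i + 1}" for i, t in enumerate(order)}
    groups = {label_of[t]: [l for l in lines if tuples[l] == t] for t in order}
    values = {lab: phen[members].to_numpy(float) for lab, members in groups.items()}
    rows = []
    for t in order:
        lab = label_of[t]
        v = values[lab]
        rows.append(
            dict(
                haplotype=lab,
                alleles="".join(t),
                n=len(v),
                mean=float(np.mean(v)),
                median=float(np.median(v)),
                q1=float(np.percentile(v, 25)),
                q3=float(np.percentile(v, 75)),
            )
        )
    summary = pd.DataFrame(rows)
    nonempty = [v for v in values.values() if len(v)]
    if len(nonempty) < 2:
        stat, p = float("nan"), float("nan")
    else:
        stat, p = sps.kruskal(*nonempty)
    concordance = None
    if bulk_labels is not None:
        bl = pd.Series(bulk_labels)
        concordance = {}
        for snp in alleles.columns:
            sub = [l for l in lines if l in bl.index]
            if not sub:
                continue
            al = alleles.loc[sub, snp]
            labs = bl[sub]
            best = 0
            for target_allele in al.unique():
                for bulk in labs.unique():
                    match = ((al == target_allele) == (labs == bulk)).mean()
                    best = max(best, match)
            concordance[snp] = float(best)
    return dict(
        summary=summary,
        groups=groups,
        values=values,
        kruskal_stat=float(stat),
        kruskal_p=float(p),
        concordance=concordance,
    )


def expression_trait_correlation(expression: Sequence[float], trait: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between expression and the trait."""
    x = np.asarray(expression, float)
    y = np.asarray(trait, float)
    if x.shape != y.shape:
        raise ValueError("expression and trait must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def allele_count_ratio(count_a: int, count_b: int, decimals: int = 1) -> float:
    """Carrier-count ratio a:b reported as a rounded scalar (e.g. 5.8)."""
    if count_b == 0:
        raise ValueError("denominator count must be positive")
    return round(count_a / count_b, decimals)
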