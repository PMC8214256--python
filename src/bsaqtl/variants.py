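"""Variant ingestion: read a 4-sample VCF (two parents, two bulks) and apply
the parent-based SNP selection that precedes the bulk statistics.

Coordinates are 1-based, fully closed, matching VCF.  Allele depths are
stored in REF/ALT order as in the file; the tolerant-first orientation used
by the statistics is exposed through :attr:`Variant.ad_t` / :attr:`Variant.ad_s`,
which count reads carrying the tolerant parent's allele first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

DEFAULT_SAMPLES = ("P_T", "P_S", "B_T", "B_S")

_HOM_REF = (0, 0)
_HOM_ALT = (1, 1)


@dataclass(frozen=True)
class Variant:
    """One biallelic site with parent genotypes and per-bulk allele depths."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gt_t: tuple[int, int] | None  # tolerant parent genotype (allele indices)
    gt_s: tuple[int, int] | None  # sensitive parent genotype
    ad_bt: tuple[int, int]  # tolerant bulk (ref reads, alt reads)
    ad_bs: tuple[int, int]  # sensitive bulk (ref reads, alt reads)
    ad_pt: tuple[int, int] = (0, 0)
    ad_ps: tuple[int, int] = (0, 0)
    is_snp: bool = True

    def _parent_allele(self, gt: tuple[int, int] | None) -> str | None:
        if gt is None or gt[0] != gt[1] or gt[0] < 0:
            return None
        return self.ref if gt[0] == 0 else self.alt

    @property
    def parent_t_allele(self) -> str | None:
        """Tolerant parent's allele, if homozygous; else None."""
        return self._parent_allele(self.gt_t)

    @property
    def parent_s_allele(self) -> str | None:
        return self._parent_allele(self.gt_s)

    def _oriented(self, ad: tuple[int, int]) -> tuple[int, int]:
        allele = self.parent_t_allele
        if allele is None:
            raise ValueError(
                f"{self.chrom}:{self.pos}: tolerant-first depths undefined for a "
                "heterozygous/missing tolerant parent; filter first"
            )
        return ad if allele == self.ref else (ad[1], ad[0])

    @property
    def ad_t(self) -> tuple[int, int]:
        """Tolerant bulk depths as (tolerant-parent-allele reads, other reads)."""
        return self._oriented(self.ad_bt)

    @property
    def ad_s(self) -> tuple[int, int]:
        return self._oriented(self.ad_bs)

    @property
    def dp_t(self) -> int:
        return self.ad_bt[0] + self.ad_bt[1]

    @property
    def dp_s(self) -> int:
        return self.ad_bs[0] + self.ad_bs[1]


def read_variants(
    path: str, samples: Sequence[str] = DEFAULT_SAMPLES
) -> tuple[list[Variant], dict[str, int]]:
    """Read biallelic SNPs from a VCF with the four named samples.

    Multiallelic records, indels, and records lacking allele depths are
    skipped; the counts are returned alongside the variants.
    ``samples`` order is (tolerant parent, sensitive parent, tolerant bulk,
    sensitive bulk).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    missing = [s for s in samples if s not in vcf.samples]
    if missing:
        raise ValueError(f"VCF {path} lacks required sample(s): {', '.join(missing)}")
    idx = [vcf.samples.index(s) for s in samples]
    skipped = {"multiallelic": 0, "indel": 0, "missing_ad": 0}
    out: list[Variant] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped["indel"] += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            skipped["missing_ad"] += 1
            continue
        ad = ad.astype(int)
        gts = rec.genotypes  # [allele0, allele1, phased]

        def gt_of(i: int) -> tuple[int, int] | None:
            g = gts[i]
            if g is None or g[0] < 0 or g[1] < 0:
                return None
            return (int(g[0]), int(g[1]))

        def ad_of(i: int) -> tuple[int, int]:
            a = ad[i]
            return (max(int(a[0]), 0), max(int(a[1]), 0))

        it, is_, ibt, ibs = idx
        out.append(
            Variant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                gt_t=gt_of(it),
                gt_s=gt_of(is_),
                ad_bt=ad_of(ibt),
                ad_bs=ad_of(ibs),
                ad_pt=ad_of(it),
                ad_ps=ad_of(is_),
            )
        )
    if any(skipped.values()):
        log.info("read_variants(%s): skipped %s", path, skipped)
    return out, skipped


def filter_parent_polymorphic(
    variants: Iterable[Variant],
    infer_from_depth: bool = False,
    purity: float = 0.9,
) -> list[Variant]:
    """Keep sites where both parents are homozygous for different alleles.

    With ``infer_from_depth``, a missing parent genotype is inferred from
    allele-depth purity: a parent whose major-allele fraction is at least
    ``purity`` is treated as homozygous for that allele (for callers that
    omit genotype fields).
    """

    def resolve(gt, ad):
        if gt is not None:
            return gt if gt[0] == gt[1] else None
        if not infer_from_depth:
            return None
        total = ad[0] + ad[1]
        if total == 0:
            return None
        if ad[0] / total >= purity:
            return _HOM_REF
        if ad[1] / total >= purity:
            return _HOM_ALT
        return None

    kept = []
    for v in variants:
        gt_t = resolve(v.gt_t, v.ad_pt)
        gt_s = resolve(v.gt_s, v.ad_ps)
        if gt_t is None or gt_s is None or gt_t == gt_s:
            continue
        kept.append(replace(v, gt_t=gt_t, gt_s=gt_s))
    return kept


def depth_filter(
    variants: Iterable[Variant], min_depth: int = 0
) -> list[Variant]:
    """Remove sites where either bulk's total depth is below ``min_depth``."""
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    return [v for v in variants if v.dp_t >= min_depth and v.dp_s >= min_depth]


def write_vcf(
    variants: Sequence[Variant],
    path: str,
    contigs: dict[str, int] | None = None,
    samples: Sequence[str] = DEFAULT_SAMPLES,
) -> None:
    """Write variants as a minimal 4-sample VCF 4.2 with GT:AD:DP fields."""

    def fmt_gt(gt: tuple[int, int] | None) -> str:
        return "./." if gt is None else f"{gt[0]}/{gt[1]}"

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for v in variants:
            cells = []
            for gt, ad in ((v.gt_t, v.ad_pt), (v.gt_s, v.ad_ps), (None, v.ad_bt), (None, v.ad_bs)):
                cells.append(f"{fmt_gt(gt)}:{ad[0]},{ad[1]}:{ad[0] + ad[1]}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT:AD:DP\t" + "\t".join(cells) + "\n"
            )


def write_tsv(variants: Sequence[Variant], path: str) -> None:
    """Write the filtered set as a TSV with tolerant-first depths."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tparent_t\tparent_s\tad_t_tol\tad_t_other\tad_s_tol\tad_s_other\n")
        for v in variants:
            at, as_ = v.ad_t, v.ad_s
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.parent_t_allele}\t{v.parent_s_allele}\t"
                f"{at[0]}\t{at[1]}\t{as_[0]}\t{as_[1]}\n"
            )
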