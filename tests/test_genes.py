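"""Coding-effect classification, interval queries and haplotype association."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from bsaqtl.genes import (
    NON_CODING,
    NON_SYNONYMOUS,
    SYNONYMOUS,
    GeneModel,
    allele_count_ratio,
    classify_variant_effect,
    classify_variants,
    expression_trait_correlation,
    filter_candidate_snps,
    genes_in_interval,
    haplotype_groups,
    read_gff3,
    write_gff3,
)

# reference with a + strand gene whose CDS is ATG GAA GGG TTT TAA (pos 11..25)
CDS = "ATGGAAGGGTTTTAA"
REF = {"chr1": "A" * 10 + CDS + "A" * 25}
PLUS_GENE = GeneModel("gplus", "chr1", "+", 6, 30, ((11, 25),))


class TestGenesInInterval:
    GENES = [
        GeneModel("g1", "chr1", "+", 100, 200, ((100, 129),)),
        GeneModel("g2", "chr1", "-", 300, 400, ((310, 339),)),
        GeneModel("g3", "chr1", "+", 500, 600, ((520, 549),)),
    ]

    def test_no_overlap_gives_empty(self):
        assert genes_in_interval(self.GENES, "chr1", 210, 290) == []

    def test_partial_overlap_counts(self):
        hits = genes_in_interval(self.GENES, "chr1", 150, 300)
        assert [g.gene_id for g in hits] == ["g1", "g2"]

    def test_two_of_three(self):
        hits = genes_in_interval(self.GENES, "chr1", 350, 550)
        assert [g.gene_id for g in hits] == ["g2", "g3"]

    def test_unknown_chromosome_raises(self):
        with pytest.raises(ValueError, match="chrX"):
            genes_in_interval(self.GENES, "chrX", 1, 10)


class TestClassifyEffect:
    def test_plus_strand_missense(self):
        # CDS offset 5 (second codon GAA, third base? no: offset 5 = 6th base)
        eff = classify_variant_effect("chr1", 15, "A", "T", PLUS_GENE, REF)
        # codon 2 is GAA; offset 4 is its middle base -- here pos 15 is offset 4
        assert eff.classification == NON_SYNONYMOUS
        assert eff.aa_change == "E/V"

    def test_plus_strand_synonymous_third_base(self):
        eff = classify_variant_effect("chr1", 16, "A", "G", PLUS_GENE, REF)
        assert eff.classification == SYNONYMOUS
        assert eff.aa_change == "E/E"

    def test_stop_gain_flagged_nonsynonymous(self):
        # GAA (Glu) codon at 14..16; G->T at the first base gives TAA (stop)
        eff = classify_variant_effect("chr1", 14, "G", "T", PLUS_GENE, REF)
        assert eff.classification == NON_SYNONYMOUS
        assert eff.alt_aa == "*" and eff.note == "stop-gain"

    def test_non_coding_within_gene(self):
        eff = classify_variant_effect("chr1", 8, "A", "G", PLUS_GENE, REF)
        assert eff.classification == NON_CODING

    def test_minus_strand_matches_manual_translation(self):
        # put the reverse complement of the CDS on the genome; gene on - strand
        rc = str(Seq(CDS).reverse_complement())
        ref = {"chr1": "C" * 10 + rc + "C" * 25}
        gene = GeneModel("gminus", "chr1", "-", 6, 30, ((11, 25),))
        # genomic position complementing the CDS middle base of codon 2:
        # CDS offset 4 is genomic position 11 + (15 - 1 - 4) = 21
        pos = 21
        ref_base = ref["chr1"][pos - 1]
        alt = "A" if ref_base != "A" else "G"
        eff = classify_variant_effect("chr1", pos, ref_base, alt, gene, ref)
        # manual oracle: mutate, reverse-complement, translate
        seq = list(ref["chr1"])
        seq[pos - 1] = alt
        cds = str(Seq("".join(seq[10:25])).reverse_complement())
        manual_ref = str(Seq(CDS).translate())
        manual_alt = str(Seq(cds).translate())
        assert eff.classification == (SYNONYMOUS if manual_ref == manual_alt else NON_SYNONYMOUS)
        assert eff.aa_change == f"{manual_ref[1]}/{manual_alt[1]}"

    def test_strand_consistency(self):
        """A − strand gene classifies like its reverse-complemented + strand twin."""
        rc_genome = str(Seq(REF["chr1"]).reverse_complement())
        n = len(REF["chr1"])
        minus_gene = GeneModel(
            "gm", "chr1", "-", n - 30 + 1, n - 6 + 1, ((n - 25 + 1, n - 11 + 1),)
        )
        for pos, ref_b, alt in [(15, "A", "T"), (16, "A", "G"), (12, "T", "C")]:
            plus = classify_variant_effect("chr1", pos, ref_b, alt, PLUS_GENE, REF)
            mpos = n - pos + 1
            mref = str(Seq(ref_b).complement())
            malt = str(Seq(alt).complement())
            minus = classify_variant_effect("chr1", mpos, mref, malt, minus_gene, {"chr1": rc_genome})
            assert (plus.classification, plus.aa_change) == (minus.classification, minus.aa_change)

    def test_reference_mismatch_raises(self):
        with pytest.raises(ValueError, match="chr1:15"):
            classify_variant_effect("chr1", 15, "C", "T", PLUS_GENE, REF)

    def test_bad_cds_length_rejected_at_construction(self):
        with pytest.raises(ValueError):
            GeneModel("bad", "chr1", "+", 1, 100, ((10, 20),))


class TestClassifyVariants:
    def test_partition_conserves_counts(self):
        sites = pd.DataFrame(
            dict(chrom="chr1", pos=[3, 8, 12, 15, 16, 35],
                 ref=list("AATAAA"), alt=list("TTCTGT"))
        )
        eff = classify_variants(sites, [PLUS_GENE], REF)
        assert len(eff) == 6
        counts = eff["classification"].value_counts()
        assert counts.sum() == 6
        assert set(counts.index) <= {SYNONYMOUS, NON_SYNONYMOUS, NON_CODING}

    def test_gff3_roundtrip(self, tmp_path):
        genes = [
            PLUS_GENE,
            GeneModel("two_exon", "chr1", "-", 100, 200, ((110, 130), (140, 160))),
        ]
        path = tmp_path / "genes.gff3"
        write_gff3(genes, str(path))
        back = read_gff3(str(path))
        assert [(g.gene_id, g.strand, g.cds) for g in back] == [
            (g.gene_id, g.strand, g.cds) for g in genes
        ]


TABLE3 = pd.DataFrame(
    dict(
        chrom="chr6",
        pos=[30_484_096, 30_499_155, 30_499_218, 30_512_105, 30_563_973],
        delta=[0.71, 0.47, 0.58, 0.29, 0.60],
        g=[55.54, 21.54, 33.47, 8.52, 18.83],
        ed=[1.02, 0.44, 0.68, 0.17, 0.72],
        fisher_p=[4.97e-13, 9.03e-6, 1.73e-8, 4.49e-3, 4.71e-5],
    )
)


class TestFilterCandidateSnps:
    def effects(self, classification="non-synonymous"):
        return pd.DataFrame(
            dict(chrom="chr6", pos=TABLE3["pos"], gene_id="g", aa_change="L/S",
                 strand="-", classification=classification, note="")
        )

    def test_reported_threshold_keeps_three_rows(self):
        out = filter_candidate_snps(TABLE3, self.effects(), "chr6", 30_400_000, 30_600_000, 0.48)
        assert out["pos"].tolist() == [30_484_096, 30_499_218, 30_563_973]

    def test_impossible_threshold_empties_table(self):
        out = filter_candidate_snps(TABLE3, self.effects(), "chr6", 30_400_000, 30_600_000, 1.1)
        assert out.empty

    def test_synonymous_only_input_empties_table(self):
        out = filter_candidate_snps(TABLE3, self.effects("synonymous"), "chr6", 30_400_000, 30_600_000, 0.48)
        assert out.empty


class TestHaplotypeGroups:
    def test_two_snp_grouping_and_labels(self):
        rng = np.random.default_rng(0)
        lines = [f"L{i}" for i in range(40)]
        alleles = pd.DataFrame(
            dict(s1=rng.choice(["T", "A"], 40), s2=rng.choice(["G", "A"], 40)),
            index=lines,
        )
        phen = pd.Series(rng.normal(50, 10, 40), index=lines)
        res = haplotype_groups(alleles, phen)
        assert 1 <= len(res["groups"]) <= 4
        sizes = res["summary"]["n"].tolist()
        assert sizes == sorted(sizes, reverse=True)
        assert res["summary"]["haplotype"].tolist() == [f"Hap{i+1}" for i in range(len(sizes))]

    def test_perfect_bulk_concordance(self):
        lines = [f"T{i}" for i in range(30)] + [f"S{i}" for i in range(30)]
        alleles = pd.DataFrame(dict(snp=["A"] * 30 + ["T"] * 30), index=lines)
        phen = pd.Series([80.0] * 30 + [20.0] * 30, index=lines)
        labels = pd.Series(["T"] * 30 + ["S"] * 30, index=lines)
        res = haplotype_groups(alleles, phen, bulk_labels=labels)
        assert res["concordance"]["snp"] == 1.0
        assert res["kruskal_p"] < 1e-6

    def test_single_group_has_missing_test(self):
        lines = ["a", "b", "c"]
        alleles = pd.DataFrame(dict(s=["A", "A", "A"]), index=lines)
        phen = pd.Series([1.0, 2.0, 3.0], index=lines)
        res = haplotype_groups(alleles, phen)
        assert np.isnan(res["kruskal_p"])

    def test_null_kruskal_p_roughly_uniform(self):
        rng = np.random.default_rng(1)
        lines = [f"L{i}" for i in range(60)]
        alleles = pd.DataFrame(dict(s=rng.choice(["A", "T"], 60)), index=lines)
        hits = 0
        n_shuffles = 400
        for _ in range(n_shuffles):
            phen = pd.Series(rng.normal(size=60), index=lines)
            res = haplotype_groups(alleles, phen)
            hits += res["kruskal_p"] < 0.05
        assert 0.02 < hits / n_shuffles < 0.09


class TestExpressionCorrelation:
    def test_perfect_linear(self):
        sr = np.linspace(0, 100, 30)
        r, p = expression_trait_correlation(2 * sr + 5, sr)
        assert r == pytest.approx(1.0)
        assert p < 1e-20

    def test_independent_vectors_mostly_uncorrelated(self):
        rng = np.random.default_rng(2)
        small = 0
        for _ in range(100):
            r, _ = expression_trait_correlation(rng.normal(size=60), rng.normal(size=60))
            small += abs(r) < 0.3
        assert small >= 95

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            expression_trait_correlation([1.0, 2.0], [3.0, 4.0])
        r, p = expression_trait_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and np.isnan(p)


class TestAlleleCountRatio:
    @pytest.mark.parametrize("a,b,expected", [(1600, 275, 5.8), (10, 10, 1.0), (0, 5, 0.0)])
    def test_values(self, a, b, expected):
        assert allele_count_ratio(a, b) == expected

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            allele_count_ratio(5, 0)
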