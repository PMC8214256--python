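"""Simulate a complete bulked-segregant study and summarise the phenotype.

Builds an F2:3 cross of 460 lines with one survival-rate QTL explaining a
quarter of the variance, selects 30+30 extreme bulks, and simulates pooled
~50x allele depths at every parent-polymorphic SNP.
"""

from bsaqtl import SimConfig, phenotype_summary
from bsaqtl.pipeline import simulate_study

config = SimConfig(
    chrom_lengths=(10_000_000, 10_000_000),
    variant_density=0.5,
    qtl_chrom="chr1",
    qtl_pos=5_000_000,
    target_pve=0.25,
    seed=1,
)
bundle = simulate_study(config)
pop, phen, bulks = bundle["pop"], bundle["phen"], bundle["bulks"]

print(f"{pop.n_lines} lines genotyped at {pop.n_sites} SNPs on {len(pop.chrom_names)} chromosomes")
summary = phenotype_summary(phen)
print("survival rate (%):", {k: round(v, 2) for k, v in summary.items()})
print(f"tolerant bulk mean SR:  {phen.sr[bulks.tolerant].mean():.1f}")
print(f"sensitive bulk mean SR: {phen.sr[bulks.sensitive].mean():.1f}")
# The bulks sit in the distribution's tails; their SR gap is what powers the
# allele-frequency contrast every downstream statistic measures.
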