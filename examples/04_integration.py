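"""Integration: the >=2-of-3 rule over the three assay gene lists.

Reproduces the published overlap arithmetic: 2 TFs found by all three
assays, 26 by RNA+DNA only and 5 by RNA+protein only give 33 candidates.
"""

from tfscreen import integrate, venn_counts

all_three = ["STAT1", "PPARA"]
rna_dna = [f"RD{i:02d}" for i in range(26)]
rna_protein = [f"RP{i}" for i in range(5)]

rna = all_three + rna_dna + rna_protein + [f"R{i:02d}" for i in range(99)]
dna = all_three + rna_dna + [f"D{i:02d}" for i in range(67)]
protein = all_three + rna_protein + [f"P{i}" for i in range(4)]

table = integrate(rna, dna, protein, min_assays=2)
print(table.head(8))
print("\nVenn regions:", venn_counts(rna, dna, protein))
print("candidates (>=2 assays):", int(table["candidate"].sum()))
# The candidate count equals the sum of the all-three region and the three
# pairwise-only regions: 2 + 26 + 5 + 0 = 33.
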