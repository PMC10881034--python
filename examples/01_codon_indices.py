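"""Score coding sequences with codon-usage-bias indices.

Builds a small gene under a known codon-weight distribution, then reports
RSCU for one family, the gene's geometric-mean index (CAI-style) and its
effective number of codons (ENC). An index near 1 means the gene uses each
family's preferred codon almost exclusively; ENC runs from 20 (one codon
per amino acid) to 61 (uniform synonymous usage).
"""

import codonhealth as ch

w = ch.random_weight_table(seed=1, label="demo")
gene = ch.random_cds(200, w, seed=2, id="demo_gene")

counts = ch.count_codons(gene)
vec = ch.rscu(counts)
print("RSCU of the Ala family (sums to its degeneracy, 4):")
for codon in ch.standard_code().families["A"]:
    print(f"  {codon}: {vec.get(codon):.3f}")

index = ch.geometric_index(gene, w)
enc = ch.enc(counts)
print(f"\ngeometric index under its own weight table: {index:.3f}")
print(f"ENC: {enc:.1f}  (20 = extreme bias, 61 = no bias)")

best = ch.max_index_recode(gene.protein, w)
print(f"maximal-index recode scores {ch.geometric_index(best, w):.1f} "
      f"with ENC {ch.enc(ch.count_codons(best)):.0f}")
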