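# codonhealth

Codon-usage quantification and fitness-aware synonymous gene recoding for
microbial protein expression.

Overexpressing a recombinant gene drains a host cell's translational
resources: ribosomes dwell on the overexpressed mRNA and the rest of the
proteome competes for what is left. Which synonymous codons the gene uses
decides how severe that burden is. `codonhealth` is a toolkit for engineers
and modelers working on this problem in *E. coli*-like hosts. It
quantifies codon usage bias, derives codon weights directly from measured
per-codon fitness data (the Codon Health Index, χ), designs recoded genes to
any target index value, and predicts translational behavior with a ribosome
flow model.

## The quantities at the core

For amino acid *i* with *n*<sub>*i*</sub> synonymous codons and
*X*<sub>*ij*</sub> occurrences of codon *j*:

- **RSCU** (relative synonymous codon usage):
  RSCU<sub>*ij*</sub> = *X*<sub>*ij*</sub> / ((1/*n*<sub>*i*</sub>) Σ<sub>*j*</sub> *X*<sub>*ij*</sub>).
  1 means no bias; each family's values average to 1.
- **Relative adaptiveness**:
  *W*<sub>*ij*</sub> = RSCU<sub>*ij*</sub> / RSCU<sub>*i*,max</sub>, so the
  most-used codon of every family scores 1.
- **CAI-style geometric index**: (∏<sub>*k*=1..*L*</sub> *w*<sub>*k*</sub>)<sup>1/*L*</sup>
  over a gene's codons. The same engine scores CAI (W from highly expressed
  genes), sTAI-referenced indices, **nTE** (tRNA supply / codon demand,
  renormalized per family), and **χ**.
- **ENC** (effective number of codons):
  ENC = 2 + 9/F₂ + 1/F₃ + 5/F₄ + 3/F₆, with F<sub>k</sub> the mean
  homozygosity of degeneracy-*k* amino acids; 20 = one codon per amino
  acid, 61 = uniform synonymous usage.
- **χ (Codon Health Index)**: each codon is assayed by substituting it
  throughout two overexpressed reporters (CFP, mCherry) and measuring the
  host's Co-Expression Fitness fold change, giving a coordinate (c, m) with
  parents at (1, 1). The raw score is the Euclidean distance
  d = √(c² + m²) from the origin, and family-wise normalization
  d/d<sub>max</sub> turns distances into W-style weights.

Recoding algorithms (all translation-preserving, with a configurable fixed
5′ prefix, default 17 codons): maximal-index (ENC = 20) designs, systematic
single-codon sweeps (41 recodes for a gene containing all 20 amino acids),
a seeded greedy walk to any achievable target index, maximally dissimilar
recode sets via RSCU clustering, codon-bias matching between genes, and
exact synonymous-space counting. The ribosome flow model chunks an mRNA
into nine-codon ribosome footprints and solves the occupancy dynamics to
steady state. Plate-reader time series become Growth Fitness,
Co-Expression Fitness and Expression Level via background-subtracted,
ceiling-truncated AUCs.

The bundled tables (`codonhealth/data/*_synthetic.csv`) are synthetic
stand-ins generated by `codonhealth.simulate` with fixed seeds — use your
own measured weight/elongation-time tables for real design work.

## Worked example

```python
import codonhealth as ch
from codonhealth import io as chio

chi = chio.read_weight_table(ch.bundled_path("chi_weights_synthetic.csv"), label="chi")
(_, cfp), = ch.read_protein_fasta(ch.bundled_path("cfp_synthetic.fasta"))

n = ch.synonymous_space_size(cfp, fixed_prefix_len=17)
print(ch.scientific_notation(n))            # 1.8e+104

parent = ch.max_index_recode(cfp, chi)
print(ch.geometric_index(parent, chi))      # 1.0
print(ch.enc(ch.count_codons(parent)))      # 20.0

spec = ch.RecodeSpec(weights=chi, target_index=0.85, tolerance=0.005, seed=11)
res = ch.greedy_recode(spec, cfp)
print(round(res.achieved_index, 4))         # 0.8452
```

The 238-residue CFP-type protein admits ~1.8 × 10<sup>104</sup> synonymous
sequences once the first 17 codons are pinned — why design must be
algorithmic, not exhaustive. The maximal-χ design uses each family's
fittest codon everywhere (index exactly 1, ENC exactly 20), and the greedy
recode lands within tolerance of the requested χ = 0.85. The
`examples/` scripts walk through each capability (indices, χ derivation,
recoding, ribosome flow, plate metrics, landscape PCA/clustering) and print
annotated output; a thin CLI (`codonhealth --help`) wraps the same calls
for shell use.

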