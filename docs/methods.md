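# Methods

This note records the models implemented in `codonhealth`, the conventions
and numerical choices behind them, what the synthetic generators do and do
not emulate, and the package's known limitations.

## Codon-bias indices

**RSCU and relative adaptiveness.** RSCU is observed codon frequency over
the frequency expected under uniform synonymous usage; each family of
synonymous codons therefore averages to 1. Amino acids with zero
observations have an undefined RSCU (0/0) and are *flagged absent* rather
than written as 0 — downstream consumers (weight derivation, matrices)
decide explicitly how to treat them. Relative adaptiveness W divides each
RSCU by its family maximum, so every present family has exactly one codon
(or tied codons) at W = 1.

**Geometric index.** CAI, χ-, sTAI- and nTE-style scores all use one
engine: the geometric mean of W over a gene's scored codons, computed in
log space. Conventions:

- Stop codons are never scored.
- Single-codon amino acids (Met, Trp) are excluded by default — they carry
  W = 1 identically, so including them only dilutes L; the classical
  practice excludes them, and a flag restores inclusion for comparison
  with tools that keep them.
- A zero weight would annihilate the product; the scoring floor
  `epsilon_floor` (default 0.01, per weight table) substitutes for W = 0.
  Strict mode raises instead, naming the codon. The floor only matters for
  user-supplied tables containing true zeros.
- Recoding operations score the variable region only by default, since
  targets describe the designed region; whole-gene scoring is a flag.

**ENC.** Per amino acid the homozygosity uses the bias-corrected estimator
F̂ = (nΣp̂² − 1)/(n − 1); amino acids observed ≤ 1 time are dropped. Class
means over degeneracy classes {2, 3, 4, 6} feed
ENC = 2 + 9/F₂ + 1/F₃ + 5/F₄ + 3/F₆. Two practical details:

- A class with no estimable member — or whose mean F̂ is non-positive,
  which the corrected estimator can produce at extreme evenness — is
  imputed from the mean *standardized* homozygosity of the estimable
  classes (b = (F̂ − 1/k)/(1 − 1/k), averaged, then mapped back to the
  missing class's [1/k, 1] range), with a warning. This keeps short or
  compositionally skewed genes scorable while respecting each class's
  admissible range.
- The result is capped at 61. Finite samples of perfectly uniform usage
  give F̂ slightly below 1/k, which would push the formula above the
  theoretical maximum; the cap is the standard convention and makes the
  uniform boundary exact. `enc_from_homozygosity` exposes the raw formula
  for direct evaluation at stated F values.

**nTE.** Ratio of sTAI weight (tRNA supply) to genomic codon frequency
(demand), renormalized within each family to max 1 so the ratios serve as
W values. Genomic frequency, not transcript-weighted codon use, is the
demand term. Zero frequencies error in strict mode or are floored at 1e-9
with a warning.

**Expected RSCU of a perfectly adapted gene.** Two constructions are
offered. `perfect` (default): a gene that always uses the W = 1 codon, so
that codon's RSCU is the degeneracy n and synonyms are 0 — this matches
the notion that a perfectly adapted gene scores index 1. Ties at the
family maximum make this undefined and raise. `proportional`: usage
proportional to W, RSCU = n·W/ΣW. Scale comparisons
(`compare_scales`) pair either raw weights or expected-RSCU vectors over
61 sense codons (default) or 59 (Met/Trp dropped; their values are
constant across scales) and report Pearson r with the two-tailed t-based
p at n − 2 degrees of freedom.

## χ derivation

Each codon's measured pair (c, m) — Co-Expression Fitness fold change
under CFP and mCherry overexpression, parents at (1, 1) — maps to the raw
score d = √(c² + m²). Distance from the origin deliberately rewards a
codon that strongly helps one context even if it mildly hurts the other; a
conservative min(c, m) score is available as a clearly separate option.
Within each family W = d/d_max. Ties at the maximum resolve toward the
parent codon, else lexicographically — a deterministic convention that
only decides where indicator-style designs collapse. Duplicate records and
stop codons are rejected; a family represented only partially is an error
(silently scoring an incomplete family would bias d_max), while a family
with no records is flagged absent.

The derivation is exactly scale-invariant (multiplying all pairs by a
positive constant cancels in the ratio) and exactly inverts the synthetic
fitness-table generator at zero noise, which the tests exploit for
parameter recovery at machine precision.

## Recoding algorithms

All recoders treat the protein as fixed, never touch the first
`fixed_prefix_len` codons (default 17 — the 5′ region interacts with
initiation and is held constant across designs), and preserve a trailing
stop codon as-is.

- **Maximal-index**: argmax-W per family; ties break lexicographically
  with a warning. Scores exactly 1 and has ENC = 20 when all classes are
  present.
- **Systematic sweeps**: defined only from a parent whose variable region
  uses one codon per amino acid; every (amino acid, alternative codon)
  pair yields one recode. A parent containing all 20 amino acids gives
  61 − 20 = 41 recodes.
- **Greedy target recoding**: the variable region starts fully randomized
  (uniform per family) to erase initial bias; proposals pick a uniform
  mutable position, then a uniform *alternative* synonym; acceptance
  requires strictly shrinking |index − target| (plateau moves rejected).
  Because one swap moves the log-mean by at most max|log W|/L, targets
  inside the achievable range are reachable within the default tolerance
  0.005 (which also guarantees correct two-decimal rounding);
  `max_iterations` defaults to 50·L. Scoring inside the walk is
  incremental in log space; the returned index is an independent re-score
  of the emitted sequence. Non-convergence raises, carrying the best
  sequence found. The achievable range is the closed-form geometric mean
  of per-position extreme weights.
- **Diverse sets**: a pool of greedy recodes (default 50 candidates,
  seeds derived deterministically from the spec seed) is clustered on
  59-dimension RSCU vectors (Euclidean, average linkage — stop/Met/Trp
  excluded as invariant dimensions); a maxclust cut at k picks each
  cluster's closest-to-target member, and the selection must clear the
  requested minimum pairwise RSCU distance or the call errors.
- **CUB matching**: to give gene B the codon-bias scheme of a designed
  gene A, each family's template proportions are apportioned onto B's
  codon demand with largest-remainder rounding (deterministic, and
  optimal per family for the Euclidean proportion error), then laid out
  sequentially. Families absent from the template fall back to uniform
  with a warning.
- **Space sizing**: exact arbitrary-precision product of per-position
  degeneracies over the variable region, with decimal-based rounding to
  scientific notation.

## Ribosome flow model

The mRNA is divided into nine-codon chunks (≈ one E. coli ribosome
footprint); chunk time λᵢ is the sum of member codon times and the
hopping rate is rᵢ = 1/λᵢ (the model needs rates; the reciprocal is the
documented conversion). Dynamics:
dxᵢ/dt = rᵢ₋₁xᵢ₋₁(1 − xᵢ) − rᵢxᵢ(1 − xᵢ₊₁) with initiation-rate inflow at
site 1 and open exit; production rate is rₙxₙ. The trailing partial chunk
defaults to `merge` (absorbed into the last full chunk); `scale`
(per-codon speed preserved at full footprint size) is offered for
sensitivity analysis.

Steady states integrate the ODEs (LSODA, rtol 1e-10) over doubling time
spans until max|dx/dt| < 1e-10; a damped fixed-point iteration of the
flux-balance relations is implemented as an independent route and the two
agree to ≤ 1e-7 in tests. At steady state the junction fluxes balance to
1e-8, densities lie strictly in (0, 1) for positive rates, production is
non-decreasing and saturating in initiation rate, and uniformly slower
profiles hold more ribosomes at matched initiation — the sequestration
signature of elongation-limited sequences.

## Plate metrics

Signals are summarized as trapezoidal AUCs of the background-subtracted
(scalar per-channel blank, default the first sample; clipped at zero)
signal over a common window. The window ends at the earliest time any
monitored channel reaches its detector ceiling (configurable to a fixed
end); boundary values are interpolated so AUC is exactly additive over
adjacent windows. Growth Fitness and Co-Expression Fitness are
induced/uninduced AUC ratios for OD600 and the constitutive reporter;
Expression Level is the induced AUC of the overexpressed channel (the
uninduced AUC is reported alongside for diagnostics). Ratios are not
clamped to [0, 1] — values above 1 occur in real data and are reported
as-is. Fold changes take replicate means *before* the ratio.

## Landscape analysis

RSCU matrices hold codons in rows (61, or 59 without Met/Trp) and
sequences in columns; absent amino acids fill with 0 by default (the
unused-codon convention) or 1 (`family_mean`, the no-bias value), flagged
per column. PCA centers each codon across sequences without variance
scaling (RSCU shares a natural scale) and uses SVD with a deterministic
sign convention (largest-|loading| codon positive per component); tests
cross-check scores and variance fractions against an independent PCA
implementation. Clustering is agglomerative (average or Ward linkage,
Euclidean) on columns; flat labels come from maxclust cuts. Operons are
aggregated by concatenating member CDSs in membership order into a
pseudo-CDS (internal-stop validation off), so operon codon counts are the
sums of member counts; operons with fewer than two genes are dropped.
Genome-scale operon analyses require the user to supply the gene set and
operon table — no annotation source is bundled.

## Synthetic generators and what they show

The generators produce every consumed format with known ground truth:
weight-proportional random CDSs (χ²-checked against the stated sampler),
fitness tables that exactly invert the χ derivation at zero noise
(quarter-circle placement at radius W·√2, parents exactly at (1, 1),
Gaussian coordinate noise clipped at zero), logistic growth/fluorescence
plates with a programmable burden (induced rate and carrying capacity
scaled by 1 − burden; multiplicative log-normal noise keeps signals
positive; default gains put the overexpression channel across the
detector ceiling mid-run so window truncation is exercised), and codon
elongation times inversely related to a weight table. Everything is a
pure function of its seed.

Passing round-trip tests show the *analysis* code is a correct inverse of
the stated generative model — they do not show that real plate curves are
logistic, that real fitness landscapes are quarter-circular, or that real
elongation times follow any weight table. The bundled
`*_synthetic.csv`/`cfp_synthetic.fasta` files are fixed-seed outputs of
these generators (the CFP-type protein is a 238-residue reconstruction of
a superfolder-GFP-derived sequence); they stand in for measured tables in
examples and tests and are labelled synthetic for that reason.

Default problem sizes in the test suite (30-codon brute-force oracles,
100–300-codon greedy trials, ≤ 15-chunk flow profiles, 20-seed noise
studies) were chosen as the smallest scales at which each property is
meaningfully exercised.

## Limitations

- χ weights are host- and context-specific; the package derives and
  applies them but ships no measured table.
- No codon-pair bias, mRNA secondary structure, GC-window or motif
  constraints in recoding; no multi-objective expression+fitness
  optimizer.
- The flow model is single-mRNA; shared ribosome-pool competition between
  transcripts is out of scope, as is stochastic (TASEP) simulation.
- No growth-curve model fitting (lag/µmax/K) — AUC is the deliberate
  aggregate.
- Standard genetic code only, though the code table is data-driven.
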