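# Methods

## Inheritance model and phasing

The package models a three-generation F2 intercross between divergent
founder lines on the X chromosome.  Outside the pseudoautosomal region
(PAR), males are hemizygous; male meiosis transmits the X intact.  Two
deterministic consequences drive the whole analysis:

1. **Phasing by subtraction.**  An F1 female's paternal allele at any marker
   is her F0 sire's single allele; the remaining member of her unordered
   pair is maternal.  No population phasing or EM is needed, and phase is
   exact wherever both genotypes are present.  A sire allele absent from the
   daughter's pair is a Mendelian error: the marker is flagged and set to
   unknown, never fatal — at survey scale errors are rare and local, and
   aborting would discard the remaining data.
2. **One maternal meiosis per F2 offspring.**  Sons carry the maternal
   gamete directly; daughters reveal it after subtracting the F1 father's
   single X allele.  Where the mother is heterozygous, the gamete allele
   maps to a grandparental origin (GM = from the F0 sow, GP = from the F0
   boar).  Origins are never called at markers where the mother is
   homozygous or unresolved.

PAR-flagged markers are excluded from every male-based step (males carry X
and Y copies there and the hemizygous subtraction is invalid).

## Counting, estimation and mapping

A meiosis is informative for an adjacent interval iff both flanking origins
are known and the mother is doubly heterozygous; it is recombinant iff the
two origin labels differ.  Only strictly adjacent flanking markers define an
interval; spans over several intervals are sums of adjacent ones.  θ̂ = r/n
is the plain binomial MLE — deliberately not an EM or multipoint estimate,
matching the table-level semantics of the reference data, where every
printed fraction is a ratio of small integers.  Distances use the Kosambi
map function d = ¼·ln((1+2θ)/(1−2θ)) Morgans (×100 for cM), defined for
θ < ½, with inverse θ = ½·tanh(2d); two-point maps are cumulative sums of
adjacent-interval distances anchored at 0.  Full precision is kept
internally; TSV reports round θ to 3 and cM to 2 decimals as is conventional
for linkage tables.

## Morton heterogeneity test

For units i = 1..k sharing one interval, X² = 2·[Σᵢ lnL(rᵢ,nᵢ;θ̂ᵢ) −
lnL(R,N;θ̄)] with binomial kernels and θ̄ = R/N, referred to χ²(k−1).
Conventions that matter for degrees of freedom:

* units with n = 0 carry no likelihood and are dropped **before** k is
  counted;
* units with r = 0 contribute lnL = 0 at θ̂ = 0 (0·ln 0 := 0) and are
  **retained** — they are evidence against a common nonzero θ.

No continuity correction and no map-function transformation are applied
inside the test.  P-values are raw upper-tail χ² probabilities; no
multiple-testing correction is applied (reports cover few pre-specified
intervals).

**Calibration caveat.**  The χ² reference is asymptotic.  With per-unit
expected recombinant counts of only ~1–5 (e.g. 17 units of 27–96 meioses at
θ = 0.05) the LRT is anticonservative: simulated type-I error at the nominal
5% level is closer to 8–9%.  The dedicated calibration test in the suite
documents this; borderline P-values from small units should be read with
that in mind (an exact or permutation reference would be the remedy and is
out of scope here).

## Haplotype grouping

Females are grouped by the concatenated phased alleles of one parental side
over an ordered marker subset (e.g. maternal label `1122`).  Labels with
unresolved positions (`?`) are excluded by default; a flag lets each
distinct partial label form its own group instead.  Grouped counts are
component-wise sums, so group-level θ̂ is automatically the meiosis-weighted
pooled fraction.

## Landscape and order comparison

Interval rate = Δ(Kosambi cM)/Δ(Mb) between adjacent markers carrying both
coordinates; physical positions are point coordinates (no clone-extent
arithmetic).  The chromosome-wide average is total cM / total Mb, so the
weighted mean of interval rates reproduces it identically.  Classification
thresholds (hotspot candidate > 2× average, coldspot < 0.1× average) are
configuration defaults chosen to match how such regions are described in
the linkage literature; there is no universal formal cutoff and both are
exposed as parameters.

Order discordance between two maps: markers are sorted by map-A coordinate
and map-B coordinates are scanned for maximal runs that fail strict
increase against the running maximum (merged transitively); each reported
segment therefore starts at the running-maximum marker and has length ≥ 2.
If most adjacent B steps decrease, B is flipped first so a globally inverted
map reports zero segments rather than one giant one.  Duplicate coordinates
(co-located assays) are rejected; callers deduplicate.  For the bundled pig
panel, the comparison between the pig clone map and the human X is run over
the linkage-mapped markers — the marker set over which the published
two-segment discordance claim is defined; including every clone-mapped
marker additionally surfaces a three-marker non-monotone run in Xq23
(UMNP870/SLC25A5/UMNP1008) whose status the source data leave open, and two
coordinate ties from duplicate assays.

## Synthetic-data generator

`simulate_dataset` draws the full design forward: F0 boar × sow crosses,
F1 females (boar X intact + recombined sow gamete) and F1 males (sow
gamete), then F2 offspring as maternal gamete (sons) or maternal gamete +
father's X intact (daughters).  Gametes follow a Markov model along the
marker order: start haplotype uniform, independent switch in interval j with
probability θⱼ.  Defaults emulate the reference design: 6 crosses, 3 F1
females per cross, 60 genotyped offspring per female (the study mean),
baseline θ = 0.05 per interval; per-female litter-size vectors or a Poisson
mode are available.  Founder models: `divergent` (lines fixed for
alternative alleles — maximal informativeness, as between divergent
breeds), `two_sow_haplotypes` (full-sisters can inherit either
grand-maternal haplotype — needed to emulate haplotype effects), and
`frequencies` (random allele draws producing uninformative meioses).
Heterogeneity: per-female θ multipliers, or a multiplier attached to
designated maternal founder haplotypes read over a marker subset.
Corruption applies missingness then random allele replacement
(arity-preserving) to the genotype table only; the truth record (phased
haplotypes, per-meiosis origins and crossover indicators) is untouched, and
origin/crossover consistency (origin switches exactly at crossover
intervals) is a tested invariant.  One seeded generator drives everything;
identical seeds give byte-identical output files.

What the generator does **not** emulate: crossover interference (switches
are independent per interval — irrelevant to interval-by-interval counting
but wrong for joint multi-interval patterns), mutation, realistic
platform-specific error structure, and linkage disequilibrium among founder
haplotypes.  Passing tests on simulated data therefore validate the
book-keeping and the estimators, not the biology of interference or
genotyping chemistry.

## Reconstructed reference counts

The bundled tables report per-unit (N, θ) only; integer recombinant counts
are reconstructed as r = round(N·θ).  Every printed θ in the fine-interval
and family tables round-trips under this rule and group sums match the
published group rows exactly.  Exact halves (N·θ = x.5) are an error by
default; the one affected broad-interval cell (a female with N = 50,
θ = 0.190, where N is the genotyped-offspring count rather than the
interval-specific informative count) is resolved half-to-even by the
bundled loader and documented there.  Because informative n per broad
interval is not published, broad-interval statistics other than the
fully-informative *UMNP71–SW1943* column are approximate; their degrees of
freedom, which depend only on the count of informative females, reproduce
exactly.

## Problem sizes in the test suite

Deterministic reproductions run on the bundled tables (≤ 1028 meioses).
Stochastic checks use: 2000 replicates for type-I calibration (17 units,
real litter sizes), 100 simulated datasets (4 females × 25 offspring × 5
markers) for the counting oracle, 200 replicates of 500 meioses for
estimator bias, and 10⁴-meiosis runs for convergence and haplotype-effect
recovery — sizes at which binomial standard errors make the stated bounds
meaningful while the whole suite stays fast.

## Known limitations

* Strictly adjacent flanking markers define intervals; no multipoint or HMM
  rescue of partially missing flanks (missing flanks lower n, visible as a
  diagnostic).
* χ² calibration of the Morton test degrades for sparse units (above).
* Two-point maps ignore multipoint order likelihoods; marker order is an
  input, not an inference.
* The order-discordance scan is a single-chromosome monotone-run analysis,
  not a synteny-block algorithm.
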