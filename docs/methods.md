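# Methods

## Scope and data model

`cubkit` analyses sets of protein-coding nucleotide sequences (CDS). All
sequences are held internally in the RNA alphabet (U, not T) because codon
tables in this literature are conventionally printed as RNA triplets; DNA
FASTA input is converted on read. The standard nuclear genetic code is
assumed throughout. The unit of analysis is a single CDS; genome-level
statements are either arithmetic means of per-gene indices or statistics of
the pooled codon counts — both aggregations are exposed, and they are not
interchangeable (the RSCU of pooled counts is not the mean of per-gene
RSCU values; the pooled form is what published genome tables report).

## CDS screening

A sequence is kept only if it passes, in this fixed order: (1) length a
multiple of three; (2) length ≥ 300 nt counting start and stop; (3) only
A/C/G/U bases — ambiguity codes (N, R, Y, …) fail rather than being
resolved; (4) AUG start; (5) UAA/UAG/UGA terminal codon; (6) no in-frame
internal stop. The order is fixed so that the reported reason (the first
failing rule) is deterministic. The 300 nt threshold is interpreted as
including the start and stop codons; it is a parameter (`min_len`) for
users who read it otherwise.

## Synonymous family schemes

Two partitions of the 61 sense codons are provided. `standard` keeps
Leu/Ser/Arg as six-fold families. `split` divides each six-fold family
into its four-fold and two-fold codon boxes (Leu → CUN + UUR, Ser → UCN +
AGY, Arg → CGN + AGR). `split` is the default for RSCU and the ΔRSCU
screen: it is the convention under which published genome RSCU tables for
the bundled species are reproduced from their printed counts (e.g. CUU in
*A. capillus-veneris* is 1.502 under `split` but 1.474 under `standard`).
ENC always uses the standard Wright degeneracy classes (9 two-fold, 1
three-fold, 5 four-fold, 3 six-fold) regardless of the RSCU scheme.

## Index definitions and numerical choices

- **RSCU**: `x_j · n / Σ_k x_k` within the codon's family. A family with
  zero total usage yields missing values (NaN), never 0. Single-codon
  families (AUG, UGG) are 1 by definition.
- **ENC** (Wright): per amino acid with total count `n ≥ 2` and usage
  fractions `p_i`, homozygosity `F = (n Σp_i² − 1)/(n − 1)`; class means
  over amino acids of each degeneracy; `ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ +
  3/F̄₆`, capped at 61. Missing-class imputation: `F̄₃ ← (F̄₂+F̄₄)/2`,
  `F̄₆ ← F̄₄`; if the two- or four-fold class is itself empty the gene's
  ENC is reported missing. Amino acids observed fewer than twice are
  excluded from class means.
- **Silent-site composition** (A3s/T3s/C3s/G3s): numerator = synonymous
  codons ending in the base; denominator = synonymous codons whose family
  offers that base at the third position (the CodonW convention), so the
  four values need not sum to 1. GC3s is the plain G+C fraction over
  synonymous third positions.
- **CAI**: geometric mean (computed in log domain) of relative
  adaptiveness `w_j = x_ref,j / max_family(x_ref)` over synonymous codons.
  The reference set is not fixed by convention for non-model species; the
  default is the 10 % of genes with the lowest ENC in the same genome (the
  most biased genes, standing in for high expression), overridable by an
  explicit weight table. Codons unseen in the reference get the customary
  weight floor of 0.01 so the geometric mean stays defined.
- **CBI/Fop**: `Fop = N_opt/N_tot`; `CBI = (N_opt − N_rand)/(N_tot −
  N_rand)` with `N_rand` the optimal count expected under uniform usage.
  When no optimal set is supplied, codons with pooled RSCU > 1 are used.
- **Gravy/Aromo**: mean Kyte–Doolittle hydropathy and the Phe+Tyr+Trp
  fraction of the encoded protein, stop excluded.
- **PR2**: third positions of sense codons excluding AUG/UGG by default; a
  four-fold-family-only mode is provided (and is the one with an exact
  parity expectation under strand-symmetric mutation, since two-fold
  families offer only pyrimidines or only purines at the silent site).
- **Neutrality regression**: unweighted OLS of GC12 on GC3 with Pearson
  correlation and a two-sided p-value. The mutation share is reported as
  `|slope|·100 %`; the absolute value makes the share well-defined for
  (rare) negative slopes, which are flagged in the output.
- **ENC-ratio histogram**: `(ENC_exp − ENC_obs)/ENC_exp` binned into eight
  0.1-wide classes centred on −0.2 … 0.5; out-of-range genes are tallied in
  an overflow row, never dropped silently.
- **Correspondence analysis**: SVD of the standardised residuals
  `D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}` of the per-gene RSCU matrix (the
  raw-count alternative is accepted too). Principal coordinates; inertia
  share per axis = squared singular value over total inertia. Singular
  values below 1e−12 of the largest are treated as numerical rank
  deficiency and discarded. All-zero rows/columns are dropped with a
  warning.
- **ΔRSCU screen**: groups are the ENC deciles. Read literally, some
  descriptions assign the *highest*-ENC genes to the high-expression
  group; the package default follows the established extreme-ENC
  convention (lowest ENC = most biased = high expression proxy) and a
  `literal_groups` flag restores the inverted reading. The choice cannot
  affect pooled-count results. Optimal codons satisfy ΔRSCU ≥ 0.08
  (inclusive), RSCU > 1 in the high group, and genome RSCU > 1. Ties at
  the decile cutoff are broken by gene id, so the screen is deterministic
  under reordering.
- **Species comparison**: frequencies per 1000 codons (the Kazusa native
  unit); codons with ratio ≥ 2 or ≤ 0.5 (inclusive) are flagged; the
  similarity verdict counts flags among the 59 synonymous codons only.
  Stop codons are excluded; AUG/UGG appear in the table but not in the
  verdict.

## The synthetic genome generator

The generator emulates exactly the features the statistics above measure:
genes are independent; codons within a gene are drawn i.i.d. (an amino
acid from a composition vector, then a codon from that amino acid's
preference vector), with an AUG start, a sampled stop and no internal
stops, so generated genes always pass the screen. Controls and their
defaults:

- gene count and length (default 200 genes of 100–500 codons — enough for
  stable pooled RSCU while keeping the test suite fast);
- a scalar `bias` in [0, 1] interpolating uniform usage (ENC → 61) to one
  codon per family (ENC = 20);
- `target_gc3`, enforced by tilting third-position base odds within each
  family; the tilt is calibrated by root finding on the exact expected
  GC3, so the realised value differs from the target only by sampling
  error (and the fixed AUG start, ~1/L per gene);
- a two-strata design for the ΔRSCU screen, built as a model of
  translational selection: one designated optimal codon per split-scheme
  subfamily is mildly enriched genome-wide (weight 1.6) and strongly
  enriched (weight 8) in a 10 % high-expression stratum. The margins this
  creates — every codon's RSCU well away from 1 and from the 0.08
  threshold, and stratum ENC ≈ 25 units below the bulk — make the planted
  codon set and the stratum membership recoverable essentially surely,
  not just on a lucky seed;
- a mutational gradient sweeping per-gene GC3 targets across a range
  while the amino-acid composition interpolates between AU-rich and
  GC-rich endpoints, so expected GC12 co-varies with expected GC3. The
  truth record stores each gene's exact codon distribution and expected
  GC fractions; the "generating slope" for neutrality-recovery checks is
  the regression on those noise-free expectations.

Because codons are site-independent, the generator does not reproduce
codon-pair or dinucleotide structure, amino-acid autocorrelation along
proteins, isochore-scale GC heterogeneity within genes, or any coupling
between expression and gene length. Passing tests therefore demonstrate
the correctness of the statistics and the recoverability of planted
single-codon structure — not that real genomes satisfy the generator's
independence assumptions.

## Problem sizes in the test suite

Stochastic checks run on seeded genomes of 100–500 genes (200–500 codons
each); the unbiased-screen null check uses 120 genes of 15 000 codons,
since the empty-optimal-set property is asymptotic in gene length (group
RSCU sampling noise must fall well below the 0.08 threshold). All seeds
are fixed and stated in the tests.

## Known limitations

- Only the standard nuclear genetic code is supported.
- The CAI reference set heuristic (lowest-ENC decile) is a proxy; with a
  curated highly expressed gene set, supply explicit weights.
- The mutation/selection "shares" from the neutrality slope are the
  field's conventional heuristic, not a statistical decomposition; no
  model comparison is attempted.
- The bundled four-genome table contains pooled counts only, so per-gene
  statistics (ENC distributions, neutrality slopes, CoA) cannot be
  recomputed for those genomes without the original assemblies; they are
  exercised on synthetic data instead.
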