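# Methods

This note records the models, conventions and numerical choices behind
tsrnakit, and what the synthetic-data validation does and does not show.

## Reference model

A tRNA gene record carries the genomic body (no CCA), an optional intron
(1-based inclusive interval strictly inside the body), 5' leader and 3'
trailer flanks, and the annotated anticodon position *in the spliced
body*.  Maturation is modeled as intron splicing followed by 3' CCA
addition; the precursor is leader | unspliced body | trailer.  The
anticodon position comes from annotation (as GtRNAdb-style sidecar files
provide it), not from structure prediction — nothing downstream folds
tRNAs.  All coordinates in the package are 1-based inclusive; sequences
are held as DNA and any U in inputs is mapped to T on read.  Histidine
G−1 addition is not modeled: position 1 of a His mature tRNA is its first
annotated nucleotide, the simplest convention consistent with published
fragment IDs that start His fragments at position 1.  Mature sequences
include the CCA, so a 3' fragment's end coordinate equals the CCA-included
mature length — the convention that published 3'-fragment coordinates
(…:75, …:76, …:86) imply.

## Subtype classification

Fragments are 14–40 nt.  The literature gives only coarse bands (tRFs
14–30 nt, halves 31–40 nt) that published tables themselves stretch
(31–32-nt fragments labeled tRF-5c), so the classifier uses the minimal
contiguous partition consistent with every published row we bundle:

* 5' fragments (start = 1): 14–16 tRF-5a, 17–24 tRF-5b, 25–32 tRF-5c,
  33–40 tiRNA-5;
* 3' fragments (end = mature length): 14–20 tRF-3a, 21–30 tRF-3b,
  31–40 tiRNA-3;
* precursor trailer → tRF-1; precursor leader or internal → tRF-other.

The tiRNA-5 call is by length band only; the classifier does not require
the 3' end to sit at the anticodon boundary.  The simulator *does* place
halves at the anticodon loop, so the annotation is used for realism of
generated data rather than as a classification constraint.

## Trimming, placement, naming

The 3' adapter is located as the leftmost exact occurrence of its first
8 bases (configurable adapter, minimum 6 nt); the read prefix before it
is the insert.  Reads without an adapter hit, or with inserts outside
14–40 nt, are rejected with logged reasons.  Placement is an exhaustive
scan of every offset of every mature tRNA: 0-mismatch hits beat
1-mismatch hits; reads unplaced on matures fall through to precursors
under the same tiering.  This mirrors the common two-pass mapping scheme
and is deterministic.  All best-tier hits are kept: hits across
isodecoders of one family at identical coordinates merge into one species
named `-Mn` with n the number of distinct supporting genes (ordered by
amino acid, anticodon, then numeric isodecoder index; the smallest gene
lends its index to the name).  Reads whose best-tier hits disagree on
coordinates, or span more than one anticodon family, are discarded with a
logged count — the conservative choice for ambiguous multi-mappers.  A
species' canonical sequence is the reference substring of its lead gene,
so 1-mismatch (error) reads aggregate into the species they came from.

The aligner is intentionally exhaustive rather than indexed: tRNA
reference sets are hundreds of sequences of ~70–110 nt, where an exact
O(genes × length) numpy scan per unique insert is faster to verify and
fast enough (unique inserts are deduplicated before alignment).  Indels
and modification-aware alignment are out of scope.

## Quantification and differential expression

Counts are normalized as counts per million of each sample's total
aligned tRNA reads.  A species is *expressed* in a group when its group
mean CPM is at least 20 (inclusive), giving the common / control-only /
treatment-only Venn partition.

The DE test is a simplified DESeq2-style analysis, reimplemented rather
than wrapped so its behaviour is fully specified here:

* **Size factors** — median over species positive in every sample of
  counts/geometric-mean (library-size ratios as fallback, with warning).
* **Dispersion** — per-species method of moments on normalized counts,
  φ̂ = (s²_within − μ)/μ², clipped to [0, 10], then shrunk toward a
  parametric trend φ(μ) = a/μ + b fitted by least squares, with weight
  w = d/(d + 2) on the per-species estimate (d = n₁+n₂−2 residual df).
* **Effect and test** — log₂FC of normalized group means with pseudocount
  0.5 (bounded fold changes for group-specific species); the Wald
  statistic uses the delta-method standard error from NB variances and is
  referred to a t distribution with n₁+n₂−2 df.  The t reference and the
  light shrinkage were chosen so that at n = 5 per group the null type-I
  error is close to nominal (≈ 0.04 at α = 0.05 in the bundled
  simulations) — a plain normal reference is anticonservative and heavy
  shrinkage overcorrects.
* **Screening** — |log₂FC| > 1.5 and p < 0.05, both strict; the raw p is
  thresholded by default (the adjusted p can be selected), and padj is
  Benjamini–Hochberg over tested species.  All-zero species are excluded
  from testing and reported NS with p = 1.

Not implemented (and explicitly out of scope): Cox–Reid dispersion
adjustment, dispersion-trend GLM fitting, Cook's-distance outlier
handling and independent filtering.  Exact numeric parity with DESeq2 is
not claimed; an independent per-species NB GLM (statsmodels) is used in
the test suite to confirm agreement on strong effects.

The qPCR helper returns 2^−ΔΔCt for a target against a reference gene
(e.g. RNU6) and a control condition.

## Target prediction and enrichment

The seed is nucleotides 2–7 of the fragment (5'→3'); fragments shorter
than 8 nt have no seed and are skipped.  The seed-match scanner finds
every reverse-complement occurrence of the seed in a UTR and types it:
pairing of tsRNA position 8 one base 5' of the core gives 7mer-m8, an A
opposite position 1 (one base 3' of the core, required to be A regardless
of pairing) gives 7mer-A1, both give 8mer.

The duplex score is a local affine-gap alignment of the tsRNA against the
reversed UTR window (both strands then advance 5'→3', antiparallel):
+5 Watson–Crick, +1 G:U wobble, −3 mismatch, −8 gap open, −2 gap extend,
and all pair/mismatch scores at tsRNA positions 2–8 doubled.  A gene is
duplex-predicted when any 40-nt window (step 20) reaches the threshold,
default 80 — calibrated so a perfect 14-mer duplex (score 105) passes
while seed-only pairing (≈ 60) does not.  The seed weighting makes the
score deliberately asymmetric in its arguments; without it the score is
symmetric under swapping the two strands' roles, which the test suite
checks.  Free-energy models are not used: no energy parameters are
published for this screening step, and the score threshold plays that
role.  The final target set is the intersection of the seed-match and
duplex predictions — consensus reduces false positives at the cost of
recall.

Enrichment is the one-sided hypergeometric tail P(X ≥ k) for a query of
n genes overlapping a K-gene term in a universe of N (default universe:
all genes of the supplied UTR database), BH-corrected across terms.
Reproducing any particular published genome-wide target count would
require the exact external tool versions and UTR build and is explicitly
not a goal; the contract here is algorithmic correctness against
enumeration and brute-force oracles.

## Synthetic data

The generator emulates a two-condition small-RNA study at the level the
pipeline consumes:

* **Reference** — n families (default 15) drawn from a pool of real
  amino-acid/anticodon pairs; per family a random 70–74-nt body with the
  anticodon at positions 32–36, and isodecoders as 2–5 point mutations of
  the family consensus (occasionally a 10-nt intron after the anticodon);
  20-nt leaders and 25-nt trailers.
* **Species** — all feasible placements per subtype are enumerated
  (5'/3' length bands, halves cut at the anticodon loop, tRF-1 starting
  immediately after the body in the trailer), each validated by the
  *production* trim/align/name path: a fragment is kept only if it trims
  intact and maps back to exactly its intended placement, unambiguously.
  Duplicate fragments across isodecoders collapse into one multi-gene
  species.  Subtype counts are multinomial over the configured mix
  (default: 5' > 3' species, one-quarter tiRNA-5, small tRF-1 class — the
  shape of sperm tsRNA profiles), and species are drawn without
  replacement from each pool; a mix the reference cannot host raises a
  config error.
* **Counts** — abundances are a normalized log-normal composition;
  expected counts are depth × abundance with planted log₂FC split
  symmetrically between groups (default depth 10⁵ aligned reads/sample,
  5 samples/group — group size is a simulation choice, not a published
  value); counts are negative binomial with var = μ + φμ² (default
  φ = 0.1), Poisson in the φ → 0 limit.
* **Reads** — insert + 3' adapter, truncated/padded to 50 bp (single-end,
  the platform convention), uniform-random pad bases (so trimming cannot
  exploit pad content), substitution errors at the configured rate
  (default 10⁻³) on the insert+adapter portion, constant 'I' qualities.

Because species are closure-validated at generation time, an error-free
run of the full pipeline recovers the manifest exactly — the end-to-end
test asserts byte-level count equality.  What passing these tests does
*not* show: robustness to quality-dependent errors, PCR duplication,
ligation bias, RNA-modification read-through, indels, or reference
incompleteness — none of which the generator models.  Real libraries will
also contain non-tRNA reads; here every read is tRNA-derived, so the
aligned-fraction statistics of real data are not emulated.

## Determinism and problem sizes

Every stochastic component takes a numpy `Generator` or integer seed;
identical configurations produce byte-identical outputs (the pipeline
re-run test asserts this).  The bundled simulations use problem sizes
chosen to keep the full suite fast while leaving the statistical checks
well-powered: 2 000 null species for calibration, 20 replicate seeds of a
300-species study for planted-effect recovery, 500 random inserts for the
aligner oracle, ≤ 40-nt windows for the duplex DP oracle, and a
100-species error-free study for closure.

## Known limitations

* The classifier's sub-bin boundaries are a reconstruction from published
  rows, not a community standard; other pipelines draw the 5' sub-bins
  slightly differently.
* Multi-family ambiguous reads are dropped rather than fractionally
  assigned; profiles of families with near-identical sequences are
  therefore conservative.
* The DE model tests one two-level factor only (no covariates, no GLM
  design matrix).
* Duplex scoring constants are miRanda-flavored but not calibrated
  against experimental binding data; the threshold is a screening device.
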