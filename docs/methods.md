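# Methods

This note documents the models, defaults and numerical choices behind
`dikarase`, and what the synthetic-data generator does and does not
emulate.

## The biological setting and the model

A dikaryotic mycelium carries two haploid nuclei; each contributes one
allele of every gene to a shared transcript pool.  For a gene whose two
alleles differ at one or more transcribed SNPs, an RNA-seq read that
covers such a locus can be attributed to its allele of origin.  We model
the allele of origin of each read as Bernoulli(π), where π is the latent
probability that a transcript originates from the haplotype-1 allele.
Balanced expression means π = 0.5; allelic expression bias means π ≠ 0.5
sustained across growth conditions.  The observable is the read-count
ratio r = n₁/(n₁+n₂) at distinguishing loci, an estimate of π.

### Bias testing

Per condition and gene we use the exact two-sided binomial test of
H₀: π = 0.5 (the two-sided p sums all outcome probabilities not exceeding
that of the observed count), Benjamini–Hochberg adjusted across genes
within each condition.  The exact test was chosen over a normal
approximation because clone counts and low-depth genes are small-sample;
at high depth the two coincide.  A gene is called *consistently biased*
when one direction achieves q < α (default α = 0.05) in at least a
fraction f (default 0.9) of its informative conditions, with a minimum
of two informative conditions.  f = 0.9 was chosen so that a single
discordant condition out of ~19 (the xylan-like case in the default
design) does not veto an otherwise uniform pattern, while any alternating
pattern fails.

**Aggregation caveat.**  Allele counts are summed over a gene's SNP loci
(default).  Loci of one gene share reads — a read spanning two loci
contributes to both — so the summed counts are positively correlated and
the nominal binomial n overstates the number of independent fragments.
The ratio estimate is unbiased, but p-values at very high depth are
mildly anti-conservative.  A `mean_ratio` aggregation mode is provided
for sensitivity analysis.  An overdispersed (beta-binomial) model is out
of scope.

### Clone validation

Clone-sequencing experiments (n clones Sanger-sequenced, k matching one
allele) are validated with the same exact binomial test plus a
Clopper–Pearson 95% interval.  `required_clone_count(π, α, power)`
computes, by exact enumeration of the rejection region for each n, the
smallest clone count at which the test attains the requested power; it
makes explicit that a ~0.6 bias requires on the order of a hundred
clones, so clone counts of a few dozen are qualitative support only.

## Allelic pairing

Protein pairs are aligned globally (Needleman–Wunsch with affine gaps;
BLOSUM62, gap open 10, extend 1, where the open score covers the first
gap position).  Percent identity uses the full alignment length,
including gap columns, as its denominator (BLAST-like; this choice is
configurable because identity denominators are not standardized).
Pairing is by reciprocal best raw score with ties broken toward the
lexicographically smaller id, filtered at ≥95% identity; output is
deterministic under any input ordering.  Duplication grouping applies
single-linkage closure over pairs satisfying both criteria — coverage of
the longer protein ≥75% by both-residue columns, similarity ≥90% —
where "similarity" defaults to percent identity, with a
substitution-matrix-positive definition behind a flag.

Sisterhood of allele pairs is checked on a neighbor-joining tree built
from p-distances (1 − identity fraction).  The NJ agglomeration is the
standard Saitou–Nei procedure with deterministic tie-breaking; on
additive matrices it reproduces path lengths exactly, which the tests
verify, and branch lengths are reported unclamped.

## Variant calling

Allelic sequences are aligned globally (match +2, mismatch −3, gap open
5, extend 2; configurable) and variants are read off the columns:
mismatches as single-base SNPs (a multi-base substitution is counted as
N per-column SNPs, not one MNP), and maximal gap runs as single
insertion/deletion events.  Indels are left-aligned to the VCF
convention, so representations inside homopolymers are unique; the
round-trip invariant — applying the calls to haplotype 1 reconstructs
haplotype 2 byte-exactly — holds for every call set and is enforced in
tests.  Positions are reported on haplotype-1 coordinates; an
indel-aware coordinate map carries positions onto haplotype 2.  Coding
effects are annotated per SNP against the reference codon (strand
aware), and amino-acid changes are flagged when they fall inside
supplied domain intervals.

The gene region partition assigns every base exactly one label.  The
promoter is defined, as in the study design, as the 3 kb upstream of the
start codon — an interval that necessarily contains the 5′UTR — so
transcribed labels take precedence and the `promoter` label covers only
the non-transcribed upstream part.

## Promoter motif analysis

JASPAR matrices (bracketed or bare-whitespace dialect) are converted to
log₂-odds PWMs with a total pseudocount of 0.8 distributed by the
background (uniform by default; promoter-composition background behind a
flag).  Every window on both strands is scored; hits are kept at
relative score (score − min)/(max − min) ≥ 0.85, a CiiiDER-style deficit
of 0.15.  An `N` base contributes log-odds 0 (background probability) by
default, or the window can be skipped.  Differential sites between the
two allele promoters are found by pairing hits of the same motif and
strand through the indel-aware coordinate map built from the promoter
variant list: unpaired hits are gained/lost, paired hits with a relative
score difference ≥0.1 are score-shifted, and each site is annotated with
the overlapping variants.  Note that near-consensus windows can occur by
chance in 3 kb of promoter; they surface in the differential list only
when a variant actually breaks them on one allele, which is precisely
the phenomenon of interest.

## The synthetic-data generator

The generator is first-class, tested code.  It emulates the study
conditions:

- **Genomes.**  15 gene families (default), one per contig, with
  realistic architecture: CDS of 900–1998 bp split by 1–12 introns of
  50–120 bp, 150/200 bp UTRs, a full 3 kb promoter, genes alternating
  between strands.  Coordinates are 0-based half-open internally; GFF3
  output is 1-based inclusive.
- **Divergence.**  Haplotype 2 is derived from haplotype 1 by per-site
  Bernoulli substitutions at 0.005 in coding and 0.015 in non-coding
  sequence (the higher non-coding rate is a property of the system the
  package targets), with the alternative base uniform over the three
  non-reference bases.  Indels (rate 5e-4 per non-coding site, lengths
  1–10) are placed only in non-coding regions, since coding indels would
  frameshift and inter-allele coding variation is essentially SNPs.  A
  candidate indel that would cross a region boundary or fall within
  10 bp of an accepted variant is re-drawn, so every truth variant has a
  unique left-normalized representation.  Exonic substitutions preserve
  each codon's stop status (purifying selection against nonsense
  alleles; the alternative base is re-chosen, and joint same-codon
  effects are post-checked), so both allele proteomes translate cleanly.
- **Reads.**  Single-end 150 bp reads per gene × condition, Poisson
  count with mean `depth_per_gene` (default 800), start uniform on the
  mature transcript, allele of origin Bernoulli(π), i.i.d. substitution
  errors at `seq_error_rate` (default 0).  The paper-scale design needs
  ≥500 informative (SNP-covering) reads per gene and condition for the
  cross-condition recovery property; 800 total reads yields that for
  typical transcripts.  No depth is stated by the source study; this
  default is ours.  Fragment-size and quality models, paired-end
  orientation and RNA structure are deliberately not modeled.
- **Bias.**  By default one family (index 6) carries π = 0.626 — the
  average bias the design targets — on every condition except XM, where
  it reverts to 0.5; all other genes are balanced.  Any per-gene,
  per-condition map can be supplied.
- **Clones and qPCR.**  Clone draws are Binomial(n, π).  qPCR plates
  follow Ct = base − log(template)/log(1+E): with E = 1 a twofold
  dilution step shifts Ct by exactly one cycle; Gaussian Ct noise is
  optional.  Analysis-side, efficiency is estimated by OLS of Ct on
  log₁₀(concentration) and relative expression by 2^(−ΔΔCt).
- **Motifs.**  A planted consensus site is written into the haplotype-1
  promoter *before* divergence and the window is protected from
  mutations, so both alleles inherit it identically and the ground-truth
  round trip stays exact; the disruption (the single-base change that
  destroys the most PWM score, deterministic under ties) is then applied
  to one allele and recorded as a regular truth SNP.  The bundled
  demonstration matrix `ZNF_SYN1` is synthetic — its counts are invented,
  with five highly informative columns so that one disrupted base drops
  a site below the 0.85 threshold — and is not taken from any database.

Identical configuration (including the seed) produces byte-identical
FASTA/GFF3/FASTQ/TSV output; the pipeline run is deterministic end to
end.

**What passing tests do and do not show.**  The generator's reads are
error-free by default and place exactly on transcripts, so read
assignment is tested under ideal mapping; real data add mapping bias
toward the reference allele, sequencing error, and unannotated
transcript structure, none of which are claimed to be handled.  The
statistical properties verified (test calibration, interval coverage,
parameter recovery) are properties of the inference machinery, not
guarantees about any particular organism's data.

## Numerical choices

- Exact binomial p-values come from point-mass summation semantics; the
  test suite verifies agreement with a direct enumeration oracle for all
  (k, n ≤ 60).
- The type-I calibration check samples 1,000 null genes by stratified
  sampling over the Binomial(200, 0.5) quantiles: each gene's count has
  the exact null marginal while the Monte-Carlo error of the estimated
  rejection fraction drops well below the width of the calibration band.
- NJ joins pick the minimum-Q pair with the smallest index pair on ties;
  alignment ties are resolved by Biopython's leftmost traceback, which
  does not affect any reported statistic.
- Division-by-zero cases (zero-depth genes, zero-variance expression
  profiles, empty samples) are flagged and excluded rather than imputed;
  truncated promoters are returned shorter with a warning.

## Known limitations

- No mapping-bias correction (WASP-style) and no overdispersion model;
  see the aggregation caveat above.
- The DEG rule is applied to supplied fold changes and p-values (or a
  plain mean-TPM log₂FC with pseudocount 1); no negative-binomial DE
  model is included.
- Duplication grouping uses single-linkage closure, so a chain of
  borderline pairs can merge groups whose extreme members fall below the
  pairwise thresholds.
- The VCF writer emits the minimal v4.2 subset (anchored indels, INFO
  region/effect tags) sufficient for downstream text processing, not a
  full-featured VCF implementation.
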