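# Methods

`patseq` implements a complete 3′-end sequencing analysis for poly(A)-tag
(PAT-Seq) data: from oligo-dT-primed reads to poly(A)-site clusters (PACs),
differential expression at gene and PAC level, poly(A)-site switching calls,
and nucleotide-composition profiles around cleavage sites. This note records
the model behind each stage, the defaults and why, the numerical choices made
where the method description leaves room, and what the synthetic validation
data do and do not establish.

## Coordinate conventions

A *cleavage position* is the 0-based genomic coordinate of the last
transcribed base before the poly(A) tail. On the + strand this is the
3′-most aligned base of a tag; on the − strand it is the lowest genomic
coordinate of the alignment, with the transcript running toward lower
coordinates. BED output/input uses 0-based half-open single-base intervals
at this position; GFF3 input is converted from 1-based inclusive to 0-based
half-open on load and all internal intervals are half-open.

## Read preprocessing

Reads are quality-filtered with FASTX `-q/-p` semantics: a read survives iff
at least `min_percent_at_quality` (default 50) percent of its bases have
Phred quality ≥ `min_quality` (default 10), boundary inclusive. The leading
poly(T) run left by the oligo-dT primer is then trimmed; one non-T base is
tolerated after 10 consecutive T (the anchored primer base) provided the run
continues. Reads whose leading run is shorter than `min_polyt_run`
(default 8 nt) carry no oligo-dT evidence and are discarded; trimmed tags
shorter than `min_trimmed_length` (default 20 nt) are discarded. The minimum
poly(T) run is a package choice — the upstream method does not state one —
and is exposed in `PreprocessConfig`.

Mapping is by exact substring search against the genome in both
orientations, using a 20-mer seed index with full-length verification. A tag
whose reverse complement occurs exactly once on the forward genome is a
+ strand tag (cleavage at the match's 3′-most base); a tag occurring
directly is a − strand tag (cleavage at the match start). Zero hits is
unmapped, more than one is a multi-mapper; both are discarded and counted.
This exact matcher is intended for the package's toy-scale genomes
(≤ ~5 Mb); real datasets enter through BED import of externally aligned tag
3′ ends.

## PAS and PAC construction

Tags at identical (chromosome, strand, position) form one poly(A) site
(PAS) with per-sample counts. Internal-priming artifacts — oligo-dT
annealing to genomic A stretches rather than a tail — are removed at the
PAS level: a PAS is discarded iff the 10 nt of transcript-strand sequence
immediately downstream of its cleavage position contain ≥ 7 adenosines or a
run of ≥ 6 consecutive adenosines. These window parameters are the
field-standard heuristic (the upstream description cites the procedure
without values) and are exposed in `PacParams`. Bases beyond the chromosome
end count as non-A.

Surviving PAS are single-linkage clustered per chromosome strand:
consecutive PAS whose positional gap is ≤ 24 nt (inclusive — "within 24 nt"
is read inclusively) chain into one PAC. Whether the 24-nt rule means
consecutive-gap chaining or a fixed window is not specified upstream;
chaining is implemented and is what the clustering oracle in the test suite
checks (it equals all-pairs transitive closure). PACs supported by fewer
than 10 reads summed over all samples are discarded (a PAC totalling
exactly 10 is retained). Each PAC is represented by its most abundant
member PAS; ties break to the 3′-most position in transcription direction,
a deterministic rule chosen here since the upstream description is silent.

## Annotation

Every annotated 3′UTR is extended by 120 nt in the transcription direction
before assignment, truncated where the extension would enter the next
same-strand gene (important in compact toy genomes). Each PAC is assigned
at its representative position with precedence
extended-3′UTR > CDS > 5′UTR > intron; positions hitting no gene footprint
are intergenic. When extended footprints of several genes cover the
position, the gene with the nearest 3′ end wins. Precedence and tie-break
are package-documented deterministic rules. Gene-level counts sum the PAC
counts per gene; intergenic PACs are excluded from the gene matrix and
reported separately, so the conservation identity
`gene matrix + intergenic = PAC totals` holds exactly.

## Differential expression

Size factors are median-of-ratios: factor_j = median over features (nonzero
in every sample) of count_ij divided by the feature's geometric mean, then
rescaled to geometric mean 1. The negative-binomial model is
`var = μ + α·μ²`. The differential test is an in-package re-implementation
of the normalize-and-Wald-test approach; exact DESeq2 numerics are not a
goal — threshold behaviour and simulation calibration are.

Per-feature dispersion is estimated by the method of moments on the pooled
within-group variance of normalized counts, then shrunk 50/50 toward a
global target, with two numerical corrections that matter at 3-vs-3:

* the raw median of the moment estimates under-estimates a common
  dispersion (the pooled variance is approximately chi²_df-distributed), so
  the target is the median divided by `chi2.median(df)/df`;
* the shrunk estimate is floored at the target, so a feature whose own
  dispersion is under-estimated by chance cannot inflate its Wald statistic
  — the dominant small-sample failure mode of the plain moment estimator.

With these corrections the null raw-p fraction below 0.05 sits at
0.036–0.049 across seeds (3v3, 2,000 features, α = 0.1 dispersion) with no
Benjamini–Hochberg calls at padj < 0.01, while a planted 8-fold change at
mean 200 is always called. Without them the test is visibly
anti-conservative in the far tail.

The Wald statistic is the log2 fold change of group means over a
delta-method standard error, `var(log2 μ̂) ≈ (1/μ + α)/(n·ln²2)` per group,
with a 0.5 pseudocount inside the log2 and normal reference distribution.
Features whose mean normalized count falls below 1 are excluded from
testing (independent filtering) and flagged. BH correction runs over tested
features; genes use padj < 0.01, PACs padj < 0.05 by default, both
configurable. One-vs-one comparisons cannot support dispersion estimation
and fall back to a two-sided exact binomial test on the pooled per-feature
proportion (documented lower power). Gene-set enrichment is a one-sided
hypergeometric over-representation test with BH across sets (FDR < 0.05
default); gene sets are user-supplied.

## Switching detection

For each gene with ≥ 2 PACs, every unordered PAC pair (PA1, PA2) is tested
against five criteria; all must hold: (1) one of PA1/PA2 has ≥ 5 reads in
each of the two samples; (2) one of PA1/PA2 has ≥ 20 reads totalled across
all samples; (3) PA1/PA2 ≥ 2 in one sample and PA2/PA1 ≥ 2 in the other;
(4) |PA1 − PA2| > 5 (strictly — criterion 4 is printed as a strict
inequality, unlike the ≥ of 1–3) in both samples; (5) at least one of the
pair is a significant DE-PAC in the same comparison (optional, on by
default). Interpretive choices, each exposed as a parameter:

* "sample" means the replicate-summed count of one side of the comparison
  (conditions are compared, not single libraries); a per-replicate mode
  requires criteria 1/3/4 to hold in every replicate pairing;
* criterion 2's "across all samples" sums over every sample group in the
  dataset (`total_pair_only` restricts it to the pair);
* zero-count ratios: x/0 counts as infinite for x > 0; 0/0 fails;
* criterion 4's "each sample in which switching occurred" is implemented as
  both samples of the evaluated pair.

The shift direction (proximal→distal or distal→proximal) is derived from
the representative positions, the strand, and the change in the proximal
site's usage share. A gene is switching if any pair passes.

## Composition profiles

For each PAC (optionally restricted by region label) the transcript-strand
sequence covering relative positions −300..+99 — 400 nt, cleavage base at
index 0, reverse-complemented for − strand PACs — is extracted; positions
off the chromosome are masked and excluded from denominators, not
zero-filled. Per-position A/C/G/T fractions are reported long-form with the
number of covering sites. Whether the upstream "−300 to 100" window
includes position +100 is not stated; a 400-nt window ending at +99 is
used and documented. De-novo motif discovery is out of scope; composition
profiles are the in-package analogue.

## Synthetic data generator

The generator is first-class, tested code and defines the validation
conditions. It emulates: multi-gene toy genomes (fixed 1,600-nt loci:
200 nt flank, 100 nt 5′UTR, 600 nt CDS, 200 nt 3′UTR, 500 nt flank;
alternating strands over 2 chromosomes); 1–3 poly(A) sites per gene placed
in 3′UTR/CDS/downstream-intergenic space with mix (0.8, 0.1, 0.1) and ≥ 50 nt
separation; per-gene NB(μ = 200, α = 0.1) expression over 2 conditions × 3
replicates; Dirichlet site usage (concentration 5) shared across conditions
for non-switching genes; 10 switching genes with the deterministic usage
flip 0.8/0.2 ↔ 0.2/0.8 on two 3′UTR sites 150 nt apart; N(0, 2) rounded
cleavage jitter; an AATAAA element planted at −30..−25 upstream of every
3′UTR site so profiles have recoverable structure; 10-nt A tracts planted
in half the gene bodies as internal-priming decoys, with a configurable
fraction of tags re-assigned to them (cleavage immediately 5′ of the
tract); and oligo-dT-primed read structure (poly(T) prefix of 10–16 nt plus
the reverse-complemented upstream context, Phred+33, with configurable
no-oligo-dT and low-quality fractions to exercise the discard rules).

Deliberate idealizations, and hence what passing tests do *not* show about
real data:

* the background sequence caps A/T homopolymers at 4 nt and the planted
  decoys are the only ≥ 8-nt transcript-strand A tracts, so the
  internal-priming filter's measured operating point (recall ~1.0, true-tag
  loss ~0) reflects rule correctness, not performance on a real A-rich
  genome where true sites sit in A-rich context;
* the three transcript bases at offsets −2..0 of every planted site are
  never A and the ~50 nt around each site are A-depleted, which removes
  poly(A)-tail/template ambiguity so that a mapped tag 3′ end identifies
  its site exactly; real 3′ ends cleaved at CA dinucleotides carry an
  irreducible ±1-nt ambiguity the toy does not model;
* no sequencing errors, PCR duplicates, barcode demultiplexing, introns, or
  overlapping genes; the exact mapper would be brittle to all of these.

Tag-length distribution after fragmentation is not specified upstream; the
poly(T)/read-length split is a parameter rather than a fixed value.

## Problem sizes and runtime

Validation runs use 200 genes (~240,000 tags) for parameter recovery,
10 × 2,000-feature null matrices for calibration, and a ~20,000-tag FASTQ
run (NB mean 17) for the end-to-end determinism check — sizes chosen so the
whole suite and the acceptance script each complete in well under a minute
on one CPU while keeping binomial/recovery tolerances tight.

## Known limitations

No gapped or mismatch-tolerant alignment (import BED for real data); no
isoform-aware annotation or antisense PAC classes; no LFC shrinkage,
Cook's-distance outlier handling, or multi-factor designs in the DE module;
no continuous switching scores or global 3′UTR-length indices; intergenic
PACs never enter gene-level counting (reported separately).
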