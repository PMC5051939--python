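# Methods

## The model

remapq treats read mapping as a Bayesian model-selection problem over the
candidate set *A* of all loci an aligner reports for one read.  For
candidate *i* with alignment length *L_i* (expanded positions excluding
reference skips and padding) the posterior is

    Pr(map_i | A) = L_i · 10^{ll_i} / Σ_k L_k · 10^{ll_k}

The locus prior Pr(loc_i) = L_i / L_G is proportional to alignment length;
the effective genome size L_G cancels in the ratio and never enters the
computation.  The log10 likelihood ll_i sums per-position terms over the
expanded alignment:

| status      | contribution                  |
|-------------|-------------------------------|
| match       | lg(1 − 10^(−Q/10))            |
| mismatch    | −Q/10                         |
| gap open    | −Q/10 − γ_o                   |
| gap extend  | −Q/10 − γ_e                   |
| soft clip   | −Q/10 − γ_s                   |
| hard clip   | −Q̂/10 − γ_h                  |
| N / P       | 0 (ignored)                   |

Q̂ is the estimated quality of the unobserved hard-clipped bases: the mean
of up to `clip_window` (default 5) observed bases adjacent to each clipped
end.  Deletion positions have no read base; their quality is synthesised as
the mean of the two flanking read-base qualities (one flank at an
alignment end), which keeps the sum total over all positions.

Reported mapQ is the phred-scaled error probability of the mapping,
`round(−10·lg(1 − posterior))`, rounded half-up and capped at `mapq_cap`
(default 250; SAM reserves 255 for "unavailable").

### Paired ends

Mate likelihoods are computed independently; the pair posterior is
proportional to `L_fwd·L_rev·10^{ll_fwd+ll_rev}·Pr_pair(d)`, where *d* is
the outer mate distance (TLEN convention: rightmost end − leftmost start).
Pr_pair is the Gaussian density φ(d; μ, σ²) when the fragment-size model is
reliable — estimated from fragments whose mates each map uniquely, with
reliability requiring at least `min_frag_n` (default 1000) observations,
σ > 0 and σ/μ < 2 — and a constant otherwise (the constant cancels within
a group; its value is immaterial).  A candidate whose mate has no
alignment at its locus is paired with a pseudo-mate whose every base is
soft-clipped (using the unmapped mate's own qualities when its record is
present, else the mapped mate's length and mean quality) and scored with
the constant density in the same normalisation pool, so orphan placements
compete with, but do not systematically dominate, concordant ones.

### Known variants

With a VCF loaded, an apparent mismatch whose read base equals a known
alternate allele is scored both as a sequencing error (plain term) and as
a correctly-sequenced polymorphism, `lg(1 − 10^(−Q/10)) − γ`, and the
larger contribution is kept per variant, independently.  γ is γ_v/γ_g/γ_b
by variant class (SNV/indel/MNP), replaced by −lg(AF_alt) when the allele
frequency is available.  MNPs are matched as whole blocks; indels must
match the left-aligned position and the inserted/deleted sequence, and
replace the whole run's gap penalties with a single γ while keeping the
per-base quality factors.  Note the alternative reading in which the
variant term keeps the mismatch error factor (−Q/10 − γ) can never beat
the plain term for point variants, making variant awareness vacuous; a
`strict_literal` flag implements that reading for comparison, but the
default is the non-vacuous form, consistent with variant input measurably
improving precision.  Positions already re-scored by one variant are not
re-scored by another (deterministic order: position, kind, allele).

### Insert-range trimming (1DP)

For aligners without local-alignment support, non-genomic read parts
(adapters, barcodes, splice overhangs) inflate the alignment.  The true
insert is re-estimated as the contiguous range of expanded positions
maximising Σ A_i with A_i = a_m for matches (default +1), a_x for
mismatches (default −2, the common 1:2 local-alignment ratio), −γ for
gaps/clips, and 0 for N/P (so ranges may bridge introns).  The optimum is
found by the linear recurrence `S(i) = max(S(i−1) + A_i, 0)` with
traceback; ties resolve leftmost-then-longest; an all-negative profile
yields the empty range and the record is flagged unmapped.  Trimming
soft-clips read bases outside the range, drops outside reference-consuming
positions (advancing the start coordinate), and rewrites CIGAR and MD so
the record stays valid; a range edge inside a deletion run is pulled to
the run boundary, since a deletion cannot be half-kept.  The operation is
idempotent.

## Numerical choices

* Posterior normalisation is done in log10 space with max-subtraction
  before exponentiation, so groups with likelihood spreads of hundreds of
  log units normalise exactly.
* The match term clamps the error probability at 1 − 10⁻¹² so Q = 0 bases
  keep the likelihood finite.
* mapQ rounds half-up; a posterior within machine epsilon of 1 maps to the
  cap.
* Posterior ties are broken deterministically by (reference, start,
  strand), lexicographically smallest first, so repeated runs select the
  same primary.
* Exact duplicate candidates (same reference, start, CIGAR, strand) within
  a group are collapsed; secondary/supplementary flags on input are
  ignored and recomputed.

## The simulator and what it does (not) model

The generator emulates Illumina-like data: uniform region starts (whole
genome or BED features), truncated-Gaussian region sizes (default
300 ± 50 bp in [150, 500]), 100 bp reads, per-position qualities drawn
from Gaussians whose mean is fixed at 35 over a 25 bp seed and then
decays linearly at 0.2 phred/base (sd 2, clamped to [2, 41], forward and
reverse independent), and per-base errors with probability 10^(−Q/10)
split 0.90/0.05/0.05 between substitutions, insertions and deletions.
Truth (reference, 0-based half-open interval, strand) is encoded in each
read name.  Multi-mapping stress comes from planting segmental
duplications (default ten 2 kb copies at 95% identity) into a uniform
random genome.  Real genomes add features this deliberately omits — GC
bias, indel-rich homopolymers, CNVs, rearrangements, RNA editing,
context-dependent error profiles — so passing tests demonstrate
correctness of the probability model and plumbing, not performance claims
on real libraries.

The bundled toy aligner reports *every* locus within `max_edits` of a
read on either strand: exact k-mer seeds (pigeonhole split into
max_edits + 1 segments, so at least one seed survives any edit pattern;
enforced read length ≥ (max_edits+1)·k) verified by banded edit distance
in ±max_edits-padded windows.  It exists to provide complete candidate
sets on small (≲1 Mb) fixtures, not to compete with production aligners.

## Evaluation

A mapping is correct when reference and strand match the truth and both
boundaries are within 20% of the true interval, relative to the alignment
length.  Sweeping mapQ cutoffs (0, 3, 6, 10, 13, 20, …) partitions reads
into TP/FP/FN; precision = TP/(TP+FP), sensitivity = TP/(TP+FN),
FDR = 1 − precision.  Reads filtered out or unmapped count as FN.  The
random-hit baseline picks uniformly among candidates with its own seeded
generator.

## Problem sizes

The end-to-end checks use 200 kb genomes, 2,000 reads per seed and five
seeds; oracle comparisons use 1,000 random candidates/vectors and
normalisation invariants 5,000 random groups per mode.  These sizes give
binomial standard errors well below the asserted margins while keeping
the default suite fast on one core.

## Known limitations

* Single-threaded by design; the intended bottleneck is I/O.
* PE processing makes two passes over the input (fragment-model
  estimation, then scoring), so the input must be a seekable file rather
  than a pipe.
* Name-order violations are detected via a set of 64-bit name hashes — a
  small constant per read rather than strictly group-bounded memory.
* Spliced (RNA) simulation over transcript FASTA treats the transcript as
  the reference; genome-projected truth via exon maps is not implemented.
* Chimeric/split alignments are not modelled as pairs.
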