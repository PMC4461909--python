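# Methods

This note documents the models, numerical choices and limitations behind
each `regsplice` component, and what the synthetic-data generators do and do
not emulate.

## Degenerate-motif scanning and cluster screening

A *cis*-element consensus is an ordered list of IUPAC codes; its degeneracy
is the product of per-position class sizes (the dsxRE `NMDNCRWNCWAYM`
expands to 12,288 words, the Nasonia-like site `NGAAGAWN` to 32, the RBP1b
motif `ATCYNNA` to 32, the TRA-2-ISS `CAAGR` to 2). Matching is exact and
full-length: a position matches iff the subject base is a member of the
pattern class. This is implemented as a vectorised class-membership test,
which is equivalent to matching the full expansion set (a property test
checks it against a lookahead-regex over the expansions) and to a BLASTn
search with word size equal to the pattern length, without the external
dependency.

Conventions that matter:

- Overlapping matches are all reported and all count toward clusters.
- Ambiguity codes in the *subject* (N, masked bases) never match any pattern
  position, so masked regions cannot produce spurious clusters.
- Sequences are case-insensitive; U is treated as T.
- Transcript/CDS screens scan the forward (sense) strand by default; `both`
  is available for genomic scans and maps reverse-strand hits to forward
  coordinates.
- A hit belongs to a window iff its full span lies inside; candidate windows
  slide 1 nt; ties between equal-count windows go to the smallest start.
  The implementation evaluates only the window starts where a hit enters
  (count changes occur nowhere else), which equals brute force over every
  start (property-tested).

The transcriptome screen retains sequences whose best window holds ≥ k
copies; defaults follow the enrichment criteria of the motivating analysis
(k = 6, w = 224 for the dsxRE; k = 8, w = 546 for RBP1b).

## Occurrence-count null model

The number of motif occurrences in an i.i.d. background sequence of length L
is computed exactly. Because every expansion shares one length m and
per-position classes, the text's match state is fully captured by *which
pattern prefixes are currently matched* — a bitmask over prefix lengths
1..m−1. The automaton over this state space is deterministic and compact
(43 reachable states for the 13-mer dsxRE versus 12,288 expanded words); a
step that completes the length-m prefix emits one occurrence. The DP runs
over (state, min(count, cap)) in plain double precision — probabilities at
desk scale are far from underflow — and lumps counts at a cap (default
k + 1, since only the tail P(count ≥ k) is usually wanted). Correctness is
checked three ways: exhaustive enumeration of all 4^L sequences for short
patterns and L = 8; the closed-form mean (L − m + 1)·p for
non-self-overlapping patterns; and a seeded Monte Carlo estimator (3-SE
agreement), which simulates sequences in batches and counts matches with the
same vectorised class test but is otherwise independent of the automaton.

Only 0-order (Bernoulli) backgrounds are supported, uniform by default, with
empirical frequencies computable from any sequence. Published probabilities
of this kind rarely state their background frequencies, so agreement is
expected in order of magnitude, not digits: for six dsxRE copies in 8,045 bp
under a uniform background the DP tail is 4.25 × 10⁻³. No p-value is offered
for "k copies within a w-sub-window of an L-sequence"; that compound event
is not what the DP computes, and the screen reports the empirical retention
rate instead.

## Splice-acceptor strength

The statistic is the pyrimidine (C/T) count Y of the 12 nt immediately 5' of
the 4-nt splice-acceptor end of an intron (N counts as neither). Population
summaries use the arithmetic mean and *sample* SD; a published dispersion of
1.39 accompanying a mean of 8.58 over 52,278 acceptors is treated as an SD —
as a standard error it would be impossible by three orders of magnitude.
"Weak" is a one-sided call: z = (Y − mean)/SD ≤ −2 flags a significantly
purine-interrupted tract; a pyrimidine-rich outlier is a strong acceptor and
is not flagged. The −2 threshold is a package choice (no test was stated in
the motivating analysis); it cleanly separates the Y = 5 exon-6 acceptor
(z ≈ −2.58) from the next-lowest tract (Y = 8, z ≈ −0.42).

Contexts are extracted per intron from a genome + gene models (GFF3, 1-based
closed, converted to 0-based half-open internally; all reports 1-based).
Minus-strand genes are processed on the reverse complement, so contexts read
in transcript sense and are strand-invariant (property-tested by
round-trip). The first exon has no acceptor; the last exon's acceptor is
included. Introns under 30 nt are skipped with a warning — their donor and
acceptor contexts would overlap. Canonicality is GT..AG, case-insensitive.

## Core-promoter detection

An accepted call requires an initiator match (YYANWY or YYANWYY; the adenine
at motif position 3 is the TSS, +1) and a DPE match (RGWYV, or RGWYT as its
fifth-position-T specialisation) whose first base sits exactly at
+`dpe_position` (default +28, i.e. 27 nt downstream of the TSS), with an
optional ± slack. "+28" is interpreted as first-DPE-base-at-+28 counting the
TSS as +1. TATA (consensus TATAWAW, configurable) is searched with its start
inside a window of TSS-relative positions (default [−40, −15]) and only
*reported*; it neither accepts nor rejects a call, since the promoter class
of interest is defined by Inr/DPE spacing and TATA absence is an observation
about the locus. Both the consensus and the window are configurable because
neither is standardised. The CLI exposes `--center/--radius` to restrict the
search to ±250 bp around an externally determined 5' end (e.g. where RNA-seq
coverage ceases); inferring that point from reads is out of scope.

## Ka/Ks (NG86) and the windowed profile

CDS pairs are aligned at the protein level (Biopython's `PairwiseAligner`,
global, BLOSUM62, gap open −10 / extend −0.5) and back-threaded to codons,
so gaps occur only in whole-codon units. Terminal stops are trimmed;
internal stops are an error naming the codon index.

Site counting: at each codon position the synonymous fraction is taken over
the *non-stop* single-nucleotide neighbours (stop mutations excluded with
renormalisation), so s + n = 3 per codon exactly — NG86 variants differ
here, and this choice keeps the site total fixed. Differences for codon
pairs differing at 2–3 positions are averaged over all minimum-length
substitution pathways, excluding pathways that pass through a stop codon;
in the rare case that every pathway is blocked, all pathways are used
unfiltered. Proportions are corrected with Jukes–Cantor,
d = −3/4 ln(1 − 4p/3), undefined at p ≥ 3/4. The estimate is symmetric in
the two sequences and additive over concatenation (both property-tested).

Windows are 30 aligned nt (10 codons) advancing 3 nt, keyed by the central
nucleotide, fixed as window_start + 15 in 1-based coordinates (position 16
of the window; an even-length window has no unique centre, so the convention
is stated rather than discovered). Gap and ambiguous columns are skipped
within each window; a window with < 5 comparable codons is reported
undefined. Ratios are truncated at 6 *for display only* (raw values are
kept); a window with Ks = 0 and Ka > 0 reports an undefined ratio displayed
at the cap, and an all-zero window displays 0.

NG86 counting deliberately replaces multi-estimator "model averaging": it is
the transparent, assumption-light standard against which the synthetic
recovery experiment is meaningful. The acceptance surface is parameter
recovery on simulated pairs (below), not numeric equality with any
particular averaged estimator.

## Synthetic data: what it emulates and what it does not

All generators consume a single seeded NumPy generator per call and return a
truth record (and, through the CLI, a manifest) sufficient to regenerate and
score the output.

- **Background/transcriptomes**: i.i.d. bases at chosen frequencies. Real
  transcriptomes have codon structure, repeats and composition
  heterogeneity; a screen that is clean here can still yield repeat-driven
  false positives on real data (tandem repeats satisfied the RBP1b cluster
  criterion in the motivating analysis), so passing the planted-cluster test
  demonstrates correct mechanics, not real-data specificity.
- **Planted clusters**: k expansions sampled uniformly from the expansion
  set, placed without overlap inside one random w-window (uniform slack
  between copies), leaving the rest untouched — so every planted copy is
  guaranteed recoverable and recall is a sharp 0/1 criterion. Overlapping
  planted copies are not generated (overlaps among *matches* still count).
- **Gene loci**: exon/intron sizes drawn from ranges (defaults 60–120 /
  40–90 nt, desk-scale rather than the tens-of-kb introns of real *dsx*
  loci); introns are GT + 14 random nt … tract + NCAG, with the 12-nt tract
  realising the requested pyrimidine count exactly. Minus-strand encodings
  are exact reverse complements.
- **Promoters**: one Inr and one DPE written at the canonical spacing into
  background; chance Inr/DPE or TATA matches elsewhere remain possible and
  are the expected false-positive channel.
- **Codon pairs**: ancestor drawn codon-wise (stops rejected); divergence by
  repeated single-nt proposals, rejecting stops, accepting synonymous
  changes with probability 1 and nonsynonymous with min(ω, 1) (ω > 1
  down-weights synonymous acceptance to 1/ω), until round(subs/codon ×
  codons) substitutions accrue. This proposal–acceptance scheme is not a
  continuous-time substitution model; it is adequate for recovery tests at
  ~0.3 substitutions/codon. At ω = 0 a synonymous step is additionally
  rejected if the resulting codon, against the *ancestral* codon, would
  admit a minimal pathway with a nonsynonymous step (e.g. CTT→CTA→TTA, all
  leucine, leaves the path-ambiguous pair CTT/TTA); this makes "ω = 0 ⇒
  NG86 Ka = 0 exactly" hold by construction rather than with high
  probability.

Recovery under these conditions (200 codons, 0.3 subs/codon, 50 replicates):
median NG86 ω̂ ≈ 0.19 / 0.93–1.04 / 1.80–1.99 at ω = 0.2 / 1 / 2 across
seeds — within the ±30% band, with the mild compression at ω = 2 expected
from multiple hits and equal-rate site counting.

## Problem sizes and determinism

The test suite and the acceptance script regenerate everything they measure:
enumeration oracles run at L = 8 (4⁸ sequences), Monte Carlo cross-checks at
10⁵ replicates, the cluster screen at 20 seeds × 100 × 2-kb transcripts, and
ω-recovery at 4 × 50 replicates of 200 codons — sizes chosen so a full run
stays in the minutes range on one CPU while keeping binomial/median noise
well inside the asserted bands. Hypothesis profiles are derandomised; every
stochastic routine takes an explicit seed and records it in its output.

## Known limitations

- No PWM/log-odds motif scoring, MaxEnt splice models, branch-point
  detection or donor-strength statistic — the statistics implemented are the
  exact-consensus and pyrimidine-count ones the analyses above require.
- Backgrounds are 0-order only; no higher-order Markov or dinucleotide
  composition.
- No maximum-likelihood (GY94-style) Ka/Ks, no site-model tests.
- Junction-read counts are consumed as tables (the usage report rounds
  half-up to one decimal); read mapping and gene-model assembly are out of
  scope.
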