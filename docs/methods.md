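# Methods

This note documents the models, conventions and numerical choices behind
`tripcas`, in the order the analysis runs.

## Coordinates

All cut-site arithmetic uses the non-target strand (ntDNA, the strand
carrying protospacer+PAM) read 5′→3′. Nucleotide *k* is the k-th base
upstream of the PAM (1-based, position 1 abutting the PAM); junction
`j|j+1` is the bond between positions *j* and *j+1*. The canonical blunt
Cas9 cut is at 3|4; the staggered conformation considered throughout has
termini 3|4 on the target strand and 4|5 on the non-target strand, a 1-nt
5′ overhang whose polymerase fill-in duplicates ntDNA nucleotide 4.
Antisense guides are handled by reverse-complementing the reference into
the ntDNA frame; all downstream logic is frame-agnostic.

## Alignment and calling

Reads are positional: UID (16 nt), anchor, barcode (16 or 18 nt), anchor,
promoter index (5 nt), target region. Parsing rejects reads with reason
codes (`truncated`, `anchor_mismatch`, `aberrant_barcode`); barcode
matching is exact by default, with an optional unique-within-Hamming-k
rescue.

The aligner is a Gotoh three-state semi-global DP: free leading/trailing
gaps on the reference (reads sit inside a fixed amplicon, so reference
overhangs reflect layout, not biology), affine internal gaps charging
`gap_open` on the first gap column and `gap_extend` on each further
column, `N` scored as a mismatch against everything, and an additive
`initial_score` of 30 kept purely for score comparability (it never
changes the argmax). Traceback ties prefer match/mismatch over gaps and
deletions over insertions; indels are then shifted to their 3′-most
equivalent placement, bounded by the next event. Equivalence windows are
computed literally: a placement belongs to a window iff substituting the
indel there reconstructs the identical mutated sequence.

Outcome classes: zero indels → wild-type (isolated substitutions are
dominated by sequencing/PCR error and there is no substitution outcome
class); one deletion → deletion; one insertion → insertion (flagged
knock-in when the insert equals the 21-nt ssODN payload, up to rotation
within its window, within 10 bp of the cut); two or more indel events →
complex. UID collapse takes the majority outcome per (barcode, UID); ties
break toward wild-type, then deletion < insertion < complex.

When numba is importable the DP fill is JIT-compiled (~0.5 ms per
150 × 150 alignment); a pure-Python fill with identical semantics is the
fallback. Reads identical to the reference shortcut to wild-type.

## Profiles

Frequencies are molecule fractions per IR; IRs under 30 molecules in any
assay of a comparison are excluded from all of them, so every cross-assay
statistic runs over one IR set. Replicates merge by pooling counts, never
by averaging frequencies. A deletion "neighbors" a junction when one of
its boundaries coincides with that junction; a deletion with *k*
equivalent placements of which *m* qualify contributes *m/k*. Expression
is log2((cDNA+1)/(gDNA+1)); zero-gDNA barcodes are excluded rather than
rescued by the pseudocount.

## Effect sizes

η²(factor) = SS(factor)/SS(total) from nested OLS fits (statsmodels). In
this design each locus has exactly one promoter, so promoter is nested in
locus and span(promoter ∪ locus) = span(locus): promoter SS is fitted
first on the between-locus contrast, the remainder is attributed to locus,
and the aliasing is reported in the output. The model requires a balanced
complete design (every IR in every assay cell), which makes the remaining
factors orthogonal so the sequential sums equal type-II partial sums and
are term-order invariant; building the design matrices without the
redundant promoter columns also keeps them full rank (the
rank-deficient promoter+locus matrix made pinv solutions row-order
sensitive at the 1e-4 level). Nonparametric shifts are Hodges–Lehmann
estimates (median of Walsh averages when paired, median of pairwise
differences otherwise) with scipy Wilcoxon/Mann–Whitney p-values and a
seeded percentile bootstrap 0.95 CI (2000 resamples); all-zero paired
differences return shift 0, p 1. Knock-in/error-insertion ratios drop
zero-denominator IRs (counted, never clamped) and bin total mutation
frequency at width 0.10 over [0, 1]; empty bins are reported missing.

## Genomic context

Track scores are aggregated as the base-weighted mean over a 2 kb window
centered on the integration (intervals expanded to covered bases —
interval-weighted means would differ); positions without data are ignored
and all-missing windows propagate NaN. Pearson r with two-sided t-test
p-values; Benjamini–Hochberg runs over all (response, feature) pairs of a
run as one family.

## Insertion cleavage models

For each inserted base, junctions flanking a maximal run of that base form
one ambiguity window (a run of *k* bases → *k*+1 junctions); the analyzed
range is 0|1…8|9 (PAM plus 8 bp upstream) and windows are clipped to it.
Counts enter as window totals, so results are identical whether the
upstream caller reports at the 5′- or 3′-most junction of a run.

Redistribution of a window's count *c* over its junctions:

- **blunt** — proportional to the total unambiguous counts (all four
  bases) at each junction; an all-zero weight vector falls back to a
  uniform split.
- **staggered** — junctions whose downstream (PAM-ward) ntDNA base equals
  the inserted base are *likely*; each unlikely junction is assigned the
  mean of the unambiguous counts of the other three bases at that
  junction, and the remainder goes to likely junctions proportional to the
  unambiguous weights. A negative remainder is clamped to 0 and reported;
  totals are otherwise conserved exactly.
- **combined** — a window containing a likely junction 4|5 follows the
  staggered rule (its unlikely edge — 3|4 in the canonical case — thereby
  receives the blunt-model expectation); every other window follows the
  blunt proportional rule. This is one consistent resolution of how the
  per-site rules compose within a window; it reproduces the closed-form
  mixture expectation, base-4 share = f + (1−f)/4 over the 3|4+4|5 region
  for a staggered fraction f.

`model_concordance` summarizes fit only (modal base, share, χ² uniformity
p); it deliberately does not estimate the blunt:staggered mixture
fraction, which re-cleavage dynamics would bias in real data.

## End structures

For the PAM-proximal fragment with duplex `W` (PAM at index `P`) and
termini `t` (tDNA) / `nt` (ntDNA), the expected hairpin read is
`revcomp(W[P−t:]) + W[P−nt:]`. Relative to a blunt end at the same tDNA
terminus, a k-nt 5′ overhang appears as a k-base apex duplication of ntDNA
bases and a k-nt 3′ overhang as a k-base apex loss. Enumeration covers
termini within half the 30 bp window of junction 3|4 with overhangs up to
14 nt; structures with literally identical expected reads merge into one
degeneracy group (e.g. blunt 3|4 merges with the 2-nt 5′ (2|3t, 4|5nt) and
2-nt 3′ (4|5t, 2|3nt) overhangs whenever base 4 complements base 3).
Observed reads are aligned with the package's semi-global aligner —
an equivalent substitute for an external local-alignment search, since
only spans and indel operations are consumed — filtered (alignment ≥ 50 bp,
≤ 5 gap columns, span ≥ 50 bp around the target) and reduced to the
operations inside the 30 bp apex window. Group patterns are extracted from
the expected reads with the same aligner, so placement conventions can
never disagree between the two sides of a match. Substitution masking
(bisulfite-conversion noise is substitution-like, primarily T↔C) is
applied to both observed and expected patterns; masking merges groups
whose patterns collapse onto the same indel-only key, which is why the
blunt share rises under masking.

## Synthetic data: what it emulates, and what it does not

Per molecule the generator draws: mutate with probability
p_IR · g_guide (p_IR ~ Beta(2,2) per locus, shared across assays, giving
broad locus-driven variance; g_guide a per-guide multiplier, 1.3 for the
AT-rich guide); given mutation, knock-in (ssODN assays, p = 0.05), complex
(deletion+insertion, p = 0.05), insertion (p = 0.15; 90% single-base),
else deletion. 1-bp insertions follow the blunt/staggered mixture; default
per-guide staggered fractions (0.52, 0.65, 0.97) are back-computed from
dominant-base shares via share = f + (1−f)/4. Deletion sizes are
truncated-geometric (p = 0.15, max 30; ~77% below 10 bp) with an optional
microhomology spike deleting one unit of a tandem triplet; deletions are
placed to overlap the cut uniformly. Coverage is negative-binomial (mean
60, shape 5 — above the ≥30 filter but with realistic dropout); UID
duplication is Poisson (mean 0.3 extra reads); sequencing error is i.i.d.
substitution-only at 1e-3 so that read noise never fabricates indels
(indel errors are configurable off by design). One root seed spawns
per-IR child streams, so adding an IR never perturbs the others' reads.
Hairpin reads abstract bisulfite chemistry to per-C conversion-failure
substitutions (C→T) on one declared strand of the untreated-space read.

Feature tracks are built as r·z(signal) + √(1−r²)·noise on windows around
each locus, so the requested Pearson correlation is recovered as the
number of IRs grows; loci sit on a spaced grid so track windows never
overlap.

Passing tests on these data demonstrate that the statistics recover known
generative parameters under the stated noise model. They do not
demonstrate robustness to amplicon-specific PCR artifacts, chimeric or
translocated reads, quality-score-dependent errors, chromatin effects on
cleavage, or re-cleavage selection bias — none of which the generator
simulates.

## Problem sizes and determinism

Default analysis sizes: 36-IR cell-line study across three guides
(~6,500 molecules), 300-IR factorial pool (1,200 profile rows), 10,000
insertion events for cleavage-model recovery, 5,000 hairpin reads at 5%
bisulfite-failure noise. All bootstraps and generators take explicit
seeds; identical (config, seed) reproduce outputs byte-for-byte, which the
pipeline exploits for content-hash caching.

## Known limitations

- "Complex" is defined as ≥ 2 indel events in one read; alternative
  definitions can be re-derived from the per-read logs.
- The staggered redistribution uses the other-three-base mean at unlikely
  sites; an all-four-base mean is a defensible alternative reading.
- The promoter/locus ANOVA nesting is one defensible resolution and is
  labeled as such in the output.
- Real hairpin-capture references must be reconstructed from the original
  accession; the end-structure module here is exercised on synthetic
  duplexes only.
- The Hodges–Lehmann unpaired estimator materializes the full pairwise
  difference matrix; fine to a few thousand observations per group.
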