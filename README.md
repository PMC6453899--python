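# tripcas

Mutation profiling of multiplexed CRISPR-Cas9 assays on barcoded reporter
amplicons.

## The problem

Profiling Cas9 activity at many genomic loci at once is hard to do on
endogenous sequence: relaxing guide specificity inflates off-target
cleavage, and repetitive targets confound alignment. An alternative is to
integrate thousands of barcoded reporters (IRs — integrated reporters)
throughout a genome, target the *same* sequence inside every reporter with
an RNA-guided Cas9, and deep-sequence the amplified target regions. Each
read carries a unique molecular identifier (UID), the reporter barcode, and
the targeted region, so mutation outcomes can be assigned per molecule and
per locus. This package implements the analysis for that design, plus
seed-controlled synthetic-data generators that emulate its statistical
structure, so every statistic is testable against a known ground truth.

## What it computes

- **Mutation calling** (`tripcas.readcall`). Reads are parsed into
  (barcode, UID, target), the target is aligned against the wild-type
  amplicon by semi-global alignment with affine gaps (match +2, mismatch
  −2, gap open −5, gap extend −0.5, additive initial score 30; free
  end-gaps on the reference side), and each molecule is classified as
  wild-type, deletion, insertion, or complex (≥ 2 indel events).
  Indels carry their full placement-equivalence windows; reads sharing a
  (barcode, UID) collapse to one molecule by majority outcome.
- **Per-IR profiles** (`tripcas.profiles`). Outcome frequencies per IR
  (coverage ≥ 30 in every assay), indel size spectra, ambiguity-weighted
  deletion-boundary frequencies around the expected (3|4) and alternative
  (4|5) cut sites, inserted-base distributions, and cDNA/gDNA expression.
- **Effect decomposition** (`tripcas.effects`). η² = SS(factor)/SS(total)
  from a multi-way type-II ANOVA of mutation frequency on IR locus, guide,
  ssODN, promoter (nested in locus) and locus×guide; pairwise assay OLS;
  Hodges–Lehmann shifts with Wilcoxon tests; knock-in/error-insertion
  ratios with bootstrap CIs.
- **Genomic context** (`tripcas.context`). Mean feature-track score over a
  2 kb window around each integration, Pearson correlations against per-IR
  responses, Benjamini–Hochberg control.
- **Cleavage models** (`tripcas.insertion_models`). The core inference: a
  1-bp insertion next to an identical base cannot be placed uniquely
  (A·A vs ·AA), so observed counts are accumulated over maximal ambiguity
  windows and redistributed under three models — **blunt** (template-free
  insertion at junction 3|4, proportional-to-unambiguous split),
  **staggered** (template fill-in of a 1-nt 5′ overhang with termini 3|4 on
  the target strand and 4|5 on the non-target strand, duplicating ntDNA
  nucleotide 4), and **combined**. Junctions `j|j+1` count bonds upstream
  of the PAM on the non-target strand.
- **DNA end structures** (`tripcas.end_structures`). Enumerates every
  (tDNA, ntDNA) terminus pair in a 30 bp window around the cut, builds the
  expected hairpin-capture read for each conformation, merges structures
  with literally identical expected reads into degeneracy groups, and
  matches observed hairpin reads (filtered: ≥ 50 bp alignment, ≤ 5 gaps,
  ≥ 50 bp span; bisulfite-noise substitutions maskable) against them.
- **Pipeline** (`tripcas.workflow`, `tripcas` CLI). Staged execution with
  a manifest, checksums and cache; `simulate`, `call`, `profile`,
  `insmodel`, `effects`, `ends`, `all`, `fixtures` subcommands.

## Worked example

```python
from tripcas import (DEFAULT_GUIDES, SimulationConfig,
                     generate_reporter_library, simulate_cas9_reads,
                     call_reads, collapse_uids, compute_profiles)

cfg = SimulationConfig(seed=1, n_irs=36)
library = generate_reporter_library(cfg)
refs = {c.barcode: c.target_region for c in library}
g3 = DEFAULT_GUIDES[2]                      # AT-rich guide, template base T
reads, truth = simulate_cas9_reads(library, g3, cfg)
calls, summary = call_reads([s for _, s in reads], refs, g3)
molecules, _ = collapse_uids(calls)
prof = compute_profiles({"sgG3": molecules}, min_coverage=30)
print(round(summary["parse_rate"], 3), round(prof["total_mut_freq"].mean(), 3))
```

prints

```
0.964 0.597
```

i.e. 96.4% of reads parsed (sequencing errors in the barcode or anchors
reject the rest) and a mean per-IR mutation frequency of 59.7% for this
guide — each IR's frequency being the fraction of UID-collapsed molecules
carrying any indel. With the default staggered fraction of 0.97 for this
guide, 97.9% of its 1-bp insertions are T, the duplicate of ntDNA
nucleotide 4 — the signature separating staggered from blunt cleavage.

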