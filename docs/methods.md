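# Methods

## The motif model

A p53 response element is modelled as two decameric half-sites joined by an
unconstrained spacer.  Two representations are used, deliberately kept
consistent with each other:

* **Degenerate pattern** — the IUPAC string `RRRCWWGYYYN{0,15}RRRCWWGYYY`.
  A position matches iff the genome base is in the symbol's base set;
  matching is binary, there is no mismatch tolerance.  The spacer
  contributes no constraint at all.
* **PWM pair** — one 10-column position weight matrix per half-site with an
  unscored spacer between them.  Column frequencies are
  `(counts + pseudocount) / (n_sites + 4·pseudocount)`; scores are
  log₂(frequency / background) summed over positions ("bits").  The spacer
  again contributes nothing, mirroring the pattern's `N`-run.

Both representations are strand-symmetric as a *class*: the reverse
complement of `RRRCWWGYYY` is `RRRCWWGYYY`, and the spacer is free.  The
scanner therefore reports the forward strand only and labels every match
`+`; a minus-strand pass would re-report every site at mirrored coordinates.
Strand symmetry is asserted by tests rather than assumed.

### Alphabet conventions

* Matching is case-insensitive; soft-masked (lowercase) sequence is scanned
  because repeat-hosted sites are biologically relevant here (repeats are a
  documented reservoir of p53 sites), so repeats must not be excluded from
  the scan.
* A genome `N` (assembly gap) satisfies **no** pattern symbol, including a
  pattern-side `N` position: gaps can never complete a half-site.  Spacer
  positions are not tested at all, so gaps inside the spacer are harmless.
* Coordinates are 0-based half-open internally; every printed table is
  1-based inclusive; BED exports are 0-based half-open.

## Exact scanning

Per chromosome the scanner computes, for each half-site, a boolean mask
`mask[i]` = "half-site satisfied starting at i" (one vectorised pass per
pattern position over the integer-encoded sequence), then reports, for each
spacer `s` in range, every `i` with `mask1[i] AND mask2[i + 10 + s]`.  All
(position, spacer) combinations are distinct matches: overlapping hits and
nested spacer variants at one start are all reported, because downstream
statistics (spacer histogram, density) are defined over occurrences.  A
`longest_only` mode collapses to the largest-spacer variant per start for
comparability with collapsed outputs of other scanners.  Output equality
with a brute-force position-by-position oracle is part of the test suite.

## Exact p-values

The score of a random background word is a sum of independent per-position
scores, so its exact distribution is obtained by convolving the
per-position distributions on an integer grid.  Choices:

* **Discretization** — scores are rounded to a grid of 1e-3 bits
  (configurable).  The p-value error is bounded by the probability mass
  within `width × resolution` of the threshold; tests bracket the DP value
  between enumeration at threshold ± that bound.  At width 10 and the
  default resolution the DP table stays a few tens of thousands of bins.
* **Impossible words** — with pseudocount 0, a zero-frequency cell scores a
  large negative sentinel (−1e9) rather than −∞ so that sums remain
  orderable.  Words containing a sentinel are "impossible under the model":
  they rank below every finite score and their mass enters the p-value only
  at/below the sentinel, so p(−∞) = 1 always holds.
* **Pair distribution** — the combined half-site score distribution is the
  convolution of the two half distributions (the spacer adds nothing);
  verified against exhaustive enumeration at width 3+3.
* **E-value** — p-value × number of candidates scored, the "database of the
  same size" convention.  For genome scans the candidate count is the
  number of (position, spacer) windows evaluated.

Defaults: pseudocount 0.25 per cell (uniform-equivalent prior), log base 2
everywhere, background = genome base frequencies when a genome is at hand,
uniform otherwise.  PWM-scan threshold defaults to 60% of the maximum
achievable pair score; rank order, not absolute score scale, is the
meaningful quantity, and rank order is invariant to the log base.

## Annotation

* **Gene window** — a match is gene-related iff its interval overlaps
  `[gene_start − 5000, gene_end + 5000]`.  The window anchors on the whole
  gene span, not the TSS alone, because deep intronic sites are legitimate
  and observed; 5 kb is the conventional neighbourhood for this analysis.
* **Region label** — computed against the *representative transcript*
  (longest; ties broken by smallest transcript id, since annotation sources
  rarely state a canonical choice).  Precedence when a match touches
  several feature classes: 5′UTR > exon > intron > upstream > downstream >
  3′UTR.  Because 3′UTRs are normally contained in exons, the explicit
  3′UTR label only appears for annotations whose UTR features extend beyond
  exon features.  "Promoter" and "upstream" are collapsed into a single
  `upstream` label (≤ 5 kb 5′ of the TSS): the two are not separable
  without a promoter definition the inputs do not carry.
* **TSS distance** — measured from the match edge nearest the TSS, signed
  along the gene strand (negative = upstream).  A match containing the TSS
  has distance 0.
* **Strand concordance** — the scan strand is fixed `+`, so "pattern in the
  same orientation as the gene" reduces to "gene on +"; output headers
  carry this caveat.  Per-region proportions are computed over concordant
  patterns only, each pattern contributing once via its concordant
  annotation with the smallest |TSS distance| (ties: smallest gene id), so
  the four region counts (5′UTR / upstream / intron / other) sum exactly to
  the same-orientation pattern count.
* **Repeat overlap** — ≥1 bp intersection with any repeat interval counts;
  partial overlap counts.  RepeatMasker `.out` (15-column) and BED are both
  accepted.

## Similarity re-search

Validated sites of unequal spacer are laid out in a fixed frame of
`20 + max(spacer)` columns: first half-site left-justified in columns 1–10,
second half-site right-justified in the last 10 columns, the spacer
immediately after the first half, gaps filling the remainder.  The two
half-site blocks are gap-free by construction and gap columns never enter
PWM counts.  Candidates (any set of 10+spacer+10 sequences) are scored once
and gated twice: E-value ≤ 10 (ascending E-value order, ties by candidate
id) and exact p-value < 0.05 of the best combined score.  The re-search
result is the intersection, ordered by E-value rank.  No multiple-testing
correction is applied to the p < 0.05 gate by default — this matches the
workflow the package reproduces — and a Benjamini–Hochberg variant is a
natural extension left to the caller.  `pwm_robustness` repeats the whole
procedure with PWMs rebuilt from alternative seed-RE subsets and reports
per-method overlap with the reference selection.

## Prioritization

Pure bookkeeping, deliberately free of any network dependency: region /
|TSS distance| / strand filters (each disengageable), a one-to-one ortholog
join from a user TSV (conflicting one2one rows are an error), and the union
of per-tool top-k (default 50) ranking tables with provenance columns.  The
final manual curation of candidates is intentionally not automated; the
output is the filtered pool for human review.

## Synthetic data: what it does and does not emulate

The generator emulates, from a single integer seed (bit-for-bit
reproducible):

* an i.i.d. order-0 background genome with configurable base frequencies
  (order-1 backgrounds are a possible extension, not the default — the
  background enters the p-value machinery as plain nucleotide frequencies);
* planted motif instances, sampled either uniformly from the degenerate
  pattern class (`consensus_sample`) or from a PWM pair's **empirical**
  column frequencies (`pwm_sample`; the pseudocount is a scoring
  regularizer, not generative truth, so unseen bases are never planted);
  planted sites avoid chromosome edges and each other by the maximal site
  length, which keeps the truth bookkeeping exact;
* toy gene models — non-overlapping, random strand, one transcript, 2–8
  exons, 5′/3′UTRs on the terminal exons, ~10% single-exon miRNA genes —
  written as valid GFF3 with adaptive spacing so the requested gene count
  fits the chromosome;
* repeat intervals tiled to a target coverage fraction with family labels
  (`hAT-AC`, `DNA`, `TE-X-4_DR`, …); labels only, no repeat sequence model.

Not emulated: repeat sequence content (so planted sites never arise *from*
repeat sequence the way real repeat-borne sites do), alternative
transcripts, nested/overlapping genes, chromosome-scale composition
heterogeneity, and conservation.  Passing tests therefore demonstrate
correctness of the algorithms under the stated generative assumptions, not
performance on real genomes, where background structure (CpG depletion,
repeat families enriched for half-sites) changes hit counts substantially.

## Problem sizes

Desk-scale fixtures are used throughout: 1 Mb genomes with 25 planted sites
for recovery and annotation, a 10 Mb uniform genome for the analytic
match-count calibration (expected ≈ 9.5 matches), width-5 PWMs for
enumeration cross-checks (4⁵ = 1024 words), 500 sampled sites for parameter
recovery, and 100-candidate pools (20 planted / 80 background) for the
re-search.  These sizes make every expectation computable exactly or
enumerable while exercising the same code paths as genome-scale runs; the
scanner itself processes ~20 Mb/s per spacer class, so whole vertebrate
genomes are within reach of the identical entry points.

## Known limitations

* Exact matching only: no mismatch-tolerant degenerate scanning (the PWM
  route is the graded-similarity alternative).
* The p-value machinery assumes an i.i.d. background; E-values inherit
  that assumption.
* Score-level comparability with other PWM scanners is not attempted —
  only rank-level behaviour is specified and tested (scaling conventions
  differ between tools; rank order is base- and scale-invariant).
* Whether an upstream scanner collapses nested spacer variants into one
  hit affects absolute hit counts; both conventions are exposed
  (`longest_only`), with all-variants the default.
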