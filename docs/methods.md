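# Methods

## The discrimination criterion

For two groups of samples A and B at one locus, let *d*min be the
minimum K2P distance over all cross-group sample pairs and *d*max the
maximum K2P distance over all same-species pairs, where the species set
is restricted to the species represented in A ∪ B. The locus
*discriminates* A from B iff *d*min > *d*max (strict: equality or a
shared haplotype across groups fails). Same-species pairs include
clone-vs-clone comparisons within one voucher — a multi-copy locus such
as a 5S rRNA spacer with non-homogeneous paralogs therefore carries a
legitimately large intraspecific maximum, which is part of what the
criterion is meant to expose. When the two groups contain no species
with two or more samples, the intraspecific maximum is reported as 0.0
with an explicit warning flag (`n_pairs == 0`) rather than silently.

Across loci sharing one group pair, differentiation power is ranked by
descending *d*min with competition ranking (ties share the smaller rank;
the next rank is skipped). The ranking key is a design choice: the
criterion itself only orders loci by their between-group separation, and
this single key reproduces all three published ranking rows for the
Gentiana study system (see `barcodegap.gentiana.REPORTED_DIVERGENCE`),
so no secondary key is used.

## Distances

Site patterns are counted per pair under **pairwise deletion**: a column
is excluded iff either sequence holds `-` or any non-ACGT IUPAC code
(ambiguity codes are treated as missing, matching the convention of the
classic distance software this emulates). With P = transitions/n and
Q = transversions/n,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Preconditions: n > 0, 1 − 2P − Q > 0 and 1 − 2Q > 0. Violations raise
(`UndefinedDistanceError`, `SaturationError`) by default;
`on_saturation="inf"` substitutes +∞ for exploratory use but is never
used inside the gap analysis, because an infinite entry silently
corrupts min/max statistics. Distances are held at full float precision;
report writers round to 4 decimals. No variance is attached to the
distances themselves (the gap criterion uses order statistics, not
standard errors). Because distances are computed from the supplied
multiple alignment with per-pair deletion — not from per-pair
realignments — users should supply the same alignment they would feed a
tree program.

## Neighbor joining and bootstrap

NJ follows Saitou–Nei with the Studier–Keppler Q-criterion,
Q(i,j) = (m−2)·d(i,j) − r(i) − r(j). Conventions the classic
implementations leave unstated are fixed as: ties in Q break to the
lowest (row, column) pair in the current node ordering; the merged node
takes its first child's row; negative estimated branch lengths are
clamped to 0 without redistribution (display-level only — path-length
fits on additive inputs are exact because additive matrices never
produce negatives). On additive matrices the algorithm provably recovers
the generating topology; the test suite verifies exact recovery on
random 5–8-leaf trees and cross-checks against an independent NJ
implementation.

Bootstrap: columns are resampled with replacement to the original
length; the K2P matrix and NJ tree are recomputed; each nontrivial
bipartition of the reference (full-data) tree is scored as the
percentage of *successful* replicates containing it. Replicates whose
matrix is undefined (saturation, empty comparison) are skipped, counted,
and excluded from the denominator; an all-failed bootstrap raises.
Supports are displayed on the full-data tree, not a majority-rule
consensus — the usual display convention of distance-tree software; the
complete bipartition tally is returned for callers who want a consensus
view. Newick output writes branch lengths at 6 d.p. and hides supports
below a threshold (default 50%).

## Primer scanning and design

Primer placement is ungapped (Hamming-style): the placement maximising
the number of template bases contained in the corresponding primer
code's IUPAC set wins, leftmost on ties. Patterns use dot notation with
the *template* base shown at mismatches. An indel in the binding site
surfaces as a poor best placement and is flagged when mismatches exceed
⅓ of the primer length. Reverse primers are matched against the
reverse complement, with the leftmost plus-strand coordinate reported
alongside. Candidate design slides windows (default 18–25 nt) over
columns that are gap-free in every sequence, takes the majority-rule
consensus (IUPAC degeneracy when no strict majority), and filters on
worst per-sequence mismatch count, GC bounds, and an invariant 3′ tail
(default 3 bases, since 3′ mismatches are what kill extension).
Thermodynamic screening (Tm, hairpins, dimers) is deliberately out of
scope: GC% and 3′ conservation are the only quality filters.

## Simulator

Sequences evolve site-independently under K2P: uniform root, per-branch
closed-form substitution probabilities parameterised by branch length
*b* (expected substitutions/site) and κ = α/β. With βt = b/(κ+2):
P(transition) = ¼ + ¼e^(−4βt) − ½e^(−2(α+β)t), P(each transversion) =
¼ − ¼e^(−4βt). No rate heterogeneity across sites — deliberately
matching the estimator's own assumptions so parameter-recovery tests are
clean. Optional features: a conserved island (columns copied invariantly
everywhere) as a planted target for primer design; single-column
indels (half deletions, half insertions, placed uniformly per sequence
after substitution) producing spacer-like ragged ungapped lengths while
keeping the matrix rectangular; and per-leaf clone expansion along a
star of branch `clone_divergence`, emulating non-homogeneous multi-copy
loci. Every run emits a truth record (tree, κ, island coordinates after
indel shifting, event counts) for assertions.

`simulate_gap_scenario` realises a designed gap geometry: every sample
sits `within`/2 from its group hub and the hubs are `between − within`
apart, so conspecific pairs have expected divergence `within` and every
cross-group pair `between` (requires 0 ≤ within < between). Defaults:
two samples per species, κ = 2 (a typical plastid/nuclear
transition:transversion bias).

What the simulator does *not* emulate — rate variation among sites and
loci, base-composition bias, alignment error, heterotachy — bounds what
passing tests show: they validate the machinery under its own model, not
robustness to real-data violations of K2P.

## Problem sizes and tolerances

The validation suite uses: 200 random 50-column alignments against a
brute-force oracle (exact equality); 100 random additive matrices of
5–8 leaves (branch lengths 0.05–1.0; topology exact, path lengths to
1e−9); estimator recovery on a 100 kb pair at true distance 0.1 within
4 delta-method standard errors (≈0.0042); gap detection on 20 designed
datasets (within 0, between 0.1, 10 kb; expected ≥19 successes);
bootstrap at 100 replicates for the deterministic two-clade signal and
1000 replicates for a 600-bp three-species clade scenario (support
expected above 70%, typically >95%). These sizes make the whole suite
run in seconds while leaving each check statistically unambiguous.

## Known limitations

* Only the K2P model is provided (no JC69/HKY/GTR, no gamma rates);
  this matches the evaluation design the package implements.
* NJ tie-breaking and negative-branch handling are conventions, not
  community standards; trees from other software can differ in
  zero-signal regions while agreeing on supported clades.
* The intraspecific maximum pools clones with ordinary conspecific
  samples; per-voucher averaging is not offered.
* Diagnostic-site coordinates are reported in the supplied alignment's
  own frame; they are not portable across realignments.
* Accession fetching is out of scope: the pipeline consumes aligned
  FASTA the user provides.
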