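# Methods

## The model

`mitoqfp` treats a genome as a circle of length L with 1-based coordinates;
position p and p + L are the same base.  Two kinds of point sets live on the
circle: motif midpoints (possibly half-integers, from even-length elements)
and deletion breakpoints (integers).  The scientific question is whether one
set is closer to the other than a rigid rotation of either set would be.

The null model is rotation: the target set is displaced by r nucleotides for
every r = 1 … L−1, keeping its internal spacing intact.  This is a stricter
control than composition-matched resampling — it preserves the full
clustering structure of the motif set and only randomizes its phase relative
to the breakpoints.  The identity rotation is excluded, so there are exactly
L−1 controls and the smallest resolvable p-value is 1/(L−1); a p of exactly 0
is displayed as "< 1/(L−1)".  Ties are counted against the alternative
(controls with mean ≤ actual), so reported p-values are conservative.

### Minimal Distance Analysis

For from-set A and to-set B, the statistic is the mean over A of the
circular nearest-neighbour distance to B.  It is asymmetric: with many
breakpoints and few motifs, breakpoints→motifs can be insensitive even when
every motif hugs a breakpoint, which is why the analysis is always run
reciprocally.  Whether a motif lies inside or outside the deleted segment is
deliberately ignored — the minimal distance is taken in either direction
around the circle.

### Individual enrichment

For each threshold D the count K of from-points within D of the to-set is
compared with Binom(N, P), where P is the fraction of integer genome
positions within D of the to-set.  P is exactly the rotation-averaged
probability that one point lands within D, which ties the binomial null to
the same rotational reasoning as the MDA (a property the test suite checks
directly).  Two tail conventions are always computed: P(X ≥ K)
(`at_least_K`, the default) and 1 − F(K; N, P) (`greater_than_K`).  The
default is P(X ≥ K) because the other form returns p = 0 whenever K = N,
even under the null; both are reported so results can be compared against
tables produced under either convention.

### Both-ends proximity

A deletion is "close" when both its breakpoints are within D (default 10 nt)
of the motif set.  The chance probability is the rotation average of the
per-deletion qualifying indicator, P = Σ_r c_r / ((L−1)·N), and the p-value
is binomial as above.  In the paired-repeat variant a deletion qualifies
only if a single repeat pair matches both ends (5′ unit near the 5′
breakpoint and 3′ unit of the same pair near the 3′ breakpoint); the control
rotates the whole repeat-unit constellation rigidly so pairs stay paired.
The test suite includes a fixture in which a deletion matches the 5′ unit of
one pair and the 3′ unit of a different pair: it qualifies in the pooled
single-set mode but not in paired mode.

## Scanners

### QFP elements

A QFP candidate is a selection of four disjoint guanine sub-tracts, each at
least 2 (tier 2G) or 3 (tier 3G) bases, with at least one loop nucleotide
between consecutive tracts and an overall span of at most 33 nt.  Loops may
contain G, so one long run can donate two tracts separated by a one-base G
loop (GGGGG → GG·G·GG); this is required for sequences like GGGGGATGCGGGGG
to qualify and matches the behaviour of the common QGRS-style scanners.
Candidates are collapsed to elements keyed by (first-tract start, last-tract
end); the element's tetrad count is the best min-tract-length over its
selections, found by a small dynamic program over tracts inside each 33-nt
window rather than by enumerating tuples.

Overlap resolution is iterative-greedy: take the best remaining candidate by
(span ascending, tetrads descending, start ascending); when the top rank is
shared by mutually overlapping candidates of equal span and tetrads, the
member whose midpoint is closest to the group median is emitted with its
midpoint replaced by the exact median (count recorded in `merged`), which
keeps every emitted interval a real sequence region.  Everything overlapping
the emitted element is removed and the process repeats, yielding a
deterministic, maximal non-overlapping set.  Resolution runs per strand; the
reported per-genome count is the union over strands.  "Heavy strand" is
defined operationally as the G-richer strand of the input, with no
assumption about which strand the FASTA deposits.

Interstrand (ddi) candidates let each tract sit on either strand (a
complement-strand G-run is a C-run in the reference frame) and must use both
strands; candidates overlapping any intrastrand element are discarded before
resolution, keeping the intra- and interstrand sets disjoint.

Circularity is handled by scanning the sequence extended with its first 32
bases and keeping candidates whose first tract starts within one period;
scanner output commutes with rotation of the input (property-tested).

### Repeats

A window start qualifies for class c when the class transform of its k-mer
(direct: identity; inverted: reversal; complementary: base-wise complement;
inverted-complementary: reverse complement) occurs at a different start on
the reference strand, circular k-mers included.  Maximal runs of consecutive
qualifying starts merge into one repeat unit (so a single 12-bp repeat is
one unit, not two 11-mer motifs), with the unit midpoint used downstream.
Palindromic self-matches qualify provided the partner start differs from the
window's own start.  k-mers containing N never match.  A fully repetitive
genome collapses to a single genome-wide unit with a warning.  Unit pairs
are enumerated from recorded partner starts and oriented 5′→3′ in the
canonical linearization.

## Numerical choices

All positions are mapped to a half-unit integer grid of size 2L (position p
→ round(2(p−1)) mod 2L), so half-integer midpoints are exact.  Nearest-point
profiles are computed by sorted search over the grid; the L−1 control means
of the MDA come from one FFT circular cross-correlation of the from-set
histogram with the integer profile, rounded back to integers — sums are
bounded by N·2L ≪ 2^52, so the rounding is exact and the ≤ tie comparison is
integer-exact, never a floating-point coin flip.  This makes a full MDA at
L = 16,569 run in milliseconds, which is what allows the calibration suites
(hundreds of simulated MDAs) to be ordinary tests.

Chance probabilities are evaluated over integer genome positions only
(breakpoints are integers; midpoints may be half-integers).  Reported mean
distances are rounded to integers in the human-readable summary only;
machine output keeps full precision.  Significance stars follow the
conventional 0.05 / 0.01 / 0.001 thresholds, with exact p-values always
printed alongside.

## Synthetic data: what it emulates, and what it does not

`generate_genome` draws i.i.d. bases from a configurable composition; the
default "mtDNA-like" preset is strand-asymmetric (deposited strand G-poor,
≈13% G), so the complement plays the role of the G-rich heavy strand.
`shuffle_genome` permutes the base multiset exactly, giving
composition-matched nulls for motif-count-excess tests.  `plant_sequence`
overwrites bases circularly (conflicting overlapping plants are rejected),
enabling planted-motif recovery tests with the validated oligo panel.
`simulate_deletions` provides the null (uniform breakpoints, ordered
bp5 < bp3) and two alternatives: breakpoints displaced from uniformly chosen
motif midpoints (signed displacement, default uniform on [0, 5] nt, rounded
half-away-from-zero), and repeat-mediated deletions whose ends sit at the
two units of a chosen repeat pair.

An i.i.d. genome has no gene structure, no replication-origin landmarks, no
local composition gradients, and its motif counts are Poisson-like rather
than selected; real mtDNA is motif-enriched relative to such nulls.  The
deletion simulator draws breakpoints independently per record, whereas
curated collections contain hot spots shared across patients.  Passing tests
therefore demonstrate that the scanners and statistics are correct and
calibrated under controlled conditions — not that any particular biological
association holds; that conclusion requires the real reference genome and a
curated deletion table, which users must supply (see `data/` hooks in the
acceptance tests).

## Problem sizes

Calibration suites use 500 uniform-null runs (n = 50 breakpoints, 150
motifs, L = 16,569) and 200 planted-association runs; scanner oracles use
100 random 150-nt circular sequences and 2-kb all-pairs repeat comparisons.
These sizes give Monte-Carlo error comfortably inside the asserted bands
(e.g. the null fraction of p ≤ 0.05 is binomial with SD ≈ 0.01 at 500 runs).

## Known limitations

* No thermodynamic scoring of quadruplex stability (no G-scores, no melting
  predictions); detection is purely pattern-based.
* Repeats are exact and fixed-length per run; degenerate/mismatched repeats
  and multi-k scans are out of scope.
* Raw p-values only; no multiple-testing correction is applied across motif
  sets or subgroups — treat the tables accordingly.
* Distances use midpoints, not intervals; distances below ~16 nt for QFP or
  ~6 nt for 11-mer repeats can reflect literal overlap of the element with
  the breakpoint rather than mere proximity.
* The rotational null conditions on the motif set's internal geometry; it
  does not model uncertainty in motif calling itself.
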