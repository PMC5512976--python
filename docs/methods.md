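# Methods

This note documents the models and conventions implemented in `protquant`,
the choices made where several reasonable definitions exist, and what the
synthetic data used in tests and demos does and does not establish.

## Sequence model

A sequence is an ordered list of elements with an identifier and a feature
name. Raw FASTA records carry single-character residues (feature name
`fasta`); property mappings and features produce numeric or reduced-alphabet
records of the same shape, so every stage of a pipeline consumes and
produces the same container. Scalar feature results are stored as length-1
records, which keeps `compact()` (one row per identifier, one column per
feature) uniform. FASTA identifiers are the header token before the first
whitespace; the full header is kept as a description so write/read round
trips are lossless. Residue case is folded to upper on read by default;
non-standard symbols (B, Z, X, U, O, `*`, `-`) are preserved and handled by
mapping defaults downstream. Indices are 0-based everywhere.

`compact` concatenates values in encounter order and does not require every
identifier to carry every feature; a strict mode rejects ragged rows for
deterministic table export.

## Property mappings and reduced alphabets

A `PropertyMapping` is a symbol→value table with a default for unlisted
symbols; the default may be the `RAISE` sentinel, making unknown symbols an
error rather than a silent substitution. Shipped tables: Kyte–Doolittle
hydropathy (the standard 20-value scale), formal side-chain charge
(K = R = +1, D = E = −1, all others 0 — histidine is taken as uncharged at
neutral pH, a documented and overridable simplification), and Zamyatnin
residue volumes (Å³). They live as two-column data files rather than code so
their provenance is explicit and users can swap them.

The AAindex1 parser reads the flat-file format offline (records delimited by
`//`, `H`/`D`/`I` line keys, two rows of ten values in the canonical
A R N D C Q E G H I / L K M F P S T W Y V column order). `NA` values are
recorded as missing and replaced by the mapping default on application.
Online retrieval is deliberately not implemented.

Discretization conventions:

- **Thresholds** are half-open: a residue whose value equals a threshold is
  assigned the class above it. One convention had to be picked; this one is
  asserted in the tests.
- **Linear** places k − 1 thresholds at min + i·(max − min)/k; k = 1 is the
  constant mapping and a degenerate (all-equal) value range is an error.
- **k-means** (1-D, over the ≤ 20 distinct property values) draws the first
  center from a seeded generator and takes remaining centers by
  farthest-point selection, then runs Lloyd iterations until assignments are
  stable (default cap 100). Clusters are relabeled 0..k−1 by increasing
  centroid, so equal values always share a class and the labeling is
  invariant to residue-name permutation.

## Features and windows

A feature applies a function either to the whole sequence (window 0) or to
every contiguous stretch of length w (step 1, half-open 0-based windows),
yielding exactly L − w + 1 values; windowed stages must return scalars. A
window longer than the sequence raises in strict mode and yields an empty
profile with a warning in lenient mode. Chaining flattens stages, so
composition is associative by construction.

Built-in metrics: sum, mean, Shannon entropy (0·log 0 := 0; base 2 by
default), and net absolute value |Σx|/L — the absolute value is taken
*after* averaging, which is the quantity the charge–hydropathy analysis
needs (a sequence with balanced + and − charges has net absolute charge near
0, not mean |charge| near 1).

The order/disorder boundary ⟨H⟩_b = (⟨R⟩ + 1.151)/2.785 applies to mean
hydropathy on the normalized Kyte–Doolittle scale (x + 4.5)/9. The constants
come from the classic charge–hydropathy literature on intrinsic disorder;
they live in the demo layer and are arguments, not hard-coded truths.

## Recurrence quantification

The recurrence plot of a sequence embedded in dimension m (overlapping
m-tuples, lag 1) marks pairs of tuples within radius ε under one of four
metrics: identity (exact equality — the only metric defined for raw
symbols; the radius value is ignored so that parameter sweeps over
metric × radius remain well-defined), taxi (L1), euclid (L2) and sup (L∞).
The plot is symmetric with an all-true main diagonal (line of identity,
LOI). Cost is O(N²m) per plot; `rqa_features` groups parameter sets by
(metric, radius, dim) and builds each plot once, sharing it across
minimum-line-length settings, with results identical to independent
evaluation. Windowed RQA profiles reuse the feature-window machinery.

Measures (all in [0, 1], 0 when their denominator is empty):

- **RR** = off-diagonal recurrent cells / (N² − N). The LOI is excluded as
  trivially recurrent.
- **DET** = off-diagonal recurrence points on diagonal lines of length ≥ ℓ_d
  / off-diagonal recurrence points (default ℓ_d = 2, the smallest
  non-trivial line).
- **PAL** = recurrence points on antidiagonal lines of length ≥ ℓ_p / all
  recurrence points. Antidiagonals cross the LOI, so main-diagonal cells
  genuinely participate in palindromic geometry; they are included in both
  numerator and denominator by default, with an `off_diagonal`
  normalization option that excludes them from both.

**Cyclic line closure.** Lines are counted on the N cyclic diagonal classes
j − i ≡ o (mod N) and antidiagonal classes i + j ≡ s (mod N); runs may
wrap across the plot edge within their class. This was a deliberate design
choice over open-ended lines: with open lines the two corner cells of the
plot sit on lines of length 1, so even a perfectly recurrent (constant)
sequence could never reach DET = 1 — a pure boundary artifact. Under cyclic
closure an all-true plot attains DET = PAL = 1 exactly, every cell belongs
to exactly one line of each family (no double counting), and the class
o = 0 is precisely the LOI, which keeps its exclusion from RR/DET clean.
The closed-form anchors (ABBA: RR = 1/3, DET = 0, PAL = 1/2; ABAB:
DET = 1; constant: all 1; all-distinct: all 0) and exact agreement with an
independently written triple-loop reference over randomized sweeps are
asserted in the test suite. Wrap-around affects values only when a run
touches both ends of its cyclic line, so typical biological sequences give
values close to open-line conventions; comparisons with other RQA software
should nevertheless account for this convention and for PAL's inclusion of
the LOI.

## n-grams and the power-law fit

Pattern matching is gap-free; overlapping matches are all reported, and
inexact matching uses the same four metrics as RQA applied element-wise
across the pattern window. n-gram counting is a single pass per sequence;
totals satisfy Σ counts = Σ_i max(0, L_i − n + 1) exactly. A
declared-alphabet mode materializes all |Σ|ⁿ keys (zero counts included)
behind a 10⁶-cell cap, since dense bigram profiles are memory-hungry.

The Zipf fit is a discrete maximum-likelihood power law on the *multiset of
n-gram counts* (the count distribution, the statistically standard choice;
rank–frequency pairs are exported separately for log-log plotting):
the exponent maximizes −n·log ζ(α, x_min) − α·Σ log x by bounded scalar
minimization (α ∈ (1, 25]); x_min is either fixed (reproducible analyses)
or chosen to minimize the Kolmogorov–Smirnov distance between empirical and
fitted tail CDFs over all observed candidate values. Degenerate tails
(fewer than two points, or a single distinct value) are errors, not NaNs.
The companion sampler inverts the exact discrete CDF (precomputed to 10⁶,
zeta-tail bisection beyond), so exponent-recovery checks test the estimator,
not an approximation of the distribution.

## Feature-space Fisher scan

Given bounds (by default the bounding box of the pooled points), axis ranges
n and m are divided into windows of size (n/k₁, m/k₂) sliding with step
(n/(k₁·l₁), m/(k₂·l₂)); each of the (k₁·l₁)×(k₂·l₂) cells hosts the window
centered at its center, clipped to the bounds at the edges (keeping the
heat-map field complete). Window membership is half-open with the global
upper bounds closed, so every point belongs to a well-defined set of
windows and a disjoint tiling (l = 1) partitions the data exactly.

Each window's table is (in-window set 1, in-window set 2, outside set 1,
outside set 2) — local composition against the *complement*, which is the
orientation whose margins are the set sizes and hence admits an exact test.
The two-sided Fisher p-value is computed by direct hypergeometric
enumeration over the window-total support (log-binomial weights via
`gammaln`), summing all tables whose point probability is ≤ the observed
one with relative tolerance 1e−7 on the comparison; a zero margin gives
p = 1, and a modal observed table gives exactly 1. The implementation is
cross-checked exhaustively against `scipy.stats.fisher_exact` for every
table with grand total ≤ 40 in the test suite. Raw p-values are reported
per cell (matching the log-p heat-map use case); Bonferroni adjustment over
the cell count is available as an option — with heavily overlapping windows
it is conservative.

## Synthetic data

The fixture generator draws residues i.i.d. from weighted alphabets with
lengths uniform in a range, fully determined by a seed. Preset compositions:
`uniform`; `hydrophobic` / `hydrophilic` (large apolar residues ILVFWYM,
resp. small polar/charged STNQGDEKR, enriched 4×) emulating the contrast
between amyloid-forming and non-forming peptide collections; `disorder` /
`order` (D/E/K/R 5×, S/P/Q/G 3× vs I/L/V/F 5×, A/M/W/Y/C 3×, others 0.5×)
emulating compositional bias of intrinsically disordered vs folded
proteins. Default lengths are peptide-scale (10–50); the charge–hydropathy
demo uses 20–60 so per-sequence means are stable.

What this establishes — and what it does not: i.i.d. sampling reproduces
*compositional* contrasts, so it validates the mapping → feature → test
machinery end to end (separated populations are detected, same-composition
nulls are not). It has no positional structure: no real repeats, motifs,
domains or correlations along the chain, so RQA and n-gram results on
fixtures exercise correctness, not biological effect sizes, and passing
tests do not certify behavior on real proteomes.

## Problem sizes and numerical choices

The randomized verification sweeps use 200 sequences of length 5–40 for the
RQA/oracle comparison, the exhaustive Fisher sweep covers all ~1.4·10⁵
tables with total ≤ 40, power-law recovery uses 20 replicates of 10⁴
samples, and the scan checks use 500 + 500 points (alternatively 200 + 200
generated sequences) on the default 25×25 grid — sizes at which every check
runs in seconds to about a minute on a single core while keeping estimator
noise far below the asserted margins. Distance comparisons use `<= radius`
exactly (no epsilon); recurrence plots are exact boolean matrices; p-values
are clipped to (0, 1]; empty windows report NaN local ratios; all
stochastic tests fix their generator seeds.

## Known limitations

- Identity is the only metric for raw symbols; numeric metrics require a
  prior mapping.
- Time-delay embedding uses lag 1 only; laminarity/trapping-time and other
  RQA measures are out of scope.
- The power-law fit assumes an integer-valued tail; it does not implement
  continuous MLE or likelihood-ratio comparisons against alternative
  distributions.
- The Fisher scan treats sequences as single points (per-sequence scalar
  features); windowed-profile clouds per sequence are not supported.
- Charge is pH-independent; AAindex2/AAindex3 matrix formats are not
  parsed.
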