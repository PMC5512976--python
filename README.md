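# protquant

Alignment-free, quantitative analysis of protein sequences.

Most sequence-analysis tooling is built on substitution matrices and
alignments. `protquant` takes the complementary route: residues are mapped to
physico-chemical properties (charge, hydropathy, volume, or any AAindex1
scale), and sequences become points or profiles in a quantitative feature
space where they can be compared without aligning them. The package is aimed
at computational biologists who want to characterize, cluster or compare
protein sequence sets — e.g. disordered vs ordered proteins, amyloidogenic vs
non-amyloidogenic peptides, or real vs model-generated sequences.

## What it computes

**Property mapping and reduced alphabets.** A `PropertyMapping` converts
symbols to values (shipped Kyte–Doolittle hydropathy, formal charge and
residue-volume tables; an offline AAindex1 flat-file parser; user tables),
and can be discretized into reduced alphabets by explicit thresholds,
equal-width bins, or 1-D k-means over the property values.

**Chainable features.** A `Feature` wraps any function of a list of elements;
with window *w* > 0 it is evaluated on every length-*w* stretch, giving a
profile of length *L* − *w* + 1. Features chain (`mapping → aggregate`), and a
`FeatureSet` applies many features across a `SequenceSet`. Built-ins: sum,
mean, net absolute value, Shannon entropy.

**Recurrence quantification (RQA).** For a sequence embedded in dimension
*m*, the recurrence plot is the N×N boolean matrix R(i,j) = [d(v_i, v_j) ≤ ε]
(identity/L1/L2/L∞ metrics). From it:

- recurrence rate `RR = #{off-diagonal recurrent cells} / (N² − N)`,
- determinism `DET` — the fraction of off-diagonal recurrence points on
  diagonal lines of length ≥ ℓ (repeated subsequences),
- **palindromism** `PAL` — the fraction of recurrence points on
  *antidiagonal* lines of length ≥ ℓ, a measure of reversed (palindromic)
  repeats. For the exact palindrome `ABBA`, PAL = 1/2 while DET = 0.

**n-grams and Zipf's law.** Gap-free pattern matching (exact or within a
similarity radius), single-pass n-gram counting over a set, rank–frequency
tables, and a discrete maximum-likelihood power-law fit
P(x) ∝ x^(−α), x ≥ x_min (zeta-normalized, KS-based automatic x_min).

**Feature-space comparison.** Two sequence sets projected to a 2-D feature
space are compared on a (k₁·l₁)×(k₂·l₂) grid of cells: a window of size
(range/k₁, range/k₂) is centered at each cell (step range/(k·l), i.e. windows
overlap by factor l), and each window's in/out composition is tested against
the global composition with a two-sided Fisher's exact test.

**Charge–hydropathy (Uversky) analysis.** Per-sequence mean net absolute
charge ⟨R⟩ vs mean normalized hydropathy ⟨H⟩, with the classic boundary
⟨H⟩_b = (⟨R⟩ + 1.151)/2.785 separating ordered from intrinsically disordered
proteins.

All demos and tests run on synthetic sequence sets from the built-in,
seed-deterministic fixture generator — no downloads required.

## Worked example

```bash
protquant fixtures --n 5 --length-min 12 --length-max 20 \
    --composition disorder --seed 3 --label idp -o idp.fasta
protquant uversky idp.fasta -o uversky.tsv
protquant rqa idp.fasta -o rqa.tsv
```

`uversky.tsv` (sequences drawn from a charged, disorder-prone composition):

```
identifier	net_abs_charge	mean_hydropathy	boundary	side
idp_0	0.0526316	0.178363	0.432184	disordered
idp_1	0	0.376852	0.413285	disordered
idp_2	0.176471	0.179085	0.47665	disordered
idp_3	0.0588235	0.265359	0.434407	disordered
idp_4	0	0.319608	0.413285	disordered
```

Each sequence's mean normalized hydropathy (0.18–0.38) lies below the
boundary value computed from its net charge (0.41–0.48), so all five are
called disordered — as expected for D/E/K/R/S/P/Q/G-rich sequences.

`rqa.tsv` (identity metric, m = 1, minimum line length 2):

```
identifier	recurrence	determinism	palindromism
idp_0	0.0877193	0.133333	0.244898
idp_1	0.030303	0	0
idp_2	0.102941	0	0.155556
idp_3	0.0735294	0.4	0.108108
idp_4	0.102941	0.142857	0.377778
```

For `idp_0` (`ERPDKKEQDHKKPRTEPQF`), 8.8 % of position pairs recur; 13 % of
those recurrences sit on diagonal lines (repeated bigrams such as `KK…KK`)
and 24 % of all recurrence points lie on antidiagonal lines (reversed
repeats such as `KKPR…PRKK` read backwards).

The same pipelines are available from Python:

```python
from protquant import RQAConfig, rqa_measures
res = rqa_measures(list("ABBA"), RQAConfig("identity", 0, 1))
# res.recurrence = 0.333..., res.determinism = 0.0, res.palindromism = 0.5
```

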