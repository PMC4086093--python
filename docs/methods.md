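# Methods

## Spaced-word profiles

A pattern is a binary mask over match (`1`) and don't-care (`0`)
positions; its *weight* is the number of match positions. Sliding the
pattern over a sequence, every window contributes one spaced word — the
residues at the match positions only. Profiles store the relative
frequency of each observed word; they are sparse (only observed keys),
which is mathematically identical to the dense vector over all
|Σ|^weight words. Counting is single-strand, forward, with overlapping
windows at every position; there is no reverse-complement folding. A
window with a non-alphabet character (N, X, …) at a *match* position is
skipped entirely; a don't-care position accepts any character, matching
the wildcard semantics.

Two profile distances are provided:

* **Euclidean**: √Σ (f_a(w) − f_b(w))² over the union of observed words.
* **Jensen-Shannon**: JS(A,B) = H((A+B)/2) − (H(A)+H(B))/2 with Shannon
  entropy in bits, so the value is bounded in [0, 1]; 0·log 0 := 0. The
  implementation returns the divergence itself; the square root (which is
  a true metric) is available via `sqrt=True` / `--js-sqrt`. Base-2
  entropy is a scale convention only.

The distance between two sequences is the arithmetic mean of the
per-pattern distances over the whole pattern set; it is invariant to the
order of the patterns.

### Pattern generation

Random patterns of a given weight and length are drawn uniformly over
the interior positions with the first and last positions fixed to `1`:
leading or trailing don't-cares only shift the window without changing
the induced word multiset, so fixing the ends removes redundant
duplicates from the sample space. User-supplied patterns keep trailing
don't-cares, but a leading `0` is canonicalized away with a warning.
Duplicate masks are rejected; requesting more distinct masks than exist
is an error that states the maximum.

Default parameters: 10 patterns; weight
`w = clamp(⌈log_|Σ| L̄⌉ + 2, 4, 14)` for DNA and
`clamp(⌈log_20 L̄⌉ + 1, 2, 6)` for protein, where L̄ is the mean input
length, with pattern length 2w (equal numbers of match and don't-care
positions). The log-of-length rule targets roughly one expected
background word match per position: with w ≈ log_|Σ| L̄ a random spaced
word has probability |Σ|^−w ≈ 1/L̄ per window. The +2 (DNA) / +1
(protein) offset biases toward specificity. Ten patterns is a
run-time-friendly default; accuracy keeps improving up to roughly 50–70
patterns at proportional cost, so `-n` is exposed.

## kmacs

The k-mismatch matching statistic of x against y at position i is the
longest L with Hamming(x[i..i+L), y[j..j+L)) ≤ k for some j. Ambiguity
codes never match anything, including themselves. The average L(x,y) of
the statistics is converted to a distance by

d(x,y) = ln|y| / L(x,y) − ln|x| / L(x,x),   L(x,x) = (|x|+1)/2,

symmetrized as (d(x,y)+d(y,x))/2. The normalization is the ACS-style
log-length form: ln|y|/L(x,y) discounts matches expected by chance in a
longer subject, and the analytic self term makes d(x,x) = 0 hold exactly
(a tested identity, since the self statistics are |x|−i with mean
(|x|+1)/2). Natural log is a scale convention. If no character of one
sequence occurs in the other, L = 0 and the distance is capped at
2·ln(max(|x|,|y|)) with a warning.

### Computation modes

* **exact** — the definition, evaluated exhaustively. The |x|×|y|
  comparison grid is scanned one anti-diagonal at a time: along a
  diagonal the statistic at a start offset is the distance to the
  (k+1)-th mismatch at or after it, computed vectorized from the
  diagonal's mismatch positions. A single pass fills both directions
  (x vs y and y vs x), since a window's Hamming distance is symmetric.
  Time O(|x|·|y|) with small constants; an independent triple-loop
  oracle checks it in the tests.
* **heuristic** — for each query position, the longest *exact* match is
  found by binary search in a suffix array of the subject (built by
  numpy prefix doubling), then extended greedily across up to k
  mismatches by chained longest-common-extension steps. All subject
  positions attaining the maximal exact match are tried, capped at 50
  candidates to keep the worst case near-linearithmic; the best
  extension wins. Every chained extension is a feasible ≤k-mismatch
  match, so the heuristic never exceeds the exact statistic, and at
  k = 0 the two coincide.
* **auto** (default) — exact up to 1 Mb of total input, heuristic above.

k ranges over [0, 100] with default 5 — a run-time compromise: larger k
(≳10) tends to improve tree quality slightly at higher cost.

## Neighbour Joining

Standard Saitou–Nei agglomeration with the Studier–Keppler Q-criterion
Q_ij = (r−2)d_ij − R_i − R_j. Ties in Q are broken by the
lexicographically smallest (i, j) pair, making the output deterministic.
The tree is left unrooted, represented with a trifurcating root for
n ≥ 3 (two leaves joined by a single split edge for n = 2). Negative
branch-length estimates are clamped to zero and logged; on additive
matrices no clamping occurs and NJ provably recovers the generating
topology and branch lengths (verified to 1e-9 in the tests).

## Synthetic data

The simulator emulates divergence by independent per-site substitutions:
each site is replaced with probability r by a *different* symbol chosen
uniformly, plus an optional independent per-site deletion probability
(default 0) for unaligned-sequence scenarios. It deliberately omits rate
heterogeneity, transition/transversion bias, indel length distributions
and back-substitution corrections: the tests built on it show that the
estimators recover the *ordering* of divergence levels (rank correlation
with the substitution rate), not that their values equal any
model-corrected evolutionary distance on real data. Additive test
matrices come from random binary trees with branch lengths uniform in
(0.1, 2.0), whose leaf path-length matrices satisfy the four-point
condition by construction.

Test and acceptance problem sizes — 5-kb ancestors, 10 replicates over
substitution rates 0.05–0.40, a few hundred random pairs of a few
hundred nt — were chosen so the full suite runs in a couple of minutes
while leaving the statistical checks well-powered.

## Numerical and design choices

* JS divergence is clipped to [0, 1] after evaluation to absorb float
  round-off at the boundary.
* Phylip output is the relaxed dialect (full space-free names padded to
  ≥10 characters, six decimals); spaces in names become `_`, and a
  collision after that replacement is an error. FASTA input strips gap
  (`-`, `.`) and stop (`*`) characters — the methods are alignment-free,
  so alignment decoration is noise. Duplicate FASTA names are
  uniquified with `_2`, `_3`, … and a warning.
* Alphabet detection: DNA if ≥95% of residues (ignoring N/X) are
  A/C/G/T, protein otherwise; a CLI flag overrides.
* The pattern-file dialect is one 0/1 mask per line with `#` comments;
  masks of different weight/length may be mixed.
* CLI runs without an explicit `--seed` draw one from system entropy and
  log it, so any run is reproducible after the fact; identical
  invocations with the same seed are byte-identical.
* No hard input-size limits are imposed; the kmacs command logs a
  warning when the exact quadratic mode is likely to be memory-hungry
  and suggests the heuristic.

## Known limitations

* The heuristic underestimates matching statistics (hence overestimates
  distances) when the best k-mismatch match does not start with the
  longest exact match; accuracy degrades for large k on short
  sequences. Use `--mode exact` where feasible.
* Spaced-word distances and kmacs distances are ad-hoc measures without
  an explicit substitution model; they are monotone in divergence but
  not calibrated to substitutions per site.
* Profiles are single-strand; genomic comparisons where strand is
  unknown would need reverse-complement folding, which is out of scope.
* The suffix array is rebuilt per sequence pair and direction; an
  all-pairs run on many long sequences recomputes work that a
  generalized index could share.
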