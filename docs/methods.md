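# Methods

## Scoring model

A family consensus `S` (length `N`, alphabet {a,t,c,g}, code a=1, t=2,
c=3, g=4) is represented by a 16 × (N−1) dinucleotide matrix plus an
all-ones first column. For column `k` (consensus positions k−1, k) the row
of the observed pair `l = i + 4(j−1)` holds the standardized score of a
pair-match indicator under the background pair frequency `f(i,j)`:

    m(l,k) = (1 − f) / sqrt(f (1 − f)) = sqrt((1 − f)/f)

and the remaining 15 rows are 0. `f(i,j) = p(i)·p(j)` is the product of
the consensus mononucleotide frequencies — the same background that
weights the matrix summary statistics — and is clamped to
`[1/(4N), 1 − 1/(4N)]` so that degenerate compositions (homopolymers)
never produce an infinite or undefined score. The entry is strictly
decreasing in `f`: rarer pairs are worth more.

The first column is set to 1 in all 16 rows. It is consumed whenever the
aligner has no dinucleotide context (see below), a situation in which the
pair identity is undefined, so a row-independent value is the only
consistent choice.

Two scalars summarize a matrix:

* `R² = Σ m(l,k)²`, the score mass. For a freshly built matrix the sum
  over the full grid and the sum over the consensus-pair support coincide
  (all other entries are 0). The transform below conserves the
  support-restricted sum — conserving the full-grid sum instead is
  provably impossible for the working `Kd` range: with 16(N−1) cells and
  weights `p1(l)p2(k)`, Cauchy–Schwarz bounds `|Kd| ≤ sqrt(R²·Σ(p1p2)²)`
  ≈ 0.97 for a uniform-composition consensus, so no matrix with the raw
  score mass spread over the full grid can reach `Kd = −1`.
* `Kd = Σ m(l,k) p1(l) p2(k)` over the full grid, with
  `p1(l) = p(i)p(j)` and `p2(k) = 1/(N−1)` — the expected score a column
  contributes when random background sequence is aligned.

## Kd transform

`transform_pwm` applies `m′ = α·m + β` to all 16 rows of the pair columns
(the first column is untouched). β shifts every mismatch row, making the
expected per-column score of random sequence equal to the target; α
rescales the match entries so the support-restricted `R²` is conserved.
Substituting `β = Kd* − α·Kd` into the `R²` constraint yields a quadratic
in α solved in closed form; the positive root is taken (the larger one if
two exist, which preserves the match-score sign). The transform is exact
to 1e−9 by construction and invertible: re-targeting back to the original
`Kd` recovers the original entries.

Feasibility: the affine family reaches a bounded `Kd` interval whose
half-width is roughly the RMS of the match entries (≈ 3.9 for uniform
composition); an unreachable target raises an error naming the interval.
A fully degenerate matrix (every match entry equal to the current `Kd`,
e.g. a 2-nt homopolymer) reaches only `Kd = ±sqrt(R²/(N−1))`.

`Kd` behaves like an expected-score (E-value-like) parameter for boundary
placement: at 0 a local alignment extends through random sequence as an
unbiased random walk and drifts to the full matrix length; at −1 each
random column costs about one unit against match gains of ≈ +4, and
boundaries track the inserted copy; at −2 divergent copy ends are clipped.
The package default is −1.0.

## Alignment

Local alignment of a genome window against the matrix-column axis uses the
three-state affine-gap recurrence (match state F; gap-in-matrix state Fx
consuming genome symbols; gap-in-genome state Fy consuming columns), gap
open `d = 32`, extension `e = 8`. The non-standard element is the score of
a diagonal step: it is the matrix entry for the pair (previous genome
symbol consumed on the path, current symbol) — which requires knowing,
during the forward pass, whether the predecessor cell's path consumed the
previous symbol by a diagonal. F-state cells are only ever created by
diagonals, so tracking a per-cell "empty" flag suffices. The first
consumed symbol of an alignment, and any diagonal directly after a gap in
*either* sequence, has no pair context and scores the first column (+1);
the broken-context rule is applied symmetrically to both gap types.

Tie-breaking is fixed (context diagonal > diagonal from Fx > diagonal from
Fy > fresh start > empty; earliest row-major endpoint) so tracebacks are
deterministic and `score_path` — an independent left-to-right re-scorer —
reproduces `f_max` bit-exactly. Scores are compared exactly (no epsilon):
all values are finite sums of matrix entries. The DP is validated
bit-exactly against a brute-force enumerator of all monotone gapped paths
on small instances.

One boundary case deserves note: a path whose running score returns to
exactly 0 is treated as restartable (the cell is marked empty and a
following diagonal scores the first column). With real-valued matrices an
exact interior zero has measure zero; the convention only matters for
hand-constructed integer matrices.

## Significance and scanning

`Z = (Fmax − mean)/sd` against `n_shuffles = 200` single-nucleotide
Fisher–Yates shuffles of the window (sample variance, ddof = 1, floored at
1e−12). Mononucleotide shuffling preserves composition while destroying
the dinucleotide correlations the matrix rewards — exactly the null the
statistic needs. The shuffle RNG stream is derived from (seed, CRC32 of
the window), so Z is reproducible and independent of scan order.

The scanner slides a window of length `N` at `step = 10`, computes the Z
series per strand (reverse complement handled by coordinate mirroring),
selects local maxima above `Z0 = 10.0` (plateaus: leftmost index; series
ends treated as −inf), and refines each by full traceback, reporting the
alignment's genome range. `Z0 = 10` matches a false-positive calibration
of roughly one hit per tens of Mb of shuffled sequence per family; the
acceptance suite verifies zero hits on 2 Mb of i.i.d. sequence.

Two scan-cost controls exist, both statistically conservative on
stationary backgrounds:

* `NullModel(cache=True)` memoizes shuffle statistics on the exact base
  count vector of the window (off by default: it is a literal no-op only
  when compositions repeat).
* `null_every = k` recomputes the shuffle statistics at every k-th window
  and reuses them in between. With 10-nt steps, consecutive windows share
  all but 10 symbols, so their null means drift far slower than a null
  standard deviation; simulation and calibration runs here use k = 50–100
  on i.i.d. backgrounds. The default (k = 1) is the exact per-window null.

Windows containing non-ACGT symbols are skipped (the scoring alphabet is
strictly 4-letter).

## Post-processing

* Overlap resolution: greedy by descending Z; a hit is kept unless it
  overlaps an already-kept hit by more than 20% of the *shorter* of the
  two (the strictest symmetric reading; configurable). Ties: longer, then
  leftmost. The rule is deterministic and idempotent.
* Low complexity: a DUST-style symmetric triplet masker (64-nt windows,
  half-window step; within each window the maximum-scoring sub-interval
  under `S/(L−1)`, `S = Σ c_t(c_t−1)/2`, is masked when it exceeds 2.0 —
  "level 20" in the conventional 10× units). Hits whose sequence is more
  than 10% masked are discarded. The masker is reimplemented internally
  so no external binary is needed; the window/threshold defaults are
  stated assumptions, configurable to match other DUST dialects.
* `compare_hit_sets` cross-classifies two annotations per family
  (same-family overlap / other-family overlap / unique, both directions)
  at the same 20% overlap fraction.

## Simulated benchmark

`simdata` emulates the study conditions used throughout the tests:

* Substitutions: `round(rate × length)` positions drawn uniformly *with
  replacement*; each draw replaces the current base with one of the three
  alternatives (guaranteeing a change per draw, while repeat draws and
  back-mutations keep realized divergence below the nominal rate — at
  1.0 subs/position about 55% of positions end up changed).
* Indels: a uniform count (2–5; 2–3 in the two-family classification
  setting) of single-nucleotide insertions or deletions at uniform
  positions. Indel length is fixed at 1 nt, the smallest-assumption
  choice, configurable.
* Backgrounds: i.i.d. sequence at specified GC (default 0.5) — the
  download-free default — or a shuffle of a user-supplied chromosome.
* Placement: uniform non-overlapping insertion with minimum spacing of
  twice the template length, so detected/false-positive attribution is
  unambiguous.
* Conditions: full-length copies at 0.25/0.5/0.75/1.0 substitutions per
  position; 150-nt truncations at the same rates; prefixes of 75/50/25/17%
  of the template at rate 0.25; and interleaved copies of two families for
  classification. The reference condition uses 300 copies per cell with a
  293-nt template; the acceptance suite runs 50 copies per cell (25 in the
  acceptance script) — chosen as the smallest samples at which the rate
  and boundary-length contrasts of interest are stable, with problem sizes
  recorded alongside each reported number.

What the synthetic benchmark does *not* emulate: real genomic background
(repeat density, GC heterogeneity, satellite DNA), transition/transversion
bias and CpG-driven C→T hypermutation, A-tail length variation, and real
family structure. Passing tests therefore demonstrate the machinery's
correctness and its qualitative parameter response (detection falling with
divergence, boundary accuracy peaking near `Kd = −1`, false positives at
calibration level), not organism-level annotation counts. On i.i.d.
backgrounds with a synthetic template, full-length detection is 100% at
0.25–0.5 subs/position and truncated detection declines monotonically with
rate; the decline is steeper than for the reference conditions on real
SINE consensuses, whose skewed composition gives rarer, higher-scoring
dinucleotides.

## Consensus-library identity

`pid1_identity` computes percent identity on a global alignment (match +1,
mismatch −1, gap open −2, extend −0.5; marginally cheaper end gaps so
co-optimal gap runs settle at the termini) as
`100 × identical / (aligned + internal gap columns)`, terminal gap columns
excluded. Arguments are ordered canonically before aligning so the measure
is exactly symmetric under alignment tie-breaking. The scoring scheme is a
documented default: identity summaries of a given library shift by a few
points under other schemes. Libraries are filtered to ≤ 600 nt on loading.

## Numerical and engineering notes

* DP kernels are numba-compiled; a 293 × 293 alignment costs ~0.45 ms, a
  200-shuffle null ~0.1 s.
* All randomness flows from explicit seeds; per-window substreams are
  derived from (root seed, window content) so results are independent of
  evaluation order and parallel decomposition.
* Matrices serialize to a plain-text format with `repr`-exact floats;
  round-trips are bit-identical.
* BED output is 0-based half-open (score column = round(100·Z)); GFF3 is
  1-based inclusive. Output headers carry version, full configuration and
  seed.

## Known limitations

* A single-consensus matrix carries one observation per column;
  alignment-derived (multi-sequence) matrices would sharpen both scores
  and the feasible `Kd` range. A construction hook exists but is untested
  surface.
* The scanner is per-chromosome, per-family; whole-genome orchestration is
  left to the caller (the problem is embarrassingly parallel).
* Windowed scanning caps detected copy length at the consensus length;
  tandem or nested insertions longer than `N` are reported piecewise.
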