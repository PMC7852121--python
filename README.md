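# divscan

Library-based detection of **highly divergent dispersed repeats** — SINEs
in particular — using position weight matrices that encode the
*correlation of neighboring nucleotides*.

## The problem

SINEs (short interspersed nuclear elements, 100–600 nt) accumulate
substitutions and indels rapidly after insertion. Classical
similarity-search annotation (consensus vs. genome alignment) loses old
copies because per-base identity decays toward background. The signal that
decays more slowly is the *joint* identity of adjacent base pairs: if
neighboring symbols carry mutual information, matching 20 disjoint
dinucleotides is far more surprising than matching 40 single bases. divscan
scores genomes against a family consensus at the dinucleotide level and
recovers copies that per-base methods miss.

## The model

For a consensus `S` of length `N` with base probabilities `p(i)`:

* **Matrix.** 16 rows (dinucleotides, `l = i + 4(j−1)` with code
  a=1, t=2, c=3, g=4) × columns `k = 2..N`. The consensus pair of column
  `k` scores `m(l,k) = (1−f)/√(f(1−f))` with background pair frequency
  `f = p(i)p(j)`; the other 15 rows are 0. Column 1 is all ones and is the
  score used whenever pair context is unavailable.
* **Transform.** An affine map `m′ = αm + β` (α > 0) retargets the
  matrix's expected per-column score under background,
  `Kd = Σ m′(l,k) p(i)p(j) / (N−1)`, while conserving `R² = Σ m²` over the
  consensus-pair support. `Kd` plays the role of an expected score: near 0,
  local alignments drift to full matrix length; at −1 (the working
  default), boundaries track the true insert; at −2, alignments clip.
* **Alignment.** Affine-gap local alignment (open 32, extend 8) of a
  genome window against the matrix-column axis. A diagonal step scores the
  dinucleotide (previous consumed symbol, current symbol); after a gap in
  either sequence — and at the alignment start — the context is broken and
  the step scores column 1.
* **Significance.** `Z = (Fmax − mean)/sd` against 200
  composition-preserving shuffles of the window.
* **Scanning.** A consensus-length window slides at 10-nt steps on both
  strands; local maxima of the Z series above `Z0 = 10` are refined by
  full traceback. Cross-family overlaps > 20% keep only the largest-Z hit,
  and hits > 10% low-complexity (DUST-style triplet masking) are dropped.

## Worked example

```python
from divscan import (Consensus, GenomicWindow, NullModel, build_pwm,
                     transform_pwm, align, z_score, random_consensus)

template = random_consensus(293, seed_or_rng=20210202)   # synthetic family
pwm = transform_pwm(build_pwm(Consensus("fam", template)), kd_target=-1.0)
print(round(pwm.r2, 1), round(pwm.kd, 6))

window = GenomicWindow(template)                         # a perfect copy
aln = align(window, pwm)
print(round(aln.f_max, 1), aln.s1_range)

null = NullModel(n_shuffles=200, rng_seed=3)
print(round(z_score(window, pwm, null), 1))
```

prints

```
4390.4 -1.0
1123.9 (0, 293)
257.3
```

i.e. the transformed matrix hits `Kd = −1` exactly while keeping its score
mass (`R² ≈ 4390`), a perfect copy aligns end to end with `Fmax ≈ 1124`,
and that score sits ≈ 257 null standard deviations above the shuffle null —
compare the scan threshold `Z0 = 10`.

The same pipeline from the shell:

```bash
divscan simulate --kind full_length --templates fam.fa --rate 0.25 \
        --copies 50 --seed 7 --out-prefix sim
divscan scan --consensus fam.fa --genome sim.full_length_subs0.25.fa \
        --kd -1.0 --z0 10 --shuffles 200 --seed 17 --null-every 50 \
        --out hits.bed
divscan evaluate --hits hits.bed --truth sim.full_length_subs0.25.truth.bed
```

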