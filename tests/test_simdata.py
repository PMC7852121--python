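import numpy as np
import pytest

from divscan import (EvaluationReport, HitSet, MutationSpec, ScanHit,
                     evaluate, iid_background, make_dataset, mutate_copy,
                     random_consensus)
from divscan.simdata import SimulatedChromosome


def hit(start, end, z, family="fam"):
    return ScanHit("c1", start, end, "+", family, z, 0.0)


class TestMutateCopy:
    def test_zero_rate_zero_indels_identity(self):
        t = random_consensus(100, 1)
        assert mutate_copy(t, MutationSpec(0.0, (0, 0), seed=1)) == t

    def test_deterministic_given_seed(self):
        t = random_consensus(100, 1)
        a = mutate_copy(t, MutationSpec(0.5, (2, 5), seed=9))
        b = mutate_copy(t, MutationSpec(0.5, (2, 5), seed=9))
        assert a == b

    def test_length_bounds_with_indels(self):
        t = random_consensus(100, 1)
        for seed in range(30):
            out = mutate_copy(t, MutationSpec(0.25, (2, 5), seed=seed))
            assert 95 <= len(out) <= 105

    def test_rate_one_divergence_below_one(self):
        # positions drawn with replacement: repeat draws + back-mutation
        # leave ~ 1 - (3/4)(1 - e^{-4/3}) of positions... empirically the
        # distinct-positions fraction is ~0.634 and realized divergence is
        # lower still
        t = random_consensus(2000, 2)
        rng = np.random.default_rng(3)
        out = mutate_copy(t, MutationSpec(1.0, (0, 0)), rng)
        ham = sum(a != b for a, b in zip(t, out)) / len(t)
        assert 0.45 < ham < 0.634

    def test_distinct_draw_positions_fraction(self):
        # direct simulation of the with-replacement draw process
        rng = np.random.default_rng(4)
        n = 1000
        frac = np.mean([len(set(rng.integers(0, n, n).tolist())) / n
                        for _ in range(50)])
        assert frac == pytest.approx(1 - (1 - 1 / n) ** n, abs=0.01)

    def test_empty_template_rejected(self):
        with pytest.raises(ValueError):
            mutate_copy("", MutationSpec(0.1, (0, 0)))


class TestMakeDataset:
    def test_full_length_conservation(self):
        t = random_consensus(200, 5)
        (chrom,) = make_dataset("full_length", {"fam": t}, rates=[0.25],
                                copies_per_rate=10, background_length=9000,
                                seed=11)
        assert len(chrom.truths) == 10
        total_copy = sum(e - s for s, e, _, _ in chrom.truths)
        assert len(chrom.seq) == 9000 + total_copy
        for s, e, fam, _ in chrom.truths:
            assert 0 <= s < e <= len(chrom.seq) and fam == "fam"

    def test_truths_non_overlapping_and_spaced(self):
        t = random_consensus(150, 6)
        (chrom,) = make_dataset("full_length", {"fam": t}, rates=[0.5],
                                copies_per_rate=8, seed=3)
        ivs = sorted((s, e) for s, e, _, _ in chrom.truths)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert s2 - e1 >= 2 * len(t)

    def test_truncated_uses_prefix(self):
        t = random_consensus(293, 7)
        (chrom,) = make_dataset("truncated", {"fam": t}, rates=[0.0],
                                copies_per_rate=3, seed=2)
        # rate 0 keeps the prefix recognizable up to indels
        s, e, _, _ = chrom.truths[0]
        assert 145 <= e - s <= 155

    def test_small_part_fractions(self):
        t = random_consensus(293, 8)
        chroms = make_dataset("small_part", {"fam": t}, copies_per_rate=2, seed=4)
        labels = [c.label for c in chroms]
        assert labels == ["small_part_0.75", "small_part_0.5",
                          "small_part_0.25", "small_part_0.17"]

    def test_two_consensus_alternates_families(self):
        a, b = random_consensus(120, 9), random_consensus(120, 10)
        (chrom,) = make_dataset("two_consensus", {"A": a, "B": b},
                                rates=[0.25], copies_per_rate=4, seed=6)
        fams = [f for _, _, f, _ in chrom.truths]
        assert fams == ["A", "B"] * 4

    def test_deterministic(self):
        t = random_consensus(100, 12)
        c1 = make_dataset("full_length", {"f": t}, rates=[0.25],
                          copies_per_rate=5, seed=8)[0]
        c2 = make_dataset("full_length", {"f": t}, rates=[0.25],
                          copies_per_rate=5, seed=8)[0]
        assert c1.seq == c2.seq and c1.truths == c2.truths

    def test_background_too_short_rejected(self):
        t = random_consensus(200, 13)
        with pytest.raises(ValueError, match="background too short"):
            make_dataset("full_length", {"f": t}, rates=[0.25],
                         copies_per_rate=50, background_length=100, seed=1)


class TestEvaluate:
    def truth(self, ivs):
        return SimulatedChromosome("", [(s, e, f, i)
                                        for i, (s, e, f) in enumerate(ivs)])

    def test_perfect_hits(self):
        tr = self.truth([(100, 200, "fam"), (400, 500, "fam")])
        rep = evaluate(HitSet([hit(100, 200, 20), hit(400, 500, 20)]), tr)
        assert rep.detection_rate == 1.0
        assert rep.false_positives == 0 and rep.misclassified == 0
        assert rep.mean_length == 100.0

    def test_empty_hits(self):
        rep = evaluate(HitSet([]), self.truth([(0, 10, "fam")]))
        assert rep.detection_rate == 0.0 and rep.n_detected == 0

    def test_toy_hand_tally(self):
        tr = self.truth([(0, 100, "A"), (200, 300, "A"), (400, 500, "B"),
                         (600, 700, "A"), (800, 900, "B")])
        hits = HitSet([
            hit(10, 90, 20, "A"),     # detects truth 0, correct family
            hit(210, 290, 15, "B"),   # detects truth 1, wrong family
            hit(450, 520, 12, "B"),   # detects truth 2
            hit(455, 505, 30, "A"),   # also truth 2; higher z, wrong family
            hit(950, 990, 11, "A"),   # overlaps nothing: FP
            hit(995, 999, 11, "A"),   # FP
        ])
        rep = evaluate(hits, tr)
        assert rep.n_detected == 3
        assert rep.detection_rate == pytest.approx(0.6)
        assert rep.misclassified == 2  # truths 1 and 2 best-hit wrong family
        assert rep.false_positives == 2
        assert rep.detected_lengths == [80, 80, 50]


def test_iid_background_composition():
    seq = iid_background(40000, 17, gc=0.4)
    gc = (seq.count("g") + seq.count("c")) / len(seq)
    assert gc == pytest.approx(0.4, abs=0.02)
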