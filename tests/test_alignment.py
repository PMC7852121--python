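import numpy as np
import pytest

from divscan import Consensus, GenomicWindow, align, build_pwm, score_path, transform_pwm
from divscan.alignment import Move, fmax
from helpers import oracle_fmax

SQRT15 = np.sqrt(15.0)


class TestSelfAlignment:
    def test_consensus_against_own_matrix(self):
        pwm = build_pwm(Consensus("t", "acgt"))
        aln = align(GenomicWindow("acgt"), pwm)
        # first step scores the all-ones first column, then three pair cells
        assert aln.f_max == pytest.approx(1 + 3 * SQRT15)
        assert aln.s1_range == (0, 4)
        assert aln.s2_range == (0, 4)
        assert aln.n_matches == 4 and aln.n_gaps == 0
        assert aln.path[0][2] == Move.DIAG_BROKEN
        assert all(mv == Move.DIAG_CTX for *_ij, mv in aln.path[1:])

    def test_score_path_matches_fmax(self):
        pwm = build_pwm(Consensus("t", "acgt"))
        w = GenomicWindow("acgt")
        aln = align(w, pwm)
        assert score_path(aln.path, w, pwm) == aln.f_max

    def test_dissimilar_window_empty(self):
        pwm = transform_pwm(build_pwm(Consensus("t", "acgtacgtacgtacgtacgt")), -2.0)
        # make even context-broken restarts unprofitable
        pwm.matrix[:, 0] = -1.0
        aln = align(GenomicWindow("tttt"), pwm)
        assert aln.f_max == 0.0
        assert aln.s1_range == (0, 0) and aln.path == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(60))
    def test_small_random_instances(self, trial):
        rng = np.random.default_rng(9000 + trial)
        n_win = int(rng.integers(2, 7))
        n_cons = int(rng.integers(2, 6))
        mat = np.zeros((16, n_cons))
        mat[:, 0] = 1.0
        mat[:, 1:] = rng.normal(0.0, 3.0, size=(16, n_cons - 1))
        codes = rng.integers(0, 4, size=n_win).astype(np.int8)
        d, e = 4.0, 1.0  # small penalties so gapped paths compete
        from divscan._kernels import fmax_kernel
        got = fmax_kernel(codes, mat, d, e)
        want = oracle_fmax(codes, mat, d, e)
        assert got == want  # bit-exact

    def test_gap_paths_actually_selected(self):
        # sanity: with tiny penalties some instance must use a gap, so the
        # equivalence above exercises the affine states
        rng = np.random.default_rng(77)
        used_gap = False
        for _ in range(50):
            mat = np.zeros((16, 5))
            mat[:, 0] = 1.0
            mat[:, 1:] = rng.normal(0.0, 3.0, size=(16, 4))
            codes = rng.integers(0, 4, size=6).astype(np.int8)
            pwm_like = _wrap(mat)
            aln = align(GenomicWindow("".join("atcg"[c] for c in codes)),
                        pwm_like, 1.0, 0.5)
            if aln.n_gaps:
                used_gap = True
                assert score_path(aln.path,
                                  GenomicWindow("".join("atcg"[c] for c in codes)),
                                  pwm_like, 1.0, 0.5) == pytest.approx(aln.f_max, abs=1e-12)
        assert used_gap


def _wrap(mat):
    from divscan.pwm_core import DinucleotidePWM
    n = mat.shape[1]
    return DinucleotidePWM("w", mat, np.zeros(n - 1, dtype=np.int64),
                           np.full(16, 1 / 16))


class TestProperties:
    def test_no_gap_closed_form(self, rng):
        # with prohibitive gap penalties the best local alignment is the
        # best contiguous diagonal run, computable by direct scanning
        for _ in range(20):
            n_cons = int(rng.integers(3, 8))
            mat = np.zeros((16, n_cons))
            mat[:, 0] = 1.0
            mat[:, 1:] = rng.normal(0, 2, size=(16, n_cons - 1))
            codes = rng.integers(0, 4, size=int(rng.integers(2, 9))).astype(np.int8)
            from divscan._kernels import fmax_kernel
            got = fmax_kernel(codes, mat, 1e9, 1e9)
            best = 0.0
            for i0 in range(codes.size):
                for j0 in range(n_cons):
                    s = mat[codes[i0], 0]
                    best = max(best, s)
                    i, j = i0 + 1, j0 + 1
                    while i < codes.size and j < n_cons:
                        s += mat[codes[i - 1] + 4 * codes[i], j]
                        best = max(best, s)
                        i += 1
                        j += 1
            assert got == pytest.approx(best, abs=1e-12)

    def test_shift_equivariance(self, synthetic_pwm, synthetic_template, rng):
        w = GenomicWindow(synthetic_template[:120])
        base = fmax(w.codes, synthetic_pwm)
        from divscan import iid_background
        pad = iid_background(40, rng)
        padded = GenomicWindow(pad + synthetic_template[:120] + pad[::-1])
        assert fmax(padded.codes, synthetic_pwm) >= base

    def test_score_path_rejects_malformed(self, synthetic_pwm):
        w = GenomicWindow("acgtacgt")
        with pytest.raises(ValueError):
            score_path([(1, 2, Move.DIAG_CTX)], w, synthetic_pwm)  # no context yet
        with pytest.raises(ValueError):
            score_path([(99, 1, Move.DIAG_BROKEN)], w, synthetic_pwm)

    def test_empty_path_scores_zero(self, synthetic_pwm):
        assert score_path([], GenomicWindow("acgt"), synthetic_pwm) == 0.0

    def test_gap_penalty_arithmetic(self):
        pwm = build_pwm(Consensus("t", "acgtac"))
        w = GenomicWindow("acgtac")
        # diag, diag, then a 2-long gap in S1 (two columns skipped), diag
        path = [(1, 1, Move.DIAG_BROKEN), (2, 2, Move.DIAG_CTX),
                (2, 3, Move.GAP_S1), (2, 4, Move.GAP_S1),
                (3, 5, Move.DIAG_BROKEN)]
        got = score_path(path, w, pwm, 32.0, 8.0)
        expect = 1.0 + pwm.matrix[w.codes[0] + 4 * w.codes[1], 1] - 32.0 - 8.0 + 1.0
        assert got == pytest.approx(expect)
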