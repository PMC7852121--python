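"""Numba kernels for the context-aware local-alignment dynamic program.

Three-state affine-gap recurrence (Gotoh layout) with one twist: the score
of a diagonal step depends on the *previous genome symbol consumed on the
path*.  When the predecessor cell is a non-empty match-state cell, the step
scores the matrix entry for the dinucleotide (previous symbol, current
symbol); when the alignment is just starting or the preceding move was a
gap in either sequence, the dinucleotide context is broken and the step
scores the matrix's first column (all ones).

States:
  F  — last move consumed both a genome symbol and a matrix column (match)
  Fx — last move consumed a genome symbol only (gap in the matrix axis)
  Fy — last move consumed a matrix column only (gap in the genome)

Traceback codes for F: 0 fresh start, 1 diagonal from F with context,
2 diagonal from F without context (predecessor empty), 3 diagonal from Fx,
4 diagonal from Fy.  For Fx/Fy: 1 open (from F), 2 extend.
"""

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def fmax_kernel(seq, mat, d, e):
    """Best local score only (no traceback); rolling rows, O(N) memory."""
    n = seq.shape[0]
    ncols = mat.shape[1]
    fp = np.zeros(ncols + 1)
    fc = np.zeros(ncols + 1)
    xp = np.full(ncols + 1, NEG)
    xc = np.full(ncols + 1, NEG)
    yp = np.full(ncols + 1, NEG)
    yc = np.full(ncols + 1, NEG)
    ep = np.ones(ncols + 1, np.uint8)
    ec = np.ones(ncols + 1, np.uint8)
    best = 0.0
    for i in range(1, n + 1):
        cur = seq[i - 1]
        fc[0] = 0.0
        xc[0] = NEG
        yc[0] = NEG
        ec[0] = 1
        broken = mat[cur, 0]
        for j in range(1, ncols + 1):
            # context diagonal (predecessor non-empty), gap-state diagonals,
            # and a fresh start at this cell (first consumed symbol)
            if ep[j - 1] == 0:
                f = fp[j - 1] + mat[seq[i - 2] + 4 * cur, j - 1]
            else:
                f = broken
            a2 = xp[j - 1] + broken
            if a2 > f:
                f = a2
            a3 = yp[j - 1] + broken
            if a3 > f:
                f = a3
            if broken > f:
                f = broken
            if f <= 0.0:
                fc[j] = 0.0
                ec[j] = 1
            else:
                fc[j] = f
                ec[j] = 0
                if f > best:
                    best = f
            xo = fp[j] - d
            xe = xp[j] - e
            xc[j] = xo if xo >= xe else xe
            yo = fc[j - 1] - d
            ye = yc[j - 1] - e
            yc[j] = yo if yo >= ye else ye
        fp, fc = fc, fp
        xp, xc = xc, xp
        yp, yc = yc, yp
        ep, ec = ec, ep
    return best


@njit(cache=True)
def fmax_batch(seqs, mat, d, e):
    """fmax_kernel over the rows of a 2-D batch of equal-length sequences."""
    out = np.empty(seqs.shape[0])
    for r in range(seqs.shape[0]):
        out[r] = fmax_kernel(seqs[r], mat, d, e)
    return out


@njit(cache=True)
def align_kernel(seq, mat, d, e):
    """Full DP with traceback matrices.

    Returns (fmax, bi, bj, tb_f, tb_x, tb_y); (bi, bj) is the earliest
    (row-major) endpoint attaining fmax, in 1-based DP coordinates.
    """
    n = seq.shape[0]
    ncols = mat.shape[1]
    F = np.zeros((n + 1, ncols + 1))
    X = np.full((n + 1, ncols + 1), NEG)
    Y = np.full((n + 1, ncols + 1), NEG)
    E = np.ones((n + 1, ncols + 1), np.uint8)
    tb_f = np.zeros((n + 1, ncols + 1), np.uint8)
    tb_x = np.zeros((n + 1, ncols + 1), np.uint8)
    tb_y = np.zeros((n + 1, ncols + 1), np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        cur = seq[i - 1]
        broken = mat[cur, 0]
        for j in range(1, ncols + 1):
            # tie preference: context diag > diag from Fx > diag from Fy >
            # fresh start > empty
            if E[i - 1, j - 1] == 0:
                f = F[i - 1, j - 1] + mat[seq[i - 2] + 4 * cur, j - 1]
                code = 1
            else:
                f = broken
                code = 2
            a2 = X[i - 1, j - 1] + broken
            if a2 > f:
                f = a2
                code = 3
            a3 = Y[i - 1, j - 1] + broken
            if a3 > f:
                f = a3
                code = 4
            if broken > f:
                f = broken
                code = 2
            if f <= 0.0:
                F[i, j] = 0.0
                E[i, j] = 1
                tb_f[i, j] = 0
            else:
                F[i, j] = f
                E[i, j] = 0
                tb_f[i, j] = code
                if f > best:
                    best = f
                    bi = i
                    bj = j
            xo = F[i - 1, j] - d
            xe = X[i - 1, j] - e
            if xo >= xe:
                X[i, j] = xo
                tb_x[i, j] = 1
            else:
                X[i, j] = xe
                tb_x[i, j] = 2
            yo = F[i, j - 1] - d
            ye = Y[i, j - 1] - e
            if yo >= ye:
                Y[i, j] = yo
                tb_y[i, j] = 1
            else:
                Y[i, j] = ye
                tb_y[i, j] = 2
    return best, bi, bj, tb_f, tb_x, tb_y
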