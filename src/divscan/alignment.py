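"""Correlation-aware affine-gap local alignment of a genome window to a PWM.

The genome window S1 is aligned against the matrix-column axis S2 = 1..N.
A diagonal move consumes one genome symbol and one matrix column; its score
is the matrix entry for the dinucleotide (previously consumed genome
symbol, current symbol) in the consumed column.  The first consumed symbol
of an alignment, and any diagonal move that directly follows a gap in
either sequence, has no dinucleotide context and scores the matrix's first
column (1 by construction).  Gaps are affine: opening costs ``d``,
extension ``e`` (defaults 32.0 and 8.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import align_kernel, fmax_kernel
from .pwm_core import DinucleotidePWM, encode_sequence

__all__ = [
    "GenomicWindow",
    "LocalAlignment",
    "Move",
    "align",
    "score_path",
    "fmax",
    "DEFAULT_GAP_OPEN",
    "DEFAULT_GAP_EXTEND",
]

DEFAULT_GAP_OPEN = 32.0
DEFAULT_GAP_EXTEND = 8.0


class Move:
    """Path step labels."""

    DIAG_CTX = "diag-with-context"
    DIAG_BROKEN = "diag-context-broken"
    GAP_S1 = "gap-in-S1"   # matrix column consumed, genome gapped
    GAP_S2 = "gap-in-S2"   # genome symbol consumed, matrix gapped


@dataclass(frozen=True)
class GenomicWindow:
    """A slice of a chromosome: sequence, 0-based origin, strand."""

    seq: str
    origin: int = 0
    strand: str = "+"

    @property
    def codes(self) -> np.ndarray:
        return encode_sequence(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class LocalAlignment:
    """Best local alignment: score, half-open ranges, and the move path.

    ``s1_range`` indexes the window (0-based); ``s2_range`` indexes matrix
    columns, 0-based over 1..N (i.e. position p corresponds to consensus
    position p+1).  ``path`` holds (i, j, move) triples in 1-based DP
    coordinates of the cell each move lands on.
    """

    f_max: float
    s1_range: tuple[int, int]
    s2_range: tuple[int, int]
    path: list = field(default_factory=list)

    @property
    def n_matches(self) -> int:
        return sum(1 for *_ij, mv in self.path if mv in (Move.DIAG_CTX, Move.DIAG_BROKEN))

    @property
    def n_gaps(self) -> int:
        return sum(1 for *_ij, mv in self.path if mv in (Move.GAP_S1, Move.GAP_S2))


def fmax(codes: np.ndarray, pwm: DinucleotidePWM,
         d: float = DEFAULT_GAP_OPEN, e: float = DEFAULT_GAP_EXTEND) -> float:
    """Best local score of an encoded window (no traceback)."""
    return float(fmax_kernel(codes, pwm.matrix, d, e))


def align(window: GenomicWindow, pwm: DinucleotidePWM,
          d: float = DEFAULT_GAP_OPEN, e: float = DEFAULT_GAP_EXTEND) -> LocalAlignment:
    """Maximal-scoring local alignment of a window against a PWM."""
    codes = window.codes
    if codes.size == 0:
        return LocalAlignment(0.0, (0, 0), (0, 0), [])
    best, bi, bj, tb_f, tb_x, tb_y = align_kernel(codes, pwm.matrix, d, e)
    if best <= 0.0:
        return LocalAlignment(0.0, (0, 0), (0, 0), [])

    path = []
    i, j, state = bi, bj, "F"
    while True:
        if state == "F":
            code = tb_f[i, j]
            if code == 0:
                break
            if code == 1:
                path.append((i, j, Move.DIAG_CTX))
                state = "F"
            elif code == 2:
                path.append((i, j, Move.DIAG_BROKEN))
                state = "F"
                i, j = i - 1, j - 1
                break  # predecessor is an empty cell: alignment start
            elif code == 3:
                path.append((i, j, Move.DIAG_BROKEN))
                state = "X"
            else:
                path.append((i, j, Move.DIAG_BROKEN))
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            path.append((i, j, Move.GAP_S2))
            state = "F" if tb_x[i, j] == 1 else "X"
            i -= 1
        else:
            path.append((i, j, Move.GAP_S1))
            state = "F" if tb_y[i, j] == 1 else "Y"
            j -= 1
    path.reverse()
    return LocalAlignment(float(best), (i, bi), (j, bj), path)


def score_path(path, window: GenomicWindow, pwm: DinucleotidePWM,
               d: float = DEFAULT_GAP_OPEN, e: float = DEFAULT_GAP_EXTEND) -> float:
    """Independently re-score a move path (validates align's traceback).

    The path is scored by walking it left to right: diagonal steps add the
    matrix entry dictated by the context rule, gap runs cost d + (len-1)*e.
    """
    if not path:
        return 0.0
    codes = window.codes
    mat = pwm.matrix
    total = 0.0
    prev_move = None
    for i, j, move in path:
        if move in (Move.DIAG_CTX, Move.DIAG_BROKEN):
            if not 1 <= i <= codes.size or not 1 <= j <= pwm.n:
                raise ValueError(f"path step out of bounds: {(i, j, move)}")
            if move == Move.DIAG_CTX:
                if prev_move != Move.DIAG_CTX and prev_move != Move.DIAG_BROKEN:
                    raise ValueError("context step without a preceding diagonal")
                if j < 2:
                    raise ValueError("context step cannot land on column 1")
                total += mat[codes[i - 2] + 4 * codes[i - 1], j - 1]
            else:
                total += mat[codes[i - 1], 0]
            prev_move = move
        elif move == Move.GAP_S2:
            total -= e if prev_move == Move.GAP_S2 else d
            prev_move = move
        elif move == Move.GAP_S1:
            total -= e if prev_move == Move.GAP_S1 else d
            prev_move = move
        else:
            raise ValueError(f"unknown move {move!r}")
    return total
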