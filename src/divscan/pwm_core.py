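"""Dinucleotide-correlation position weight matrices.

A repeat family represented by a single consensus sequence ``S`` of length
``N`` is encoded as a 16-row matrix over *pairs of adjacent nucleotides*:
column ``k`` (``k = 2..N``) describes the dinucleotide ``(S[k-1], S[k])``,
and row ``l = i + 4(j-1)`` indexes the pair with previous nucleotide ``i``
and current nucleotide ``j`` under the fixed code a=1, t=2, c=3, g=4
(0-based internally).  Only the row of the observed consensus pair is
nonzero in a freshly built matrix; its value is the standardized score of a
pair-match indicator under the background pair probability
``f(i,j) = p(i)·p(j)``::

    m(l, k) = (1 - f) / sqrt(f (1 - f))

The first column (``k = 1``) is all ones and is used by the aligner whenever
the dinucleotide context is unavailable (alignment start, or the step after
a gap).

Two scalars summarize a matrix:

* ``r2`` — the sum of squared entries over the consensus-pair support,
  which controls the magnitude of match scores, and
* ``kd`` — the mean entry under the background weights
  ``p1(l) = p(i)p(j)``, ``p2(k) = 1/(N-1)`` over the full 16x(N-1) grid,
  i.e. the expected per-column score when random sequence is aligned.

``transform_pwm`` applies the affine map ``m' = alpha*m + beta`` (alpha > 0)
to the pair columns so that ``kd`` hits a requested target while ``r2`` is
conserved.  Negative ``kd`` makes random extension of a local alignment
costly and thereby tightens its boundaries; ``kd`` near zero lets
alignments drift to the full matrix length.  Because ``kd`` is defined per
column, the same target is comparable across families of different lengths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NUCLEOTIDES",
    "Consensus",
    "DinucleotidePWM",
    "PWMError",
    "build_pwm",
    "transform_pwm",
    "matrix_stats",
    "encode_sequence",
    "decode_sequence",
]

# Fixed nucleotide order; the integer code is the position in this string.
# Chosen so that the reverse complement of code c is c ^ 1.
NUCLEOTIDES = "atcg"
_CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}


class PWMError(ValueError):
    """Raised for invalid consensus input or an unsatisfiable transform."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string over {a,c,g,t} (case-folded) as int8 codes 0..3."""
    arr = np.frombuffer(seq.lower().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for ch, code in _CODE.items():
        out[arr == ord(ch)] = code
    if (out < 0).any():
        bad = sorted({chr(b) for b in arr[out < 0]})
        raise PWMError(f"sequence contains non-ACGT symbols: {bad}")
    return out


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(NUCLEOTIDES[c] for c in codes)


@dataclass(frozen=True)
class Consensus:
    """A repeat-family consensus: name, sequence, base composition."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 2:
            raise PWMError("consensus must be at least 2 nt long")
        object.__setattr__(self, "seq", self.seq.lower())
        encode_sequence(self.seq)  # alphabet check

    @property
    def codes(self) -> np.ndarray:
        return encode_sequence(self.seq)

    @property
    def base_probs(self) -> np.ndarray:
        """p(i) for i in a,t,c,g, from the consensus itself."""
        counts = np.bincount(self.codes, minlength=4).astype(float)
        return counts / counts.sum()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class DinucleotidePWM:
    """16 x N matrix: column 0 all ones, columns 1..N-1 the pair columns.

    ``pair_rows[c-1]`` is the row of the consensus dinucleotide for matrix
    column ``c`` (c = 1..N-1, i.e. consensus positions k = 2..N).
    """

    name: str
    matrix: np.ndarray          # float64, shape (16, N)
    pair_rows: np.ndarray       # int64, shape (N-1,)
    p1: np.ndarray              # float64, shape (16,), background pair probs
    consensus_codes: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        """Consensus length N (matrix has N columns)."""
        return self.matrix.shape[1]

    @property
    def n_cols(self) -> int:
        """Number of pair columns, N-1."""
        return self.matrix.shape[1] - 1

    @property
    def p2(self) -> float:
        return 1.0 / self.n_cols

    @property
    def first_col(self) -> np.ndarray:
        return self.matrix[:, 0]

    @property
    def path_values(self) -> np.ndarray:
        """Entries on the consensus-pair support, one per pair column."""
        cols = np.arange(1, self.n)
        return self.matrix[self.pair_rows, cols]

    @property
    def r2(self) -> float:
        return float(np.sum(self.path_values**2))

    @property
    def kd(self) -> float:
        return float(self.p1 @ self.matrix[:, 1:].sum(axis=1)) * self.p2

    # -- plain-text serialization (round-trip exact) --------------------

    def dumps(self) -> str:
        buf = io.StringIO()
        buf.write(f"# divscan dinucleotide PWM\n# name: {self.name}\n")
        buf.write(f"# N: {self.n}\n# r2: {self.r2!r}\n# kd: {self.kd!r}\n")
        buf.write(f"# code: {NUCLEOTIDES} (l = i + 4*(j-1), i=prev, j=cur)\n")
        buf.write("# pair_rows: " + " ".join(map(str, self.pair_rows)) + "\n")
        buf.write("# p1: " + " ".join(repr(float(x)) for x in self.p1) + "\n")
        if self.consensus_codes is not None:
            buf.write("# consensus: " + decode_sequence(self.consensus_codes) + "\n")
        for row in self.matrix:
            buf.write("\t".join(repr(float(x)) for x in row) + "\n")
        return buf.getvalue()

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    @classmethod
    def loads(cls, text: str) -> "DinucleotidePWM":
        meta: dict[str, str] = {}
        rows = []
        for line in text.splitlines():
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
            elif line.strip():
                rows.append([float(x) for x in line.split("\t")])
        matrix = np.array(rows, dtype=float)
        pair_rows = np.array([int(x) for x in meta["pair_rows"].split()])
        p1 = np.array([float(x) for x in meta["p1"].split()])
        codes = encode_sequence(meta["consensus"]) if "consensus" in meta else None
        return cls(meta.get("name", "pwm"), matrix, pair_rows, p1, codes)

    @classmethod
    def load(cls, path) -> "DinucleotidePWM":
        with open(path) as fh:
            return cls.loads(fh.read())


def build_pwm(consensus: Consensus) -> DinucleotidePWM:
    """Build the untransformed correlation matrix for one consensus.

    The background pair frequency ``f(i,j) = p(i)p(j)`` is clamped to
    ``[1/(4N), 1 - 1/(4N)]`` (a pseudo-count-scale floor) so degenerate
    compositions such as a homopolymer never produce ``f`` of 0 or 1.
    """
    codes = consensus.codes
    n = len(codes)
    p = consensus.base_probs
    p1 = np.outer(p, p).T.reshape(-1)  # p1[i + 4*j] = p[i]*p[j]; see below

    # l (0-based) = prev + 4*cur; p1[l] must equal p(prev)*p(cur).
    # np.outer(p, p)[cur, prev] = p[cur]*p[prev]; transpose+ravel gives
    # index prev + 4*cur with value p[prev]*p[cur].
    matrix = np.zeros((16, n))
    matrix[:, 0] = 1.0
    lo, hi = 1.0 / (4 * n), 1.0 - 1.0 / (4 * n)
    pair_rows = codes[:-1].astype(np.int64) + 4 * codes[1:].astype(np.int64)
    f = np.clip(p1[pair_rows], lo, hi)
    matrix[pair_rows, np.arange(1, n)] = (1.0 - f) / np.sqrt(f * (1.0 - f))
    return DinucleotidePWM(consensus.name, matrix, pair_rows, p1, codes)


def matrix_stats(pwm: DinucleotidePWM) -> tuple[float, float]:
    """Return (r2, kd): support-restricted sum of squares, grid-mean score."""
    return pwm.r2, pwm.kd


def feasible_kd_range(pwm: DinucleotidePWM) -> tuple[float, float]:
    """Largest symmetric kd interval reachable by the affine transform."""
    m = pwm.path_values
    nc = pwm.n_cols
    a_coef = float(np.sum((m - pwm.kd) ** 2))
    if a_coef <= 1e-12 * max(1.0, pwm.r2):
        # every path entry equals kd: only kd = +-sqrt(r2/(N-1)) is
        # reachable, an empty open interval
        return (0.0, 0.0)
    cross = (float(m.sum()) - nc * pwm.kd) ** 2
    denom = nc * a_coef - cross
    if denom <= 0:
        return (-np.inf, np.inf)
    bound = float(np.sqrt(a_coef * pwm.r2 / denom))
    return (-bound, bound)


def transform_pwm(pwm: DinucleotidePWM, kd_target: float) -> DinucleotidePWM:
    """Affine-transform the pair columns to hit ``kd_target`` at fixed r2.

    Solves ``m' = alpha*m + beta`` (all 16 rows of columns 2..N; the first
    column stays 1) for the unique alpha > 0 with ``kd(m') = kd_target`` and
    the sum of squares over the consensus-pair support conserved.
    """
    m = pwm.path_values
    nc = pwm.n_cols
    a_total = float(np.sum(m**2))        # conserved r2
    b_path = float(np.sum(m))
    c_kd = pwm.kd

    # beta = kd_target - alpha*c_kd; quadratic in alpha from the r2 constraint
    qa = a_total - 2.0 * c_kd * b_path + nc * c_kd**2
    qb = 2.0 * kd_target * (b_path - nc * c_kd)
    qc = nc * kd_target**2 - a_total

    if qa <= 1e-12 * max(1.0, a_total):
        # every path entry equals the current kd (concentrated-composition
        # degeneracy): the affine family only reaches kd = +-sqrt(r2/(N-1))
        rms = float(np.sqrt(a_total / nc))
        if abs(qc) <= 1e-9 * max(1.0, a_total):
            alpha = 1.0
        else:
            raise PWMError(
                f"kd_target={kd_target} unreachable for a degenerate matrix; "
                f"only kd of +-{rms:.6g} is feasible")
    else:
        disc = qb * qb - 4.0 * qa * qc
        if disc < 0:
            lohi = feasible_kd_range(pwm)
            raise PWMError(
                f"kd_target={kd_target} unreachable at r2={a_total:.6g}; "
                f"feasible kd range is [{lohi[0]:.6g}, {lohi[1]:.6g}]"
            )
        sq = np.sqrt(disc)
        roots = [(-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa)]
        pos = [r for r in roots if r > 0]
        if not pos:
            lohi = feasible_kd_range(pwm)
            raise PWMError(
                f"no alpha > 0 solves kd_target={kd_target}; "
                f"feasible kd range is [{lohi[0]:.6g}, {lohi[1]:.6g}]"
            )
        alpha = max(pos)
    beta = kd_target - alpha * c_kd

    matrix = pwm.matrix.copy()
    matrix[:, 1:] = alpha * matrix[:, 1:] + beta
    out = DinucleotidePWM(pwm.name, matrix, pwm.pair_rows.copy(), pwm.p1.copy(),
                          None if pwm.consensus_codes is None else pwm.consensus_codes.copy())
    if abs(out.kd - kd_target) > 1e-9 or abs(out.r2 - a_total) > 1e-9 * max(1.0, a_total):
        raise PWMError("transform failed to satisfy constraints (numerical)")
    return out


def build_pwm_from_alignment(name: str, sequences: list[str]):
    """Hook for alignment-derived (multi-sequence) matrix construction.

    A matrix estimated from a column-wise dinucleotide profile of several
    family members would sharpen scores relative to the single-consensus
    construction.  Deliberately unimplemented: the estimator (pseudocounts,
    column weighting, gap handling) is untested surface; use
    :func:`build_pwm` on a consensus instead.
    """
    raise NotImplementedError(
        "multi-sequence matrix construction is an untested extension; "
        "build a consensus and use build_pwm")
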