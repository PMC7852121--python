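"""Pairwise identity / distance structure of a consensus library.

Identity between two consensuses is measured on a global alignment
(Needleman-Wunsch with a simple scheme: match +1, mismatch -1, gap open
-2, gap extend -0.5) as

    PID1 = 100 * identical / (aligned + internal gap positions)

where terminal gap columns are excluded from the denominator.  Distance is
100 - identity.  Libraries are filtered to consensuses of at most 600 nt
on loading, the working length range for SINE elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .pwm_core import Consensus

__all__ = ["IdentityMatrix", "pid1_identity", "identity_matrix",
           "MAX_CONSENSUS_LENGTH"]

MAX_CONSENSUS_LENGTH = 600


def _aligner(match: float, mismatch: float, gap_open: float,
             gap_extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    # co-optimal alignments are common; marginally cheaper end gaps break
    # ties toward terminal placement, which PID1 then excludes
    al.open_end_gap_score = gap_open * 0.95
    al.extend_end_gap_score = gap_extend * 0.9
    return al


def pid1_identity(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                  gap_open: float = -2.0, gap_extend: float = -0.5) -> float:
    """Percent identity (PID1 convention) of the best global alignment."""
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    a, b = a.lower(), b.lower()
    if b < a:
        a, b = b, a  # canonical order: alignment tie-breaks stay symmetric
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    # trim terminal gap columns: outside the span where both have started
    # and neither has finished
    first = 0
    while ra[first] == "-" or rb[first] == "-":
        first += 1
        if first == len(ra):
            return 0.0
    last = len(ra) - 1
    while ra[last] == "-" or rb[last] == "-":
        last -= 1
    identical = 0
    denom = 0
    for x, y in zip(ra[first:last + 1], rb[first:last + 1]):
        denom += 1  # aligned column or internal gap column
        if x == y and x != "-":
            identical += 1
    return 100.0 * identical / denom


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity grid over a library of consensuses."""

    names: list
    identity: np.ndarray

    @property
    def distance(self) -> np.ndarray:
        return 100.0 - self.identity

    def summary(self) -> dict:
        """min / max / mean over the off-diagonal upper triangle."""
        n = len(self.names)
        if n < 2:
            raise ValueError("summary needs at least two consensuses")
        iu = np.triu_indices(n, k=1)
        vals = self.identity[iu]
        return {"min": float(vals.min()), "max": float(vals.max()),
                "mean": float(vals.mean())}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("family\t" + "\t".join(self.names) + "\n")
            for name, row in zip(self.names, self.identity):
                fh.write(name + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")


def identity_matrix(library: list[Consensus], **scoring) -> IdentityMatrix:
    """All pairwise PID1 identities of a consensus library."""
    if len(library) < 2:
        raise ValueError("need at least two consensuses")
    n = len(library)
    grid = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = pid1_identity(library[i].seq, library[j].seq, **scoring)
            grid[i, j] = grid[j, i] = v
    return IdentityMatrix([c.name for c in library], grid)


def filter_library(library: list[Consensus],
                   max_length: int = MAX_CONSENSUS_LENGTH) -> list[Consensus]:
    """Drop consensuses longer than ``max_length`` nt."""
    return [c for c in library if len(c) <= max_length]
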