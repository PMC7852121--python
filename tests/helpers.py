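"""Independent brute-force oracle for the context-aware local alignment.

Enumerates every monotone gapped local path explicitly (no dynamic
programming, no traceback bookkeeping) and scores it by walking it left to
right: the first diagonal of a path, and any diagonal directly following a
gap, scores the matrix's first column; a diagonal following a diagonal
scores the dinucleotide entry.  Gap runs cost d + (len-1)*e; a gap in one
sequence may not directly follow a gap in the other (affine three-state
convention).
"""

import numpy as np


def oracle_fmax(codes: np.ndarray, mat: np.ndarray, d: float, e: float) -> float:
    n = codes.size
    ncols = mat.shape[1]
    best = 0.0

    def extend(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if last == "D" and score > best:
            best = score
        # diagonal
        if i + 1 <= n and j + 1 <= ncols:
            if last == "D":
                sc = mat[codes[i - 1] + 4 * codes[i], j]
            else:
                sc = mat[codes[i], 0]
            extend(i + 1, j + 1, score + sc, "D")
        # gap consuming a genome symbol (matrix axis gapped)
        if i + 1 <= n and last in ("D", "I"):
            extend(i + 1, j, score - (d if last == "D" else e), "I")
        # gap consuming a matrix column (genome gapped)
        if j + 1 <= ncols and last in ("D", "X"):
            extend(i, j + 1, score - (d if last == "D" else e), "X")

    for i in range(1, n + 1):
        for j in range(1, ncols + 1):
            extend(i, j, float(mat[codes[i - 1], 0]), "D")
    return best


def greedy_overlap_reference(hits, max_overlap_frac):
    """Literal restatement of the keep-largest-Z rule for toy hit sets."""
    def frac(a, b):
        if a.chrom != b.chrom:
            return 0.0
        ov = max(0, min(a.end, b.end) - max(a.start, b.start))
        return ov / min(a.length, b.length) if ov else 0.0

    pool = sorted(hits, key=lambda h: (-h.z, -h.length, h.chrom, h.start))
    kept = []
    for h in pool:
        if all(frac(h, k) <= max_overlap_frac for k in kept):
            kept.append(h)
    return kept
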