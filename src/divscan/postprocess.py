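"""Hit-set post-processing: redundancy resolution, low-complexity
filtering, and coordinate-level comparison of two annotations.

Similar consensuses produce overlapping hits across families; overlaps
exceeding 20% (of the shorter hit) are resolved greedily in favor of the
larger Z.  Hits whose sequence is more than 10% low-complexity under a
DUST-style triplet mask are discarded: SINEs do contain an A-rich tail,
but a copy dominated by low-complexity sequence is more likely an artifact
of the correlation scoring than a real insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scanner import ScanHit

__all__ = [
    "HitSet",
    "resolve_overlaps",
    "low_complexity_fraction",
    "filter_low_complexity",
    "compare_hit_sets",
    "dust_mask",
]


@dataclass
class HitSet:
    """A list of hits plus free-text provenance, sorted by coordinate."""

    hits: list = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.hits = sorted(self.hits, key=lambda h: (h.chrom, h.start, h.end))

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)


def _overlap(a: ScanHit, b: ScanHit) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction(a: ScanHit, b: ScanHit) -> float:
    """Overlap length divided by the shorter hit's length."""
    ov = _overlap(a, b)
    if ov == 0:
        return 0.0
    return ov / min(a.length, b.length)


def resolve_overlaps(hits: HitSet, max_overlap_frac: float = 0.20) -> HitSet:
    """Greedy selection by descending Z.

    A hit is kept unless it overlaps an already-kept hit by more than
    ``max_overlap_frac`` of the shorter of the two.  Ties on Z go to the
    longer hit, then the leftmost.
    """
    order = sorted(hits, key=lambda h: (-h.z, -h.length, h.chrom, h.start))
    kept: list[ScanHit] = []
    for h in order:
        if all(overlap_fraction(h, k) <= max_overlap_frac for k in kept):
            kept.append(h)
    return HitSet(kept, provenance=hits.provenance + " | resolve_overlaps")


# ---------------------------------------------------------------------------
# DUST-style low-complexity masking (symmetric triplet score).
# ---------------------------------------------------------------------------

def _best_subwindow(codes: np.ndarray) -> tuple[float, int, int]:
    """Max triplet score S/(L-1) over sub-intervals of one window, O(w^2)."""
    w = codes.size
    best, bs, be = 0.0, 0, 0
    trip = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:] if w >= 3 else np.empty(0, int)
    for s in range(w - 3):
        counts = np.zeros(64, dtype=np.int64)
        score2 = 0  # 2*S = sum c*(c-1)
        for t in range(s, w - 2):
            c = counts[trip[t]]
            score2 += 2 * c
            counts[trip[t]] = c + 1
            ntrip = t - s + 1
            if ntrip >= 2:
                val = score2 / (2.0 * (ntrip - 1))
                if val > best:
                    best, bs, be = val, s, t + 3
    return best, bs, be


def dust_mask(seq: str, window: int = 64, threshold: float = 2.0) -> np.ndarray:
    """Boolean mask of low-complexity positions.

    Overlapping windows (step = window/2) are examined; inside each, the
    maximum-scoring sub-interval under the symmetric triplet statistic
    S/(L-1), S = sum_t c_t(c_t-1)/2, is masked whenever its score exceeds
    ``threshold`` (2.0 corresponds to the conventional "level 20" in
     10x-scaled units).
    """
    from .pwm_core import encode_sequence

    codes = encode_sequence(seq)
    n = codes.size
    mask = np.zeros(n, dtype=bool)
    if n < 4:
        return mask
    step = max(1, window // 2)
    starts = list(range(0, max(1, n - window + 1), step))
    if starts[-1] + window < n:
        starts.append(n - window)
    for s in starts:
        sub = codes[s:s + window]
        score, a, b = _best_subwindow(sub)
        if score > threshold:
            mask[s + a:s + b] = True
    return mask


def low_complexity_fraction(seq: str, window: int = 64,
                            threshold: float = 2.0) -> float:
    """Fraction of positions masked by the triplet-complexity masker."""
    if not seq:
        raise ValueError("empty sequence")
    mask = dust_mask(seq, window=window, threshold=threshold)
    return float(mask.mean())


def filter_low_complexity(hits: HitSet, genome: dict, max_frac: float = 0.10,
                          window: int = 64, threshold: float = 2.0) -> HitSet:
    """Drop hits whose extracted sequence is more than ``max_frac`` masked.

    ``genome`` maps chromosome name to sequence string.
    """
    kept = []
    for h in hits:
        seq = genome[h.chrom]
        if not (0 <= h.start < h.end <= len(seq)):
            raise ValueError(f"hit outside chromosome bounds: {h}")
        frac = low_complexity_fraction(seq[h.start:h.end], window=window,
                                       threshold=threshold)
        if frac <= max_frac:
            kept.append(h)
    return HitSet(kept, provenance=hits.provenance + " | filter_low_complexity")


# ---------------------------------------------------------------------------
# Coordinate comparison of two hit sets.
# ---------------------------------------------------------------------------

def _classify(src: HitSet, other: HitSet, min_overlap_frac: float) -> pd.DataFrame:
    rows = {}
    for h in src:
        rec = rows.setdefault(h.family, {"total": 0, "overlap_same": 0,
                                         "overlap_other": 0, "unique": 0})
        rec["total"] += 1
        same = any(o.family == h.family and
                   overlap_fraction(h, o) > min_overlap_frac for o in other)
        diff = any(o.family != h.family and
                   overlap_fraction(h, o) > min_overlap_frac for o in other)
        if same:
            rec["overlap_same"] += 1
        elif diff:
            rec["overlap_other"] += 1
        else:
            rec["unique"] += 1
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def compare_hit_sets(a: HitSet, b: HitSet,
                     min_overlap_frac: float = 0.20) -> pd.DataFrame:
    """Per-family cross-classification of two annotations on one assembly.

    For each family and each direction: hits overlapping (> threshold
    fraction) a hit of the same family in the other set, hits overlapping
    only hits of other families, and hits with no counterpart.
    """
    ta = _classify(a, b, min_overlap_frac).add_prefix("a_")
    tb = _classify(b, a, min_overlap_frac).add_prefix("b_")
    out = ta.join(tb, how="outer").fillna(0).astype(int)
    out.index.name = "family"
    return out
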