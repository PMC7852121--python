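"""Chromosome scanning: sliding windows, Z series, local maxima, hits.

A window the length of the consensus slides along the chromosome with a
fixed step (default 10 nt).  Each window position gets a shuffle-null
Z value; local maxima of the Z series exceeding the threshold Z0 (default
10.0, calibrated so a shuffled genome yields on the order of 20 hits per
family over a few hundred Mb) are refined by re-running the full alignment
on the winning window, and the alignment's window range is converted to
chromosome coordinates.

Both strands are scanned by default (dispersed repeats insert in either
orientation); ``both_strands=False`` restricts to the forward strand.
Windows containing non-ACGT symbols are skipped.

``null_every`` controls how often the shuffle-null statistics are
recomputed along the scan: 1 (default) recomputes them for every window;
k > 1 reuses the latest statistics for the next k-1 windows, which is an
excellent approximation whenever the local base composition is stationary
(i.i.d. or shuffled backgrounds) and cuts scan time by roughly the number
of shuffles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import fmax_kernel
from .alignment import DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN, GenomicWindow, align
from .pwm_core import NUCLEOTIDES, DinucleotidePWM
from .significance import NullModel

__all__ = ["ScanHit", "scan_chromosome", "local_maxima", "DEFAULT_STEP", "DEFAULT_Z0"]

logger = logging.getLogger(__name__)

DEFAULT_STEP = 10
DEFAULT_Z0 = 10.0

_CODE_MAP = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(NUCLEOTIDES):
    _CODE_MAP[ord(_c)] = _i
    _CODE_MAP[ord(_c.upper())] = _i


@dataclass
class ScanHit:
    """One detected repeat copy, in forward-strand 0-based half-open coords."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str
    z: float
    fmax: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def local_maxima(z_series, z0: float) -> list[int]:
    """Indices of local maxima strictly above ``z0``.

    A position qualifies if it exceeds its left neighbor and is not
    exceeded by its right neighbor (series ends count as -inf), so a
    plateau reports its leftmost index.
    """
    z = list(z_series)
    out = []
    for i, v in enumerate(z):
        if v <= z0 or not np.isfinite(v):
            continue
        left = z[i - 1] if i > 0 else -np.inf
        right = z[i + 1] if i + 1 < len(z) else -np.inf
        if v > left and v >= right:
            out.append(i)
    return out


def _encode_loose(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_MAP[arr]


def _scan_strand(codes: np.ndarray, raw: str, pwm: DinucleotidePWM, *,
                 step: int, z0: float, null: NullModel, d: float, e: float,
                 null_every: int) -> list[tuple[int, float, float, tuple[int, int]]]:
    """Scan one strand; returns (window_start, z, fmax, refined range)."""
    n = pwm.n
    length = codes.size
    starts = list(range(0, length - n + 1, step))
    zs = np.full(len(starts), -np.inf)
    fmaxes = np.zeros(len(starts))
    stats = None
    since_refresh = null_every  # force refresh at first valid window
    for idx, k in enumerate(starts):
        win = codes[k:k + n]
        if win.min() < 0:
            since_refresh = null_every
            continue
        if since_refresh >= null_every:
            stats = null.stats(win, pwm, d, e)
            since_refresh = 0
        since_refresh += 1
        mean, var = stats
        fm = float(fmax_kernel(win, pwm.matrix, d, e))
        fmaxes[idx] = fm
        zs[idx] = (fm - mean) / float(np.sqrt(var))
    hits = []
    for idx in local_maxima(zs, z0):
        k = starts[idx]
        window = GenomicWindow(raw[k:k + n], origin=k)
        aln = align(window, pwm, d, e)
        if aln.f_max <= 0.0:
            continue
        s0, s1 = aln.s1_range
        hits.append((k, float(zs[idx]), fmaxes[idx], (k + s0, k + s1)))
    return hits


def revcomp(seq: str) -> str:
    comp = str.maketrans("acgtACGT", "tgcaTGCA")
    return seq.translate(comp)[::-1]


def scan_chromosome(chrom_seq: str, pwm: DinucleotidePWM, *,
                    step: int = DEFAULT_STEP, z0: float = DEFAULT_Z0,
                    null: NullModel | None = None,
                    d: float = DEFAULT_GAP_OPEN, e: float = DEFAULT_GAP_EXTEND,
                    both_strands: bool = True, null_every: int = 1,
                    chrom: str = "chr") -> list[ScanHit]:
    """Scan one chromosome with one family PWM; returns refined hits."""
    n = pwm.n
    length = len(chrom_seq)
    if length < n:
        logger.warning("chromosome %s shorter than consensus (%d < %d)",
                       chrom, length, n)
        return []
    if null is None:
        null = NullModel()
    hits: list[ScanHit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        seq = chrom_seq if strand == "+" else revcomp(chrom_seq)
        codes = _encode_loose(seq)
        for _k, z, fm, (a, b) in _scan_strand(
                codes, seq.lower(), pwm, step=step, z0=z0, null=null,
                d=d, e=e, null_every=null_every):
            if strand == "-":
                a, b = length - b, length - a
            hits.append(ScanHit(chrom, a, b, strand, pwm.name, z, fm))
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    logger.info("scan %s x %s: %d hits above Z0=%.1f", chrom, pwm.name,
                len(hits), z0)
    return hits
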