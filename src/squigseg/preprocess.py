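"""Per-read current standardization anchored on the poly(A) tail.

Pore-to-pore gain and offset differences mean the same transcript yields
different absolute current levels on different reads.  The poly(A) tail is a
long homopolymer producing a stable level, so mapping each read's poly(A)
segment onto a common target mean/std puts every read on the scale of the
k-mer parameter table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from squigseg.errors import UnstandardizableReadError, ValidationError
from squigseg.kmer_table import KmerTable

MIN_POLYA_SAMPLES = 30


@dataclass
class ReadRecord:
    """One read's raw current trace plus region annotation.

    Intervals are 0-based half-open sample index pairs; the poly(A) tail
    precedes the transcript region in sample (time) order because direct
    RNA sequencing reads the molecule 3'->5'.
    """

    read_id: str
    signal: np.ndarray
    polya_interval: tuple[int, int] | None
    transcript_interval: tuple[int, int]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        n = self.signal.size
        for iv in (self.polya_interval, self.transcript_interval):
            if iv is None:
                continue
            s, e = iv
            if not (0 <= s < e <= n):
                raise ValidationError(f"interval {iv} outside [0, {n})")
        if self.polya_interval is not None:
            if self.polya_interval[1] > self.transcript_interval[0]:
                raise ValidationError("poly(A) interval must precede the transcript region")

    @property
    def transcript_signal(self) -> np.ndarray:
        s, e = self.transcript_interval
        return self.signal[s:e]


def standardize(read: ReadRecord, target_mu: float, target_sigma: float) -> ReadRecord:
    """Affinely rescale the whole read so its poly(A) segment has the target moments.

    The transform is y -> a*y + b with a = target_sigma / std(polyA) and
    b = target_mu - a*mean(polyA); it is idempotent and invariant to any
    prior affine distortion of the signal with positive gain.
    """
    if read.polya_interval is None:
        raise UnstandardizableReadError(f"read {read.read_id}: no poly(A) interval annotated")
    s, e = read.polya_interval
    if e - s < MIN_POLYA_SAMPLES:
        raise UnstandardizableReadError(
            f"read {read.read_id}: poly(A) interval has {e - s} samples "
            f"(< {MIN_POLYA_SAMPLES})"
        )
    tail = read.signal[s:e]
    mu, sd = float(np.mean(tail)), float(np.std(tail))
    if sd <= 0:
        raise UnstandardizableReadError(f"read {read.read_id}: zero variance over poly(A)")
    a = target_sigma / sd
    b = target_mu - a * mu
    return replace(read, signal=a * read.signal + b)


def default_targets(table: KmerTable) -> tuple[float, float]:
    """Standardization targets: the table's all-A k-mer baseline."""
    all_a = "A" * table.k
    if all_a not in table:
        raise ValidationError(f"table lacks the all-A k-mer {all_a!r}")
    p = table.lookup(all_a)
    return p.mu_un, p.sigma_un


def detect_polya(
    signal: np.ndarray,
    window: int = 25,
    std_threshold: float = 4.0,
    min_len: int = 200,
) -> tuple[int, int] | None:
    """Heuristic poly(A) locator: the longest low-variance run near the read start.

    This is a crude fallback for inputs lacking an external poly(A)
    annotation: it slides a window over the signal, flags positions whose
    rolling standard deviation is below ``std_threshold`` pA, and returns
    the longest flagged run if it spans at least ``min_len`` samples.
    It is *not* a reimplementation of a segmentation HMM and should not be
    trusted on noisy adapters.
    """
    y = np.asarray(signal, dtype=float)
    if y.size < min_len:
        return None
    # rolling std via cumulative moments
    c1 = np.cumsum(np.insert(y, 0, 0.0))
    c2 = np.cumsum(np.insert(y * y, 0, 0.0))
    m = (c1[window:] - c1[:-window]) / window
    v = (c2[window:] - c2[:-window]) / window - m * m
    flat = np.sqrt(np.maximum(v, 0.0)) < std_threshold
    best: tuple[int, int] | None = None
    start = None
    for i, f in enumerate(flat):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if best is None or i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if start is not None and (best is None or flat.size - start > best[1] - best[0]):
        best = (start, flat.size)
    if best is None or best[1] - best[0] + window - 1 < min_len:
        return None
    return best[0], best[1] + window - 1
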