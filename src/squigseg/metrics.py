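"""Segmentation benchmark metrics.

Two headline numbers summarize how well events match the pore model used
as ground truth: the average per-event standard deviation (lower = less
structured noise inside events) and the average log likelihood of the
event mean under the k-mer's unmodified baseline (higher = event means
closer to the reference levels).  An equal-width splitter provides the
naive control condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from squigseg.align import Event, RefKmerSeq
from squigseg.errors import ValidationError
from squigseg.kmer_table import KmerTable

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class MetricsReport:
    avg_std: float
    avg_logp: float
    n_events: int
    n_excluded: int
    per_kmer: pd.DataFrame  # macro breakdown: kmer, n, avg_std, avg_logp

    @property
    def macro_avg_std(self) -> float:
        return float(self.per_kmer["avg_std"].mean())

    @property
    def macro_avg_logp(self) -> float:
        return float(self.per_kmer["avg_logp"].mean())


def segment_metrics(events: list[Event], table: KmerTable, trim: int = 0) -> MetricsReport:
    """Per-event mean/std metrics against the pore-model baselines.

    Each event's first and last ``trim`` samples are dropped before the
    mean and std are recomputed (use trim=0 for events whose transition
    samples were already excluded during assembly, trim=3 for naive
    splitters that keep boundary samples).  log p is the natural-log
    Gaussian density of the trimmed event mean under (mu_un, sigma_un).
    Averages weight every event equally; a per-k-mer macro breakdown is
    attached.  Events too short to survive trimming are excluded and
    counted.
    """
    rows = []
    n_excluded = 0
    for e in events:
        if e.samples is None:
            raise ValidationError(f"event at {e.reference_id}:{e.position} lacks raw samples")
        y = np.asarray(e.samples, dtype=float)
        if trim > 0:
            if y.size < 2 * trim + 1:
                n_excluded += 1
                continue
            y = y[trim:-trim]
        p = table.lookup(e.model_kmer)
        mean = float(np.mean(y))
        logp = (
            -0.5 * _LOG_2PI
            - math.log(p.sigma_un)
            - (mean - p.mu_un) ** 2 / (2.0 * p.sigma_un**2)
        )
        rows.append({"kmer": e.model_kmer, "std": float(np.std(y)), "logp": logp})
    if not rows:
        raise ValidationError("no events left after trimming")
    df = pd.DataFrame(rows)
    per_kmer = (
        df.groupby("kmer")
        .agg(n=("std", "size"), avg_std=("std", "mean"), avg_logp=("logp", "mean"))
        .reset_index()
    )
    return MetricsReport(
        avg_std=float(df["std"].mean()),
        avg_logp=float(df["logp"].mean()),
        n_events=len(df),
        n_excluded=n_excluded,
        per_kmer=per_kmer,
    )


def equal_width_baseline(
    signal: np.ndarray,
    ref_kmers: RefKmerSeq,
    read_id: str = "read",
) -> list[Event]:
    """Naive control: split the signal into equal-width per-k-mer segments.

    The transcript-region signal is cut into n contiguous segments, one
    per reference k-mer in pore order; boundary/transition samples are not
    treated specially, which is exactly what the HHMM pipeline improves on.
    """
    y = np.asarray(signal, dtype=float)
    n = len(ref_kmers)
    if n < 1 or y.size < n:
        raise ValidationError("signal shorter than the number of reference k-mers")
    edges = np.linspace(0, y.size, n + 1).round().astype(int)
    events = []
    for i in range(n):
        seg = y[edges[i] : edges[i + 1]]
        events.append(
            Event(
                reference_id=ref_kmers.reference_id,
                position=ref_kmers.positions[i],
                model_kmer=ref_kmers.kmers[i],
                event_mean=float(np.mean(seg)),
                event_std=float(np.std(seg)),
                dwell=int(seg.size),
                start_idx=int(edges[i]),
                end_idx=int(edges[i + 1]),
                read_id=read_id,
                samples=seg,
            )
        )
    events.sort(key=lambda e: e.position)
    return events
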