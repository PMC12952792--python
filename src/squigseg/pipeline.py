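"""End-to-end orchestration helpers shared by the CLI, tests and scripts."""

from __future__ import annotations

import numpy as np

from squigseg.align import Event, RefKmerSeq, align_full, assemble_events
from squigseg.hhmm import (
    InnerHMMParams,
    OuterHMMParams,
    Segmentation,
    TransitionModelParams,
    segment,
)
from squigseg.kmer_table import KmerTable
from squigseg.preprocess import ReadRecord, default_targets, standardize
from squigseg.simulate import SimRead


def standardize_read(read: ReadRecord, table: KmerTable) -> ReadRecord:
    """Poly(A)-standardize a read onto the table's all-A baseline scale."""
    mu, sd = default_targets(table)
    return standardize(read, mu, sd)


def sim_to_record(read: SimRead) -> ReadRecord:
    return ReadRecord(
        read_id=read.read_id,
        signal=read.signal,
        polya_interval=read.polya_interval,
        transcript_interval=read.transcript_interval,
    )


def process_read(
    record: ReadRecord,
    reference_id: str,
    reference_seq: str,
    table: KmerTable,
    outer: OuterHMMParams | None = None,
    inner: InnerHMMParams | None = None,
    trans: TransitionModelParams | None = None,
) -> tuple[Segmentation, list[Event]]:
    """Standardized read -> segmentation -> alignment -> events."""
    y = record.transcript_signal
    seg = segment(y, outer, inner, trans, read_id=record.read_id)
    kmers = RefKmerSeq.from_sequence(reference_id, reference_seq, table.k)
    means = np.array([b.mean for b in seg.base_blocks])
    aln = align_full(means, kmers, table)
    events = assemble_events(aln, seg, y, kmers, read_id=record.read_id)
    # event sample indices are reported in whole-read coordinates
    t0 = record.transcript_interval[0]
    for e in events:
        e.start_idx += t0
        e.end_idx += t0
    return seg, events


def run_sim_pipeline(
    reads: list[SimRead],
    references: dict[str, str],
    table: KmerTable,
    outer: OuterHMMParams | None = None,
    inner: InnerHMMParams | None = None,
    trans: TransitionModelParams | None = None,
) -> tuple[list[tuple[str, str, np.ndarray, Segmentation]], list[Event]]:
    """Standardize, segment and align a batch of simulated reads.

    Returns the per-read (read_id, reference_id, transcript signal,
    segmentation) tuples (the input expected by table re-estimation) and
    the flat event list.
    """
    processed = []
    all_events: list[Event] = []
    for read in reads:
        record = standardize_read(sim_to_record(read), table)
        seg, events = process_read(
            record, read.reference_id, references[read.reference_id], table,
            outer, inner, trans,
        )
        processed.append((read.read_id, read.reference_id, record.transcript_signal, seg))
        all_events.extend(events)
    return processed, all_events
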