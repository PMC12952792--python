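"""Alignment of base-block means to the reference k-mer list.

The aligner pairs the ordered base-block means from segmentation with the
reference k-mers in pore-traversal order (3'->5').  Unlike classical global
alignment, several consecutive means may align to one k-mer (a 'stay' move),
reflecting that the hierarchical HMM can split one k-mer's residence into
several base blocks.  Match scores are log Gaussian densities under the
k-mer table (the larger of the unmodified/modified component densities);
insertions and deletions score as a fixed uniform log density.

Blocks aligned to the same k-mer are merged into an *event* carrying the
pooled mean, std and dwell of the member samples, written in an
eventalign-style TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from squigseg.errors import ValidationError
from squigseg.hhmm import Segmentation
from squigseg.kmer_table import KmerTable, normalize_kmer

_LOG_2PI = math.log(2.0 * math.pi)

# path step kinds
MATCH, STAY, INS, DEL = "match", "stay", "ins", "del"


@dataclass
class RefKmerSeq:
    """Reference k-mers in pore-traversal order (3'->5').

    ``positions[i]`` is the 0-based reference coordinate of the 5'-most
    base of ``kmers[i]``.  Because direct RNA sequencing reads 3'->5', the
    first k-mer in pore order is the one closest to the 3' end.
    """

    reference_id: str
    kmers: list[str]
    positions: list[int]

    @classmethod
    def from_sequence(cls, reference_id: str, sequence: str, k: int) -> "RefKmerSeq":
        seq = normalize_kmer(sequence)
        if len(seq) < k:
            raise ValidationError(f"reference {reference_id!r} shorter than k = {k}")
        positions = list(range(len(seq) - k, -1, -1))
        return cls(reference_id, [seq[q : q + k] for q in positions], positions)

    def __len__(self) -> int:
        return len(self.kmers)


@dataclass
class AlignmentResult:
    """A scored DP path over (mean index i, k-mer index j), both 1-based."""

    path: list[tuple[str, int, int]]  # (kind, i, j); i or j is 0 for the skipped side
    score: float
    variant: str  # 'full' or 'partial'
    matrix: np.ndarray | None = None

    def kmer_of_mean(self) -> dict[int, int]:
        """Map 1-based mean index -> 1-based k-mer index (match/stay steps only)."""
        return {i: j for kind, i, j in self.path if kind in (MATCH, STAY)}


@dataclass
class Event:
    """Merged signal segment aligned to one reference k-mer."""

    reference_id: str
    position: int  # 0-based reference coordinate of the k-mer start
    model_kmer: str
    event_mean: float
    event_std: float
    dwell: int
    start_idx: int
    end_idx: int
    read_id: str
    samples: np.ndarray | None = field(default=None, repr=False, compare=False)


def score(mu: float, kmer: str, table: KmerTable) -> float:
    """Match score: log density of ``mu`` under the k-mer's baseline.

    With a modified state enabled, the larger of the unmodified and
    modified log densities is used.
    """
    p = table.lookup(kmer)
    un = _norm_logpdf(mu, p.mu_un, p.sigma_un)
    if p.mod_enabled:
        return max(un, _norm_logpdf(mu, p.mu_mod, p.sigma_mod))
    return un


def _norm_logpdf(x: float, mu: float, sigma: float) -> float:
    return -0.5 * _LOG_2PI - math.log(sigma) - (x - mu) ** 2 / (2.0 * sigma * sigma)


def indel_score(table: KmerTable, pad_sigmas: float = 3.0) -> float:
    """Constant log density used for insertions and deletions.

    A uniform density over the spread of the table's baselines padded by
    ``pad_sigmas`` times the largest std.
    """
    mus = [p.mu_un for p in table.entries.values()]
    sigmas = [p.sigma_un for p in table.entries.values()]
    span = (max(mus) + pad_sigmas * max(sigmas)) - (min(mus) - pad_sigmas * max(sigmas))
    return -math.log(span)


def _score_grid(means: np.ndarray, kmers: RefKmerSeq, table: KmerTable) -> np.ndarray:
    m, n = means.size, len(kmers)
    f = np.empty((m, n))
    params = [table.lookup(s) for s in kmers.kmers]
    for j, p in enumerate(params):
        un = -0.5 * _LOG_2PI - math.log(p.sigma_un) - (means - p.mu_un) ** 2 / (
            2.0 * p.sigma_un**2
        )
        if p.mod_enabled:
            mod = -0.5 * _LOG_2PI - math.log(p.sigma_mod) - (means - p.mu_mod) ** 2 / (
                2.0 * p.sigma_mod**2
            )
            un = np.maximum(un, mod)
        f[:, j] = un
    return f


def align_full(
    means: np.ndarray,
    kmers: RefKmerSeq,
    table: KmerTable,
    keep_matrix: bool = False,
) -> AlignmentResult:
    """Global many-to-one alignment of all means to all k-mers.

    The score matrix M is (m+1)x(n+1) with its first row/column reserved
    for indels: M(0,0)=0, M(i,0)=i*indel, M(0,j)=j*indel.  Each cell takes
    the best of the diagonal match, a k-mer deletion, a mean insertion and
    a vertical 'stay' (an additional mean matched to the same k-mer).
    Traceback starts at (m, n).  Ties resolve stay > match > del > ins.
    """
    means = np.asarray(means, dtype=float)
    m, n = means.size, len(kmers)
    if m < 1 or n < 1:
        raise ValidationError("alignment requires at least one mean and one k-mer")
    f = _score_grid(means, kmers, table)
    g = indel_score(table)

    M = np.empty((m + 1, n + 1))
    move = np.zeros((m + 1, n + 1), dtype=np.int8)  # 1=stay 2=match 3=del 4=ins
    M[0, :] = g * np.arange(n + 1)
    M[:, 0] = g * np.arange(m + 1)
    move[0, 1:] = 3
    move[1:, 0] = 4
    for i in range(1, m + 1):
        fi = f[i - 1]
        for j in range(1, n + 1):
            options = (
                (M[i - 1, j] + fi[j - 1], 1),  # stay
                (M[i - 1, j - 1] + fi[j - 1], 2),  # match
                (M[i, j - 1] + g, 3),  # del (k-mer skipped)
                (M[i - 1, j] + g, 4),  # ins (mean skipped)
            )
            best, mv = options[0]
            for v, code in options[1:]:
                if v > best:
                    best, mv = v, code
            M[i, j], move[i, j] = best, mv

    path: list[tuple[str, int, int]] = []
    i, j = m, n
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 1:
            path.append((STAY, i, j))
            i -= 1
        elif mv == 2:
            path.append((MATCH, i, j))
            i -= 1
            j -= 1
        elif mv == 3:
            path.append((DEL, 0, j))
            j -= 1
        else:
            path.append((INS, i, 0))
            i -= 1
    path.reverse()
    return AlignmentResult(path, float(M[m, n]), "full", M if keep_matrix else None)


def align_partial(
    means: np.ndarray,
    kmers: RefKmerSeq,
    table: KmerTable,
    keep_matrix: bool = False,
) -> AlignmentResult:
    """Align all means to a prefix of the k-mer list, with no indels.

    Only diagonal (match) and vertical (stay) moves are allowed; the path
    starts at k-mer 1 and the traceback begins at the maximum of the last
    row, so trailing k-mers may stay unconsumed.
    """
    means = np.asarray(means, dtype=float)
    m, n = means.size, len(kmers)
    if m < 1 or n < 1:
        raise ValidationError("alignment requires at least one mean and one k-mer")
    f = _score_grid(means, kmers, table)

    NEG = -np.inf
    M = np.full((m + 1, n + 1), NEG)
    move = np.zeros((m + 1, n + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        fi = f[i - 1]
        for j in range(1, min(i, n) + 1):
            stay = M[i - 1, j] + fi[j - 1]
            diag = M[i - 1, j - 1] + fi[j - 1]
            if stay >= diag:
                M[i, j], move[i, j] = stay, 1
            else:
                M[i, j], move[i, j] = diag, 2
    j = int(np.argmax(M[m, 1:])) + 1
    best = float(M[m, j])
    path: list[tuple[str, int, int]] = []
    i = m
    while i > 0:
        mv = move[i, j]
        if mv == 1:
            path.append((STAY, i, j))
            i -= 1
        else:
            path.append((MATCH, i, j))
            i -= 1
            j -= 1
    path.reverse()
    return AlignmentResult(path, best, "partial", M if keep_matrix else None)


def pooled_mean_std(parts: list[tuple[int, float, float]]) -> tuple[float, float]:
    """Combine per-block (n, mean, std) into the pooled mean and std.

    Uses the combined-moments identity: the pooled second moment is the
    weighted mean of per-block variances plus the weighted spread of the
    per-block means, so the result equals the std of the concatenated
    samples (population convention, ddof=0).
    """
    n_tot = sum(n for n, _, _ in parts)
    if n_tot == 0:
        raise ValidationError("cannot pool empty blocks")
    mean = sum(n * m for n, m, _ in parts) / n_tot
    var = sum(n * (s * s + (m - mean) ** 2) for n, m, s in parts) / n_tot
    return float(mean), float(math.sqrt(max(var, 0.0)))


def assemble_events(
    alignment: AlignmentResult,
    segmentation: Segmentation,
    signal: np.ndarray,
    kmers: RefKmerSeq,
    read_id: str = "read",
    min_base_len: int = 3,
) -> list[Event]:
    """Merge base blocks aligned to the same k-mer into per-k-mer events.

    Event mean and std are the pooled statistics of the member-block
    samples; samples inside intervening transition blocks are excluded.
    K-mers hit only by deletion steps yield no event.  Events come back in
    reference-coordinate order.
    """
    y = np.asarray(signal, dtype=float)
    base_blocks = segmentation.base_blocks
    mapping = alignment.kmer_of_mean()
    if mapping and max(mapping) > len(base_blocks):
        raise ValidationError("alignment indices inconsistent with segmentation")
    by_kmer: dict[int, list[int]] = {}
    for i_mean, j_kmer in sorted(mapping.items()):
        by_kmer.setdefault(j_kmer, []).append(i_mean)
    events: list[Event] = []
    for j_kmer, mean_idx in by_kmer.items():
        parts = []
        for i in mean_idx:
            blk = base_blocks[i - 1]
            part = y[blk.start : blk.end]
            if blk.keep is not None:
                part = part[blk.keep]
            parts.append(part)
        merged = np.concatenate(parts)
        if merged.size < min_base_len:
            continue
        mean, std = pooled_mean_std(
            [(p.size, float(np.mean(p)), float(np.std(p))) for p in parts]
        )
        events.append(
            Event(
                reference_id=kmers.reference_id,
                position=kmers.positions[j_kmer - 1],
                model_kmer=kmers.kmers[j_kmer - 1],
                event_mean=mean,
                event_std=std,
                dwell=int(merged.size),
                start_idx=base_blocks[mean_idx[0] - 1].start,
                end_idx=base_blocks[mean_idx[-1] - 1].end,
                read_id=read_id,
                samples=merged,
            )
        )
    events.sort(key=lambda e: e.position)
    return events


def m6anet_features(events: list[Event], position: int) -> np.ndarray | None:
    """Nine-feature vector (mean, std, dwell of positions i-1, i, i+1).

    Returns ``None`` when any of the three consecutive events is missing
    for this read (e.g. lost to a deletion step).
    """
    by_pos = {e.position: e for e in events}
    triple = [by_pos.get(position - 1), by_pos.get(position), by_pos.get(position + 1)]
    if any(e is None for e in triple):
        return None
    return np.array(
        [v for e in triple for v in (e.event_mean, e.event_std, float(e.dwell))]
    )


EVENTALIGN_COLUMNS = [
    "contig",
    "position",
    "reference_kmer",
    "read_name",
    "event_level_mean",
    "event_stdv",
    "event_length",
    "start_idx",
    "end_idx",
    "model_kmer",
]


def events_to_frame(events: list[Event]) -> pd.DataFrame:
    rows = [
        {
            "contig": e.reference_id,
            "position": e.position,
            "reference_kmer": e.model_kmer,
            "read_name": e.read_id,
            "event_level_mean": round(e.event_mean, 6),
            "event_stdv": round(e.event_std, 6),
            "event_length": e.dwell,
            "start_idx": e.start_idx,
            "end_idx": e.end_idx,
            "model_kmer": e.model_kmer,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENTALIGN_COLUMNS)


def write_eventalign(events: list[Event], path: str | Path) -> None:
    """Write events as an eventalign-style TSV (header always present)."""
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_eventalign(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENTALIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing eventalign columns {missing}")
    return df


def frame_to_events(df: pd.DataFrame) -> list[Event]:
    return [
        Event(
            reference_id=str(r.contig),
            position=int(r.position),
            model_kmer=str(r.model_kmer),
            event_mean=float(r.event_level_mean),
            event_std=float(r.event_stdv),
            dwell=int(r.event_length),
            start_idx=int(r.start_idx),
            end_idx=int(r.end_idx),
            read_id=str(r.read_name),
        )
        for r in df.itertuples(index=False)
    ]
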