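"""Synthetic direct-RNA reads under the jiggling translocation model.

Each read is a poly(A) segment followed by alternating base and transition
blocks traversing the reference 3'->5' (pore order).  Within a base block
for k-mer s, samples are drawn from the current k-mer's Gaussian baseline
with occasional excursions to the previous/next k-mer baseline ('jiggling')
and rare uniform noise; transition blocks are steep linear ramps between
neighbouring block baselines.  Every read carries full ground truth:
block boundaries with generating k-mer, per-sample hidden-state labels and
per-site modification states, which makes the simulator the test bed for
segmentation, alignment and modification calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from squigseg.errors import ValidationError
from squigseg.hhmm import Block
from squigseg.kmer_table import KmerTable, KmerParams, is_drach, normalize_kmer

# per-sample hidden-state label codes
LABELS = ("prev", "curr", "next", "noise", "transition", "polyA")
L_PREV, L_CURR, L_NEXT, L_NOISE, L_TRANS, L_POLYA = range(6)


@dataclass
class SimConfig:
    """Generating parameters of the jiggling-translocation simulator.

    Defaults emulate RNA002-like sequencing: ~35 samples of residence per
    k-mer, short steep transition ramps (~5.5 samples on average),
    5% backward and 5% forward excursions per sample, 1% uniform noise,
    and a long stable poly(A) tail used for standardization.  A small
    per-read gain/offset jitter reproduces pore-to-pore variability and is
    undone by poly(A) standardization.
    """

    table: KmerTable
    p_prev: float = 0.05
    p_next: float = 0.05
    p_noise: float = 0.01
    dwell_mean: float = 35.0
    n_blocks_per_kmer_max: int = 1
    trans_len_range: tuple[int, int] = (3, 8)
    noise_range: tuple[float, float] | None = None
    polya_len: int = 1000
    mod_rate: float = 0.0
    seed: int = 0
    # sub-state baseline spread when a k-mer emits several base blocks
    sub_state_sigma: float = 3.0
    trans_residual_sigma: float = 0.3
    # per-read affine distortion (pore-to-pore variability)
    gain_sd: float = 0.02
    offset_sd: float = 1.5
    # run-length excursion variant (off: excursions are i.i.d. per sample)
    excursion_runs: bool = False
    excursion_run_mean: float = 3.0

    def __post_init__(self) -> None:
        if self.p_prev + self.p_next + self.p_noise >= 1.0:
            raise ValidationError("p_prev + p_next + p_noise must be < 1")
        if min(self.p_prev, self.p_next, self.p_noise) < 0:
            raise ValidationError("excursion probabilities must be >= 0")
        if self.dwell_mean < 3:
            raise ValidationError("dwell_mean must be >= 3")
        lo, hi = self.trans_len_range
        if not (1 <= lo <= hi <= 20):
            raise ValidationError("trans_len_range must lie within [1, 20]")
        if not (0.0 <= self.mod_rate <= 1.0):
            raise ValidationError("mod_rate must be in [0, 1]")
        if self.n_blocks_per_kmer_max < 1:
            raise ValidationError("n_blocks_per_kmer_max must be >= 1")

    def effective_noise_range(self) -> tuple[float, float]:
        if self.noise_range is not None:
            return self.noise_range
        mus = [p.mu_un for p in self.table.entries.values()]
        sigmas = [p.sigma_un for p in self.table.entries.values()]
        pad = 3.0 * max(sigmas)
        return min(mus) - pad, max(mus) + pad


@dataclass
class SimRead:
    """A simulated read plus its complete generating truth."""

    read_id: str
    signal: np.ndarray
    reference_id: str
    truth_blocks: list[Block]
    truth_states: np.ndarray  # int8 codes into LABELS, one per sample
    truth_mods: dict[int, bool]  # reference position (DRACH centre) -> modified
    polya_interval: tuple[int, int]
    transcript_interval: tuple[int, int]
    gain: float = 1.0
    offset: float = 0.0

    def state_labels(self) -> list[str]:
        return [LABELS[c] for c in self.truth_states]

    def boundaries(self) -> list[int]:
        """Interior truth block boundaries, in transcript-region coordinates."""
        t0 = self.transcript_interval[0]
        return [b.start - t0 for b in self.truth_blocks[1:]]


def synthetic_table(
    k: int = 5,
    seed: int = 0,
    level_range: tuple[float, float] = (78.0, 132.0),
    sigma_range: tuple[float, float] = (1.8, 2.6),
) -> KmerTable:
    """A complete random k-mer table with RNA002-like level spread.

    Levels are i.i.d. uniform over ``level_range`` (the approximate span of
    the RNA002 pore model) and per-k-mer stds uniform over ``sigma_range``.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    kmers = [""]
    for _ in range(k):
        kmers = [s + b for s in kmers for b in bases]
    entries = {}
    for kmer in kmers:
        entries[kmer] = KmerParams(
            kmer=kmer,
            mu_un=float(rng.uniform(*level_range)),
            sigma_un=float(rng.uniform(*sigma_range)),
        )
    return KmerTable(k=k, entries=entries)


def _kmer_mu_sigma(params: KmerParams, modified: bool) -> tuple[float, float]:
    if modified and params.mod_enabled:
        return params.mu_mod, params.sigma_mod
    return params.mu_un, params.sigma_un


def drach_sites(reference: str) -> list[int]:
    """Reference positions of DRACH-motif centres (the potentially modified A)."""
    ref = normalize_kmer(reference)
    return [c for c in range(2, len(ref) - 2) if is_drach(ref[c - 2 : c + 3])]


def simulate_read(
    reference: str,
    config: SimConfig,
    rng: np.random.Generator,
    read_id: str = "sim_read",
    reference_id: str = "ref",
) -> SimRead:
    """Generate one read traversing ``reference`` 3'->5' in pore order."""
    ref = normalize_kmer(reference)
    if not set(ref) <= set("ACGT"):
        bad = sorted(set(ref) - set("ACGT"))
        raise ValidationError(f"reference contains non-ACGTU symbols: {bad}")
    k = config.table.k
    if len(ref) < k:
        raise ValidationError(f"reference shorter than k = {k}")
    positions = list(range(len(ref) - k, -1, -1))  # pore order: 3' -> 5'
    kmer_at = {}
    for q in positions:
        kmer = ref[q : q + k]
        if kmer not in config.table:
            raise ValidationError(f"k-mer {kmer!r} missing from table")
        kmer_at[q] = config.table.lookup(kmer)

    # modification truth at DRACH centres
    centre_off = k // 2
    mods: dict[int, bool] = {}
    if k == 5:
        for c in drach_sites(ref):
            mods[c] = bool(rng.random() < config.mod_rate)

    def baseline(q: int) -> tuple[float, float]:
        p = kmer_at[q]
        modified = mods.get(q + centre_off, False)
        return _kmer_mu_sigma(p, modified)

    lo_n, hi_n = config.effective_noise_range()
    p_pr, p_nx, p_no = config.p_prev, config.p_next, config.p_noise

    samples: list[np.ndarray] = []
    states: list[np.ndarray] = []
    blocks: list[Block] = []

    mu_a, sd_a = _polya_baseline(config)
    polya = rng.normal(mu_a, sd_a, config.polya_len)
    samples.append(polya)
    states.append(np.full(config.polya_len, L_POLYA, dtype=np.int8))
    cursor = config.polya_len
    polya_interval = (0, cursor)

    # plan base blocks: (ref position, baseline mu with sub-state offset, sigma)
    plan: list[tuple[int, float, float]] = []
    for q in positions:
        mu, sigma = baseline(q)
        n_sub = int(rng.integers(1, config.n_blocks_per_kmer_max + 1))
        for _ in range(n_sub):
            off = rng.normal(0.0, config.sub_state_sigma) if n_sub > 1 else 0.0
            plan.append((q, mu + off, sigma))

    for bi, (q, mu, sigma) in enumerate(plan):
        # transition ramp from the previous block baseline to this one
        if bi > 0:
            prev_mu = plan[bi - 1][1]
            tlen = int(rng.integers(config.trans_len_range[0], config.trans_len_range[1] + 1))
            ramp = np.linspace(prev_mu, mu, tlen + 2)[1:-1]
            ramp = ramp + rng.normal(0.0, config.trans_residual_sigma, tlen)
            samples.append(ramp)
            states.append(np.full(tlen, L_TRANS, dtype=np.int8))
            blocks.append(Block(cursor, cursor + tlen, "T", float(np.mean(ramp)), float(np.std(ramp))))
            cursor += tlen

        dwell = 3 + int(rng.poisson(config.dwell_mean - 3.0))
        # neighbouring k-mer baselines in pore order (prev = already sequenced)
        i_pore = positions.index(q)
        mu_prev = baseline(positions[i_pore - 1])[0] if i_pore > 0 else None
        mu_next = baseline(positions[i_pore + 1])[0] if i_pore + 1 < len(positions) else None

        st = _draw_states(rng, dwell, p_pr if mu_prev is not None else 0.0,
                          p_nx if mu_next is not None else 0.0, p_no, config)
        vals = np.empty(dwell)
        for label, mu_s in ((L_PREV, mu_prev), (L_CURR, mu), (L_NEXT, mu_next)):
            mask = st == label
            if mask.any():
                vals[mask] = rng.normal(mu_s, sigma, int(mask.sum()))
        mask = st == L_NOISE
        if mask.any():
            vals[mask] = rng.uniform(lo_n, hi_n, int(mask.sum()))
        samples.append(vals)
        states.append(st)
        blocks.append(Block(cursor, cursor + dwell, "B", mu, sigma, kmer_index=q))
        cursor += dwell

    signal = np.concatenate(samples)
    truth_states = np.concatenate(states)
    gain = float(rng.normal(1.0, config.gain_sd)) if config.gain_sd > 0 else 1.0
    offset = float(rng.normal(0.0, config.offset_sd)) if config.offset_sd > 0 else 0.0
    signal = gain * signal + offset
    return SimRead(
        read_id=read_id,
        signal=signal,
        reference_id=reference_id,
        truth_blocks=blocks,
        truth_states=truth_states,
        truth_mods=mods,
        polya_interval=polya_interval,
        transcript_interval=(polya_interval[1], cursor),
        gain=gain,
        offset=offset,
    )


def _polya_baseline(config: SimConfig) -> tuple[float, float]:
    all_a = "A" * config.table.k
    if all_a not in config.table:
        raise ValidationError("table lacks the all-A k-mer needed for the poly(A) segment")
    p = config.table.lookup(all_a)
    return p.mu_un, p.sigma_un


def _draw_states(
    rng: np.random.Generator,
    n: int,
    p_prev: float,
    p_next: float,
    p_noise: float,
    config: SimConfig,
) -> np.ndarray:
    probs = np.array([p_prev, 1.0 - p_prev - p_next - p_noise, p_next, p_noise])
    if not config.excursion_runs:
        return rng.choice(4, size=n, p=probs).astype(np.int8)
    # run-length variant: excursions persist for a geometric number of samples
    st = np.empty(n, dtype=np.int8)
    i = 0
    while i < n:
        s = int(rng.choice(4, p=probs))
        run = 1 if s == L_CURR else 1 + int(rng.geometric(1.0 / config.excursion_run_mean) - 1)
        run = min(run, n - i)
        st[i : i + run] = s
        i += run
    return st


def _read_references(references) -> dict[str, str]:
    if isinstance(references, dict):
        refs = dict(references)
    else:
        from Bio import SeqIO

        refs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(references), "fasta")}
    if not refs:
        raise ValidationError("no reference sequences provided")
    return {rid: normalize_kmer(seq) for rid, seq in refs.items()}


def simulate_dataset(
    references,
    n_reads: int,
    config: SimConfig,
    out_dir: str | Path | None = None,
) -> tuple[list[SimRead], pd.DataFrame]:
    """Simulate ``n_reads`` reads cycling over the references.

    ``references`` may be a FASTA path or a mapping id -> sequence.
    Per-read RNGs are spawned deterministically from ``config.seed``, so a
    given (seed, n_reads, references) triple always reproduces the same
    dataset.  When ``out_dir`` is given, writes the signal container
    (``signals/<read_id>.txt``, one pA value per line), ``manifest.tsv``
    and ground-truth TSVs (``truth_blocks.tsv``, ``truth_mods.tsv``).
    """
    if n_reads < 1:
        raise ValidationError("n_reads must be >= 1")
    refs = _read_references(references)
    ids = sorted(refs)
    reads: list[SimRead] = []
    rows = []
    for i in range(n_reads):
        rid = ids[i % len(ids)]
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, i)))
        read = simulate_read(refs[rid], config, rng, read_id=f"read_{i:05d}", reference_id=rid)
        reads.append(read)
        rows.append(
            {
                "read_id": read.read_id,
                "reference_id": rid,
                "polya_start": read.polya_interval[0],
                "polya_end": read.polya_interval[1],
                "transcript_start": read.transcript_interval[0],
                "transcript_end": read.transcript_interval[1],
                "n_samples": read.signal.size,
                "gain": read.gain,
                "offset": read.offset,
            }
        )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "signals").mkdir(parents=True, exist_ok=True)
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        blk_rows, mod_rows = [], []
        for read in reads:
            np.savetxt(out / "signals" / f"{read.read_id}.txt", read.signal, fmt="%.4f")
            for j, b in enumerate(read.truth_blocks):
                blk_rows.append(
                    {
                        "read_id": read.read_id,
                        "block_index": j,
                        "label": b.label,
                        "start": b.start,
                        "end": b.end,
                        "mean": b.mean,
                        "std": b.std,
                        "ref_position": -1 if b.kmer_index is None else b.kmer_index,
                    }
                )
            for pos, state in sorted(read.truth_mods.items()):
                mod_rows.append(
                    {
                        "read_id": read.read_id,
                        "reference_id": read.reference_id,
                        "position": pos,
                        "modified": int(state),
                    }
                )
        pd.DataFrame(blk_rows).to_csv(out / "truth_blocks.tsv", sep="\t", index=False)
        pd.DataFrame(mod_rows).to_csv(out / "truth_mods.tsv", sep="\t", index=False)
    return reads, manifest
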