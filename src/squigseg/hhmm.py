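"""Hierarchical HMM segmentation of a read's current trace.

The outer layer divides the signal into alternating base (B) and transition
(T) blocks.  The emission probability of a base block comes from an inner
four-state HMM ('prev', 'curr', 'next', 'noise') that models the jiggling
translocation of the RNA: during one k-mer's residence the motor protein can
briefly pull the molecule back or push it forward, so individual samples
transiently match the neighbouring k-mer baselines.  'prev'/'curr'/'next'
emit Gaussians sharing one std; 'noise' emits uniformly over a wide current
interval.  Transition blocks are modelled by a steep straight line with
Gaussian residuals.

Segmentation maximizes the joint likelihood (block emissions plus the outer
chain's per-sample transition probabilities) with an exact dynamic program
over a candidate-changepoint lattice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from squigseg.errors import ValidationError

# inner-HMM state order used throughout
STATE_PREV, STATE_CURR, STATE_NEXT, STATE_NOISE = 0, 1, 2, 3
STATE_NAMES = ("prev", "curr", "next", "noise")

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class InnerHMMParams:
    """Parameters of the four-state inner HMM over one base block."""

    transition: np.ndarray = field(
        default_factory=lambda: np.tile([0.05, 0.89, 0.05, 0.01], (4, 1))
    )
    initial: np.ndarray = field(default_factory=lambda: np.array([0.05, 0.89, 0.05, 0.01]))
    # shared emission std of prev/curr/next; None = estimate per signal from
    # robust first differences (clipped to [0.8, 5.0] pA)
    sigma_inner: float | None = None
    noise_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transition.shape != (4, 4):
            raise ValidationError("inner transition matrix must be 4x4")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("inner transition rows must sum to 1")
        if not math.isclose(float(self.initial.sum()), 1.0, abs_tol=1e-9):
            raise ValidationError("inner initial distribution must sum to 1")
        if self.sigma_inner is not None and self.sigma_inner <= 0:
            raise ValidationError("sigma_inner must be > 0")


@dataclass
class OuterHMMParams:
    """Parameters of the outer B/T chain (state order: B, T)."""

    t_outer: np.ndarray = field(
        default_factory=lambda: np.array([[0.99, 0.01], [0.17, 0.83]])
    )
    pi_outer: np.ndarray = field(default_factory=lambda: np.array([0.99, 0.01]))
    min_base_len: int = 3
    min_trans_len: int = 3
    max_trans_len: int = 10
    # longest base block the DP will consider between non-adjacent candidates;
    # adjacent candidate pairs are always allowed so degenerate inputs still
    # yield a single spanning block
    max_base_span: int = 150

    def __post_init__(self) -> None:
        self.t_outer = np.asarray(self.t_outer, dtype=float)
        self.pi_outer = np.asarray(self.pi_outer, dtype=float)
        if not np.allclose(self.t_outer.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("outer transition rows must sum to 1")


@dataclass
class TransitionModelParams:
    """Straight-line model of a transition block."""

    min_abs_slope: float = 0.2  # pA per sample; shallower lines are not transitions
    residual_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.min_abs_slope <= 0:
            raise ValidationError("min_abs_slope must be > 0")


@dataclass
class Block:
    """One segment of the signal: base (label 'B') or transition ('T')."""

    start: int
    end: int
    label: str
    mean: float
    std: float
    kmer_index: int | None = None  # set by the simulator's ground truth
    # which samples of a base block were attributed to the 'curr' state and
    # entered the block statistics (None: all samples)
    keep: np.ndarray | None = None

    @property
    def n_kept(self) -> int:
        return self.n if self.keep is None else int(self.keep.sum())

    @property
    def n(self) -> int:
        return self.end - self.start


@dataclass
class Segmentation:
    """Ordered alternating B/T blocks tiling one read's (sub)signal."""

    read_id: str
    blocks: list[Block]
    total_loglik: float
    flags: list[str] = field(default_factory=list)

    @property
    def base_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.label == "B"]

    def boundaries(self) -> list[int]:
        """Interior block boundaries (sample indices between blocks)."""
        return [b.start for b in self.blocks[1:]]


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _emissions(y, mu_prev, mu_curr, mu_next, prev_ok, next_ok, sigma, lo, hi):
    """(n, 4) log emission densities for the inner HMM."""
    n = y.shape[0]
    out = np.empty((n, 4))
    log_norm = -0.5 * math.log(2.0 * math.pi) - math.log(sigma)
    log_unif = -math.log(hi - lo) if hi > lo else -np.inf
    inv2s2 = 0.5 / (sigma * sigma)
    for i in range(n):
        v = y[i]
        out[i, 0] = log_norm - (v - mu_prev) ** 2 * inv2s2 if prev_ok else -np.inf
        out[i, 1] = log_norm - (v - mu_curr) ** 2 * inv2s2
        out[i, 2] = log_norm - (v - mu_next) ** 2 * inv2s2 if next_ok else -np.inf
        out[i, 3] = log_unif if lo <= v <= hi else -np.inf
    return out


@njit(cache=True)
def _forward(emis, log_trans, log_init):
    """Log marginal likelihood of the inner HMM by the forward algorithm."""
    n = emis.shape[0]
    alpha = np.empty(4)
    for s in range(4):
        alpha[s] = log_init[s] + emis[0, s]
    work = np.empty(4)
    for t in range(1, n):
        new = np.empty(4)
        for s in range(4):
            for r in range(4):
                work[r] = alpha[r] + log_trans[r, s]
            m = work[0]
            for r in range(1, 4):
                if work[r] > m:
                    m = work[r]
            if m == -np.inf:
                new[s] = -np.inf
            else:
                acc = 0.0
                for r in range(4):
                    acc += math.exp(work[r] - m)
                new[s] = m + math.log(acc) + emis[t, s]
        alpha = new
    m = alpha[0]
    for s in range(1, 4):
        if alpha[s] > m:
            m = alpha[s]
    if m == -np.inf:
        return -np.inf
    acc = 0.0
    for s in range(4):
        acc += math.exp(alpha[s] - m)
    return m + math.log(acc)


@njit(cache=True)
def _forward_backward(emis, log_trans, log_init):
    """Per-sample posterior state probabilities (n, 4)."""
    n = emis.shape[0]
    la = np.empty((n, 4))
    lb = np.empty((n, 4))
    for s in range(4):
        la[0, s] = log_init[s] + emis[0, s]
        lb[n - 1, s] = 0.0
    work = np.empty(4)
    for t in range(1, n):
        for s in range(4):
            for r in range(4):
                work[r] = la[t - 1, r] + log_trans[r, s]
            m = work[0]
            for r in range(1, 4):
                if work[r] > m:
                    m = work[r]
            if m == -np.inf:
                la[t, s] = -np.inf
            else:
                acc = 0.0
                for r in range(4):
                    acc += math.exp(work[r] - m)
                la[t, s] = m + math.log(acc) + emis[t, s]
    for t in range(n - 2, -1, -1):
        for s in range(4):
            for r in range(4):
                work[r] = log_trans[s, r] + emis[t + 1, r] + lb[t + 1, r]
            m = work[0]
            for r in range(1, 4):
                if work[r] > m:
                    m = work[r]
            if m == -np.inf:
                lb[t, s] = -np.inf
            else:
                acc = 0.0
                for r in range(4):
                    acc += math.exp(work[r] - m)
                lb[t, s] = m + math.log(acc)
    post = np.empty((n, 4))
    for t in range(n):
        m = -np.inf
        for s in range(4):
            post[t, s] = la[t, s] + lb[t, s]
            if post[t, s] > m:
                m = post[t, s]
        if m == -np.inf:
            for s in range(4):
                post[t, s] = 0.25
        else:
            acc = 0.0
            for s in range(4):
                post[t, s] = math.exp(post[t, s] - m)
                acc += post[t, s]
            for s in range(4):
                post[t, s] /= acc
    return post


@njit(cache=True)
def _block_loglik_fused(y, a, b, mu_prev, mu_curr, mu_next, prev_ok, next_ok,
                        sigma, lo, hi, log_trans, log_init):
    """Forward loglik of y[a:b] with emissions computed on the fly."""
    log_norm = -0.5 * math.log(2.0 * math.pi) - math.log(sigma)
    log_unif = -math.log(hi - lo) if hi > lo else -np.inf
    inv2s2 = 0.5 / (sigma * sigma)
    alpha = np.empty(4)
    work = np.empty(4)
    emis = np.empty(4)
    for t in range(a, b):
        v = y[t]
        emis[0] = log_norm - (v - mu_prev) ** 2 * inv2s2 if prev_ok else -np.inf
        emis[1] = log_norm - (v - mu_curr) ** 2 * inv2s2
        emis[2] = log_norm - (v - mu_next) ** 2 * inv2s2 if next_ok else -np.inf
        emis[3] = log_unif if lo <= v <= hi else -np.inf
        if t == a:
            for s in range(4):
                alpha[s] = log_init[s] + emis[s]
            continue
        new = np.empty(4)
        for s in range(4):
            for r in range(4):
                work[r] = alpha[r] + log_trans[r, s]
            m = work[0]
            for r in range(1, 4):
                if work[r] > m:
                    m = work[r]
            if m == -np.inf:
                new[s] = -np.inf
            else:
                acc = 0.0
                for r in range(4):
                    acc += math.exp(work[r] - m)
                new[s] = m + math.log(acc) + emis[s]
        for s in range(4):
            alpha[s] = new[s]
    m = alpha[0]
    for s in range(1, 4):
        if alpha[s] > m:
            m = alpha[s]
    if m == -np.inf:
        return -np.inf
    acc = 0.0
    for s in range(4):
        acc += math.exp(alpha[s] - m)
    return m + math.log(acc)


def _log_chain(params: InnerHMMParams, prev_ok: bool, next_ok: bool):
    """Log transition matrix / initial vector with inactive states zeroed out."""
    trans = params.transition.copy()
    init = params.initial.copy()
    for ok, s in ((prev_ok, STATE_PREV), (next_ok, STATE_NEXT)):
        if not ok:
            trans[:, s] = 0.0
            init[s] = 0.0
    trans /= trans.sum(axis=1, keepdims=True)
    init /= init.sum()
    with np.errstate(divide="ignore"):
        return np.log(trans), np.log(init)


def _noise_bounds(params: InnerHMMParams, signal: np.ndarray) -> tuple[float, float]:
    if params.noise_bounds is not None:
        return params.noise_bounds
    return float(np.min(signal)) - 5.0, float(np.max(signal)) + 5.0


def estimate_noise_sigma(signal: np.ndarray) -> float:
    """Robust per-sample noise std from first differences (MAD-based)."""
    d = np.diff(np.asarray(signal, dtype=float))
    if d.size == 0:
        return 0.8
    sigma = float(np.median(np.abs(d))) * 1.4826 / math.sqrt(2.0)
    return float(np.clip(sigma, 0.8, 5.0))


def _sigma_inner(params: InnerHMMParams, signal: np.ndarray) -> float:
    if params.sigma_inner is not None:
        return params.sigma_inner
    return estimate_noise_sigma(signal)


# ---------------------------------------------------------------------------
# public operations


def inner_block_loglik(
    samples: np.ndarray,
    mu_prev: float | None,
    mu_curr: float,
    mu_next: float | None,
    params: InnerHMMParams,
) -> float:
    """Log marginal likelihood of a base block under the inner HMM.

    ``mu_prev``/``mu_next`` may be ``None`` (first/last block of a read),
    which disables the corresponding hidden state.  Computed in log space;
    returns -inf when every path has zero density.
    """
    y = np.ascontiguousarray(samples, dtype=float)
    if y.size < 1:
        raise ValidationError("base block needs at least one sample")
    lo, hi = _noise_bounds(params, y)
    prev_ok, next_ok = mu_prev is not None, mu_next is not None
    emis = _emissions(
        y,
        float(mu_prev) if prev_ok else 0.0,
        float(mu_curr),
        float(mu_next) if next_ok else 0.0,
        prev_ok,
        next_ok,
        _sigma_inner(params, y),
        lo,
        hi,
    )
    log_trans, log_init = _log_chain(params, prev_ok, next_ok)
    return float(_forward(emis, log_trans, log_init))


def inner_posteriors(
    samples: np.ndarray,
    mu_prev: float | None,
    mu_curr: float,
    mu_next: float | None,
    params: InnerHMMParams,
) -> np.ndarray:
    """Forward-backward posterior over (prev, curr, next, noise) per sample."""
    y = np.ascontiguousarray(samples, dtype=float)
    if y.size < 1:
        raise ValidationError("base block needs at least one sample")
    lo, hi = _noise_bounds(params, y)
    prev_ok, next_ok = mu_prev is not None, mu_next is not None
    emis = _emissions(
        y,
        float(mu_prev) if prev_ok else 0.0,
        float(mu_curr),
        float(mu_next) if next_ok else 0.0,
        prev_ok,
        next_ok,
        _sigma_inner(params, y),
        lo,
        hi,
    )
    log_trans, log_init = _log_chain(params, prev_ok, next_ok)
    return np.asarray(_forward_backward(emis, log_trans, log_init))


def transition_block_loglik(samples: np.ndarray, params: TransitionModelParams) -> float:
    """Log likelihood of a transition block under the steep-line model.

    Fits an ordinary least-squares line; blocks whose fitted |slope| falls
    below ``min_abs_slope`` are inadmissible as transitions (-inf), as are
    blocks of fewer than two samples.
    """
    y = np.asarray(samples, dtype=float)
    n = y.size
    if n < 2:
        return -np.inf
    # closed-form OLS line fit
    x = np.arange(n, dtype=float)
    xm, ym = (n - 1) / 2.0, float(np.mean(y))
    sxx = float(np.sum((x - xm) ** 2))
    slope = float(np.sum((x - xm) * (y - ym))) / sxx
    if abs(slope) < params.min_abs_slope:
        return -np.inf
    resid = y - (ym + slope * (x - xm))
    s = params.residual_sigma
    return float(-0.5 * n * (_LOG_2PI + 2.0 * math.log(s)) - np.sum(resid**2) / (2.0 * s * s))


def propose_changepoints(
    signal: np.ndarray,
    window: int = 16,
    mad_factor: float = 0.75,
    min_gap: int = 3,
) -> np.ndarray:
    """Candidate block boundaries from a smoothed first difference.

    The statistic at boundary position i is the absolute difference between
    the median of the ``window`` samples after i and the median of the
    ``window`` samples before i (a smoothed, excursion-robust derivative:
    isolated jiggling samples inside a window would inflate a plain mean);
    the signal is reflect-padded so boundaries near the edges are scored
    too.  The threshold is ``mad_factor`` times the statistic's noise floor,
    estimated robustly from the MAD of the signal's first difference (the
    score's own distribution is useless as a reference because genuine
    steps cover a large fraction of positions).  Each contiguous run above
    threshold contributes its peak neighbourhood and its edges, since a
    ramp's true boundaries sit at the ends of the run.  0 and n are always
    included.  Oriented toward recall: downstream the DP decides which
    candidates are real boundaries.
    """
    y = np.asarray(signal, dtype=float)
    n = y.size
    if n < window + 1:
        return np.array([0, n], dtype=int)
    yp = np.pad(y, window, mode="reflect")
    # meds[i] = median(yp[i:i+window])
    meds = np.median(np.lib.stride_tricks.sliding_window_view(yp, window), axis=1)
    # boundary b in [0, n] -> |median(y[b:b+w]) - median(y[b-w:b])|
    score = np.abs(meds[window : window + n + 1] - meds[: n + 1])
    # per-sample noise std from robust first differences; the difference of
    # two window-medians then has std ~ 1.25 * sigma * sqrt(2/window)
    sigma = np.median(np.abs(np.diff(y))) * 1.4826 / math.sqrt(2.0)
    score_sd = 1.25 * sigma * math.sqrt(2.0 / window)
    thr = mad_factor * max(score_sd, 1e-12)
    above = score > thr
    cands: set[int] = set()
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j < above.size and above[j]:
                j += 1
            peak = i + int(np.argmax(score[i:j]))
            cands.update(range(peak - 3, peak + 4))
            # the statistic plateaus over the ramp (and argmax skews to the
            # plateau's first index), so seed the whole run, subsampled
            cands.update(range(i, j + 1, 2))
            cands.add(j)
            i = j
        else:
            i += 1
    ordered = sorted({c_ for c_ in cands if 0 < c_ < n} | {0, n})
    thinned = [ordered[0]]
    for c_ in ordered[1:]:
        if c_ - thinned[-1] >= min_gap or c_ == n:
            thinned.append(c_)
    if thinned[-1] != n:
        thinned.append(n)
    return np.asarray(thinned, dtype=int)


def _trimmed_mean(x: np.ndarray) -> float:
    """10% two-sided trimmed mean (plain mean below 5 samples)."""
    n = x.size
    if n == 0:
        return math.nan
    if n < 5:
        return float(np.mean(x))
    k = int(0.1 * n)
    if k == 0:
        return float(np.mean(x))
    xs = np.sort(x)
    return float(np.mean(xs[k : n - k]))


def segment(
    signal: np.ndarray,
    outer: OuterHMMParams | None = None,
    inner: InnerHMMParams | None = None,
    trans: TransitionModelParams | None = None,
    read_id: str = "read",
    candidates: np.ndarray | None = None,
) -> Segmentation:
    """Segment a standardized transcript-region signal into B/T blocks.

    An exact dynamic program over the candidate-changepoint lattice
    maximizes block emission log likelihoods (inner HMM for B blocks,
    steep-line model for T blocks) plus the outer chain's per-sample
    transition log probabilities.  The block sequence alternates B,T,...,B.
    Base-block mean/std are computed over samples attributed to the 'curr'
    state (posterior >= 0.5); jiggling-excursion and noise samples are
    masked so the block statistics describe the residing k-mer's own level.
    """
    outer = outer or OuterHMMParams()
    inner = inner or InnerHMMParams()
    trans = trans or TransitionModelParams()
    y = np.ascontiguousarray(signal, dtype=float)
    n = y.size
    if n == 0:
        raise ValidationError("empty signal")
    if n < outer.min_base_len:
        blk = Block(0, n, "B", float(np.mean(y)), float(np.std(y)))
        return Segmentation(read_id, [blk], -np.inf, flags=["short_signal"])

    if candidates is None:
        candidates = propose_changepoints(y)
    cand = np.asarray(sorted(set(map(int, candidates)) | {0, n}), dtype=int)
    cand = cand[(cand >= 0) & (cand <= n)]
    m = cand.size - 1  # number of lattice cells

    lo, hi = _noise_bounds(inner, y)
    inner_eff = InnerHMMParams(
        transition=inner.transition,
        initial=inner.initial,
        sigma_inner=_sigma_inner(inner, y),
        noise_bounds=(lo, hi),
    )
    log_t = np.log(outer.t_outer)
    log_pi = np.log(outer.pi_outer)

    ctx = 12  # samples of context used to estimate neighbouring baselines

    # context means depend only on the candidate position -> precompute
    mu_before = {int(a): _trimmed_mean(y[max(0, a - ctx):a]) for a in cand if a > 0}
    mu_after = {int(b): _trimmed_mean(y[b:b + ctx]) for b in cand if b < n}
    chains = {
        (pok, nok): _log_chain(inner_eff, pok, nok)
        for pok in (False, True)
        for nok in (False, True)
    }

    def bscore(a: int, b: int) -> float:
        mu_curr = _trimmed_mean(y[a:b])
        prev_ok, next_ok = a > 0, b < n
        log_trans, log_init = chains[(prev_ok, next_ok)]
        return float(
            _block_loglik_fused(
                y, a, b,
                mu_before.get(a, 0.0), mu_curr, mu_after.get(b, 0.0),
                prev_ok, next_ok,
                inner_eff.sigma_inner, lo, hi, log_trans, log_init,
            )
        )

    NEG = -np.inf
    # dp[j][0] -> best (score, nblocks, backpointer) for a B block ending at cand[j]
    # dp[j][1] -> same for a T block
    dp_score = np.full((m + 1, 2), NEG)
    dp_nblk = np.zeros((m + 1, 2), dtype=int)
    back = np.full((m + 1, 2), -1, dtype=int)
    dp_score[0, 0] = 0.0  # virtual start; first real block must be B from cand[0]

    for j in range(1, m + 1):
        tj = cand[j]
        for i in range(j - 1, -1, -1):
            ti = cand[i]
            length = tj - ti
            # B block candidate from ti to tj (span-capped except adjacent pairs)
            if length >= outer.min_base_len and (
                length <= outer.max_base_span or i == j - 1
            ):
                if i == 0:
                    prev_ok = True
                    base = log_pi[0]
                elif dp_score[i, 1] > NEG:
                    prev_ok = True
                    base = dp_score[i, 1] + log_t[1, 0]
                else:
                    prev_ok = False
                if prev_ok:
                    sc = base + bscore(ti, tj) + (length - 1) * log_t[0, 0]
                    nb = (dp_nblk[i, 1] if i > 0 else 0) + 1
                    if sc > dp_score[j, 0] + 1e-12 or (
                        sc > dp_score[j, 0] - 1e-12 and nb < dp_nblk[j, 0]
                    ):
                        dp_score[j, 0] = sc
                        dp_nblk[j, 0] = nb
                        back[j, 0] = i
            # T block candidate from ti to tj (cannot start the read)
            if outer.min_trans_len <= length <= outer.max_trans_len and i > 0 and dp_score[i, 0] > NEG:
                tl = transition_block_loglik(y[ti:tj], trans)
                if tl > NEG:
                    sc = dp_score[i, 0] + log_t[0, 1] + tl + (length - 1) * log_t[1, 1]
                    nb = dp_nblk[i, 0] + 1
                    if sc > dp_score[j, 1] + 1e-12 or (
                        sc > dp_score[j, 1] - 1e-12 and nb < dp_nblk[j, 1]
                    ):
                        dp_score[j, 1] = sc
                        dp_nblk[j, 1] = nb
                        back[j, 1] = i

    flags: list[str] = []
    if dp_score[m, 0] == NEG:
        # no admissible alternating path: fall back to one base block
        mu_c = _trimmed_mean(y)
        total = log_pi[0] + inner_block_loglik(y, None, mu_c, None, inner_eff) + (n - 1) * log_t[0, 0]
        bounds = [(0, n, "B")]
        flags.append("fallback_single_block")
    else:
        total = float(dp_score[m, 0])
        bounds = []
        j, lab = m, 0
        while j > 0:
            i = back[j, lab]
            bounds.append((int(cand[i]), int(cand[j]), "B" if lab == 0 else "T"))
            j, lab = i, 1 - lab
        bounds.reverse()

    blocks: list[Block] = []
    for a, b, label in bounds:
        seg_samples = y[a:b]
        keep = None
        if label == "B":
            mu_curr = _trimmed_mean(seg_samples)
            mu_prev = _trimmed_mean(y[max(0, a - ctx):a]) if a > 0 else None
            mu_next = _trimmed_mean(y[b:b + ctx]) if b < n else None
            post = inner_posteriors(seg_samples, mu_prev, mu_curr, mu_next, inner_eff)
            # block statistics describe the residing k-mer's own level, so
            # samples attributed to jiggling excursions or noise are masked
            keep = post[:, STATE_CURR] >= 0.5
            if not keep.any():
                keep = post[:, STATE_NOISE] <= 0.5
            if not keep.any():
                keep = np.ones(seg_samples.size, dtype=bool)
            vals = seg_samples[keep]
        else:
            vals = seg_samples
        blocks.append(
            Block(a, b, label, float(np.mean(vals)), float(np.std(vals)), keep=keep)
        )
    return Segmentation(read_id, blocks, total, flags=flags)


def config_loglik(
    signal: np.ndarray,
    bounds: list[tuple[int, int, str]],
    outer: OuterHMMParams | None = None,
    inner: InnerHMMParams | None = None,
    trans: TransitionModelParams | None = None,
) -> float:
    """Objective value of an arbitrary alternating block configuration.

    Scores ``bounds`` (a tiling list of (start, end, label)) with exactly
    the objective :func:`segment` maximizes, which makes the DP's
    lattice-optimality directly checkable against any reference
    configuration.  Inadmissible configurations score -inf.
    """
    outer = outer or OuterHMMParams()
    inner = inner or InnerHMMParams()
    trans = trans or TransitionModelParams()
    y = np.ascontiguousarray(signal, dtype=float)
    n = y.size
    if not bounds or bounds[0][0] != 0 or bounds[-1][1] != n:
        raise ValidationError("configuration must tile the signal")
    lo, hi = _noise_bounds(inner, y)
    inner_eff = InnerHMMParams(
        transition=inner.transition,
        initial=inner.initial,
        sigma_inner=_sigma_inner(inner, y),
        noise_bounds=(lo, hi),
    )
    log_t = np.log(outer.t_outer)
    log_pi = np.log(outer.pi_outer)
    ctx = 12
    total = 0.0
    prev_label = None
    for a, b, label in bounds:
        length = b - a
        code = 0 if label == "B" else 1
        if prev_label is None:
            if label != "B":
                return -np.inf
            total += log_pi[code]
        else:
            if label == prev_label:
                return -np.inf
            total += log_t[0 if prev_label == "B" else 1, code]
        total += (length - 1) * log_t[code, code]
        if label == "B":
            if length < outer.min_base_len:
                return -np.inf
            mu_curr = _trimmed_mean(y[a:b])
            mu_prev = _trimmed_mean(y[max(0, a - ctx):a]) if a > 0 else None
            mu_next = _trimmed_mean(y[b:b + ctx]) if b < n else None
            total += inner_block_loglik(y[a:b], mu_prev, mu_curr, mu_next, inner_eff)
        else:
            if not (outer.min_trans_len <= length <= outer.max_trans_len):
                return -np.inf
            total += transition_block_loglik(y[a:b], trans)
        prev_label = label
    if prev_label != "B":
        return -np.inf
    return float(total)
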