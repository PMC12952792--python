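"""m6A calling with a two-component Gaussian mixture per k-mer.

Event means pooled per k-mer across reads and sites are modelled as a
mixture of an unmodified component, whose mean is pinned to the pore-model
baseline mu_un at every M-step, and a modified component whose mean, std
and weight are free.  The fitted parameters update the k-mer table; k-mers
whose two components separate by more than a minimum distance (and carry
non-negligible weight) become callable.  A read-level call compares the
event mean's density under the two components; a site-level call is the
fraction of covering reads called modified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from squigseg.errors import InsufficientCoverageError, ValidationError
from squigseg.kmer_table import KmerParams, KmerTable

_LOG_2PI = math.log(2.0 * math.pi)

SIGMA_FLOOR = 0.05  # pA; EM collapse guard
SIGMA_MOD_BOUNDS = (0.5, 10.0)  # pA; clamp for the modified component
MIN_MOD_WEIGHT = 0.05


@dataclass
class GmmFit:
    """Result of a fixed-mean two-component EM fit.

    Component 1 is the unmodified state (mean pinned to ``mu1``);
    component 2 is the candidate modified state.
    """

    mu1: float
    sigma1: float
    w1: float
    mu2: float
    sigma2: float
    w2: float
    n_points: int
    n_iter: int
    converged: bool
    loglik: float
    flags: tuple[str, ...] = ()


@dataclass
class SiteCall:
    reference_id: str
    position: int
    kmer: str
    coverage: int
    mod_rate: float


@dataclass
class ReadCall:
    read_id: str
    reference_id: str
    position: int
    prob_mod: float
    state: str  # 'modified' | 'unmodified'


def _norm_logpdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * _LOG_2PI - math.log(sigma) - (x - mu) ** 2 / (2.0 * sigma * sigma)


def fit_gmm_fixed_mean(
    values: np.ndarray,
    mu_fixed: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    min_points: int = 50,
    n_restarts: int = 3,
) -> GmmFit:
    """EM for a two-component Gaussian mixture with component-1 mean pinned.

    Initialization: component 1 at (mu_fixed, sample std); component 2 at
    the mean of the points beyond one sample-std of ``mu_fixed`` on the
    heavier side, weights (0.7, 0.3).  ``n_restarts`` seeded jitters of the
    component-2 start are run and the best log likelihood kept, so the fit
    is deterministic given ``seed``.  Stds are clamped at 0.05 pA with a
    'sigma_clamped' flag rather than being allowed to collapse.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < min_points:
        raise InsufficientCoverageError(
            f"need >= {min_points} points to fit a mixture, got {x.size}"
        )
    sd = float(np.std(x))
    if sd == 0.0:
        sd = SIGMA_FLOOR
    hi = x[x > mu_fixed + sd]
    lo = x[x < mu_fixed - sd]
    heavier = hi if hi.size >= lo.size else lo
    mu2_init = float(np.mean(heavier)) if heavier.size else mu_fixed + sd
    rng = np.random.default_rng(seed)
    jitters = [0.0] + list(rng.normal(0.0, 0.5 * sd, max(0, n_restarts - 1)))

    best: GmmFit | None = None
    for jit in jitters:
        fit = _em(x, mu_fixed, mu2_init + jit, sd, tol, max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def _em(
    x: np.ndarray,
    mu_fixed: float,
    mu2: float,
    sd: float,
    tol: float,
    max_iter: int,
) -> GmmFit:
    s1 = s2 = max(sd, SIGMA_FLOOR)
    w1, w2 = 0.7, 0.3
    prev_ll = -np.inf
    flags: list[str] = []
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        l1 = math.log(w1) + _norm_logpdf(x, mu_fixed, s1)
        l2 = math.log(w2) + _norm_logpdf(x, mu2, s2)
        m = np.maximum(l1, l2)
        ll = float(np.sum(m + np.log(np.exp(l1 - m) + np.exp(l2 - m))))
        r2 = expit(l2 - l1)
        r1 = 1.0 - r2
        n1, n2 = float(r1.sum()), float(r2.sum())
        w1, w2 = n1 / x.size, n2 / x.size
        # M-step: component-1 mean stays pinned at mu_fixed
        s1 = math.sqrt(max(float(np.sum(r1 * (x - mu_fixed) ** 2)) / max(n1, 1e-12), 0.0))
        if n2 > 1e-12:
            mu2 = float(np.sum(r2 * x) / n2)
            s2 = math.sqrt(max(float(np.sum(r2 * (x - mu2) ** 2)) / n2, 0.0))
        if s1 < SIGMA_FLOOR:
            s1 = SIGMA_FLOOR
            flags.append("sigma_clamped")
        if s2 < SIGMA_FLOOR:
            s2 = SIGMA_FLOOR
            flags.append("sigma_clamped")
        if ll - prev_ll < tol and n_iter > 1:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return GmmFit(
        mu1=mu_fixed,
        sigma1=s1,
        w1=w1,
        mu2=mu2,
        sigma2=s2,
        w2=w2,
        n_points=int(x.size),
        n_iter=n_iter,
        converged=converged,
        loglik=prev_ll,
        flags=tuple(sorted(set(flags))),
    )


def classify_read(
    event_mean: float,
    kmer_params: KmerParams,
    read_id: str = "read",
    reference_id: str = "ref",
    position: int = -1,
) -> ReadCall:
    """Per-read modification call for one event mean.

    The hard state compares the unweighted component densities (the larger
    density wins); ``prob_mod`` is the weight-aware posterior
    w_mod*phi_mod / (w_un*phi_un + w_mod*phi_mod), reported alongside.
    """
    p = kmer_params
    if not p.mod_enabled:
        raise ValidationError(f"k-mer {p.kmer} has no modified state; not callable")
    lu = _norm_logpdf(np.array(event_mean), p.mu_un, p.sigma_un)
    lm = _norm_logpdf(np.array(event_mean), p.mu_mod, p.sigma_mod)
    state = "modified" if lm > lu else "unmodified"
    a = math.log(max(p.omega_un, 1e-300)) + float(lu)
    b = math.log(max(p.omega_mod, 1e-300)) + float(lm)
    mx = max(a, b)
    prob_mod = math.exp(b - mx) / (math.exp(a - mx) + math.exp(b - mx))
    return ReadCall(read_id, reference_id, position, prob_mod, state)


def site_mod_rate(
    read_calls: list[ReadCall],
    reference_id: str,
    position: int,
    kmer: str,
    min_site_coverage: int = 20,
) -> SiteCall:
    """Site-level modification rate: fraction of covering reads called modified."""
    coverage = len(read_calls)
    if coverage < min_site_coverage:
        raise InsufficientCoverageError(
            f"site {reference_id}:{position} coverage {coverage} < {min_site_coverage}"
        )
    n_mod = sum(1 for c in read_calls if c.state == "modified")
    return SiteCall(reference_id, position, kmer, coverage, n_mod / coverage)


def reestimate_table(
    eventalign: pd.DataFrame,
    table: KmerTable,
    min_coverage: int = 1500,
    min_sep: float = 5.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[KmerTable, pd.DataFrame]:
    """Refit the k-mer table from pooled event means.

    For every k-mer whose pooled coverage reaches ``min_coverage``, a
    fixed-mean GMM is fit with mu_fixed = the current unmodified mean.
    The modified state is enabled only when the component means separate by
    more than ``min_sep`` pA and the modified weight is at least 5%; the
    modified std is clamped into [0.5, 10] pA.  K-mers failing the gates
    keep their parameters and stay unmodified-only.  Returns the new table
    and a per-k-mer significance report.
    """
    new = KmerTable(k=table.k, entries=dict(table.entries))
    rows = []
    grouped = eventalign.groupby("model_kmer")["event_level_mean"]
    for kmer, means in grouped:
        if kmer not in table:
            continue
        p = table.lookup(kmer)
        n = len(means)
        if n < min_coverage:
            rows.append({"kmer": kmer, "coverage": n, "fitted": False, "mod_enabled": False,
                         "sep": np.nan, "w2": np.nan})
            continue
        fit = fit_gmm_fixed_mean(
            means.to_numpy(), p.mu_un, tol=tol, max_iter=max_iter, seed=seed,
            min_points=min(50, min_coverage),
        )
        sep = abs(fit.mu2 - fit.mu1)
        enabled = sep > min_sep and fit.w2 >= MIN_MOD_WEIGHT
        if enabled:
            sigma_mod = float(np.clip(fit.sigma2, *SIGMA_MOD_BOUNDS))
            new.entries[kmer] = replace(
                p,
                sigma_un=max(fit.sigma1, SIGMA_FLOOR),
                mu_mod=fit.mu2,
                sigma_mod=sigma_mod,
                omega_un=fit.w1 / (fit.w1 + fit.w2),
                omega_mod=fit.w2 / (fit.w1 + fit.w2),
                mod_enabled=True,
            )
        else:
            new.entries[kmer] = replace(
                p,
                sigma_un=max(fit.sigma1, SIGMA_FLOOR) if fit.w1 > 0.5 else p.sigma_un,
                mu_mod=None,
                sigma_mod=None,
                omega_un=1.0,
                omega_mod=0.0,
                mod_enabled=False,
            )
        rows.append({"kmer": kmer, "coverage": n, "fitted": True, "mod_enabled": enabled,
                     "sep": sep, "w2": fit.w2})
    report = pd.DataFrame(rows, columns=["kmer", "coverage", "fitted", "mod_enabled", "sep", "w2"])
    return new, report


def mean_table_change(old: KmerTable, new: KmerTable) -> float:
    """Mean absolute change of component means across k-mers.

    Both components contribute where defined in both tables; a component
    appearing or disappearing contributes nothing (the stop rule tracks
    the drift of comparable means).
    """
    deltas: list[float] = []
    for kmer, a in old.entries.items():
        if kmer not in new.entries:
            continue
        b = new.entries[kmer]
        deltas.append(abs(a.mu_un - b.mu_un))
        if a.mod_enabled and b.mod_enabled:
            deltas.append(abs(a.mu_mod - b.mu_mod))
    return float(np.mean(deltas)) if deltas else 0.0


def iterate_workflow(
    reads: list,
    references: dict[str, str],
    table0: KmerTable,
    max_rounds: int = 5,
    change_tol: float = 5e-3,
    min_coverage: int = 1500,
    min_sep: float = 5.0,
    seed: int = 0,
) -> tuple[KmerTable, pd.DataFrame]:
    """Iterate align -> assemble events -> re-estimate until the table stabilizes.

    ``reads`` are (read_id, reference_id, transcript signal, Segmentation)
    tuples of standardized, segmented reads.  Stops when the mean absolute
    change of component means drops below ``change_tol`` pA (both
    components where defined), or after ``max_rounds`` rounds.  The
    returned diagnostics frame has one row per round with the change
    metric and a converged flag.
    """
    from squigseg.align import RefKmerSeq, align_full, assemble_events, events_to_frame

    table = table0
    diag_rows = []
    for rnd in range(1, max_rounds + 1):
        all_events = []
        for read_id, ref_id, signal, seg in reads:
            kmers = RefKmerSeq.from_sequence(ref_id, references[ref_id], table.k)
            means = np.array([b.mean for b in seg.base_blocks])
            aln = align_full(means, kmers, table)
            all_events.extend(
                assemble_events(aln, seg, signal, kmers, read_id=read_id)
            )
        frame = events_to_frame(all_events)
        new_table, _ = reestimate_table(
            frame, table, min_coverage=min_coverage, min_sep=min_sep, seed=seed
        )
        change = mean_table_change(table, new_table)
        table = new_table
        converged = change < change_tol
        diag_rows.append({"round": rnd, "mean_abs_change_pA": change, "converged": converged})
        if converged:
            break
    return table, pd.DataFrame(diag_rows)
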