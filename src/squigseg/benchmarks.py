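"""Desk-scale benchmark experiments on simulated data.

Each function sets up a small, fully specified simulation study, runs the
pipeline and returns summary numbers.  They are used by the test suite and
by ``scripts/acceptance.py``; the study conditions (read counts, rates,
separations) are part of the package's documented evaluation protocol.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np

from squigseg.hhmm import segment
from squigseg.kmer_table import KmerTable, with_modification
from squigseg.metrics import equal_width_baseline, segment_metrics
from squigseg.modcall import classify_read, iterate_workflow, site_mod_rate
from squigseg.align import RefKmerSeq
from squigseg.pipeline import run_sim_pipeline, sim_to_record, standardize_read
from squigseg.simulate import (
    SimConfig,
    drach_sites,
    simulate_dataset,
    synthetic_table,
)


def modification_state_combinations(k: int = 5) -> int:
    """Count binary modification-state combinations of a k-mer by enumeration."""
    return len(set(itertools.product((0, 1), repeat=k)))


def random_references(n_refs: int, length: int, seed: int) -> dict[str, str]:
    rng = np.random.default_rng(seed)
    return {
        f"ref{i}": "".join(rng.choice(list("ACGT"), length)) for i in range(n_refs)
    }


def single_drach_reference(seed: int = 3, length: int = 25) -> str:
    """A reference containing exactly one DRACH site (GGACT at 10..15)."""
    rng = np.random.default_rng(seed)
    while True:
        s = "".join(rng.choice(list("GCT"), length))
        ref = s[:10] + "GGACT" + s[15:]
        if drach_sites(ref) == [12]:
            return ref


def boundary_recovery(
    n_reads: int = 50,
    seed: int = 0,
    table_seed: int = 7,
    n_refs: int = 5,
    ref_length: int = 30,
    tolerance: int = 5,
    table: KmerTable | None = None,
) -> dict:
    """Fraction of true block boundaries recovered within ``tolerance`` samples."""
    table = table or synthetic_table(seed=table_seed)
    refs = random_references(n_refs, ref_length, seed)
    cfg = SimConfig(table=table, seed=seed)
    reads, _ = simulate_dataset(refs, n_reads, cfg)
    hits = total = 0
    for read in reads:
        rec = standardize_read(sim_to_record(read), table)
        seg = segment(rec.transcript_signal, read_id=read.read_id)
        pred = seg.boundaries()
        truth = read.boundaries()
        hits += sum(1 for t in truth if any(abs(t - p) <= tolerance for p in pred))
        total += len(truth)
    return {"recovery": hits / total, "n_boundaries": total, "n_reads": n_reads}


def gmm_recovery(
    n_seeds: int = 20,
    n_per_component: int = 1000,
    mu_un: float = 100.0,
    delta: float = 8.0,
    sigma: float = 2.0,
    seed: int = 0,
) -> dict:
    """Parameter recovery of the fixed-mean GMM on synthetic mixtures."""
    from squigseg.modcall import fit_gmm_fixed_mean

    mu_errs, w_errs, spurious = [], [], 0
    for s in range(n_seeds):
        rng = np.random.default_rng((seed, s))
        x = np.concatenate(
            [
                rng.normal(mu_un, sigma, n_per_component),
                rng.normal(mu_un + delta, sigma, n_per_component),
            ]
        )
        fit = fit_gmm_fixed_mean(x, mu_un, seed=s)
        mu_errs.append(abs(fit.mu2 - (mu_un + delta)))
        w_errs.append(max(abs(fit.w1 - 0.5), abs(fit.w2 - 0.5)))
        # single-component control: no well-separated spurious second peak
        x0 = rng.normal(mu_un, sigma, 2 * n_per_component)
        fit0 = fit_gmm_fixed_mean(x0, mu_un, seed=s)
        if abs(fit0.mu2 - mu_un) >= 1.0 and fit0.w2 >= 0.1:
            spurious += 1
    return {
        "max_mu_mod_error_pA": float(np.max(mu_errs)),
        "mean_mu_mod_error_pA": float(np.mean(mu_errs)),
        "max_weight_error": float(np.max(w_errs)),
        "n_spurious_components": spurious,
        "n_seeds": n_seeds,
    }


def modcall_benchmark(
    coverage: int = 200,
    mod_rate: float = 0.3,
    delta: float = 8.0,
    seed: int = 0,
    table_seed: int = 7,
) -> dict:
    """End-to-end single-site modification calling on simulation."""
    base = synthetic_table(seed=table_seed)
    table = with_modification(base, delta=delta, omega_mod=mod_rate)
    ref = single_drach_reference()
    refs = {"tx1": ref}
    site = drach_sites(ref)[0]
    kpos = site - 2  # k-mer whose centre is the modifiable A
    cfg = SimConfig(table=table, seed=seed, mod_rate=mod_rate)
    reads, _ = simulate_dataset(refs, coverage, cfg)
    _, events = run_sim_pipeline(reads, refs, table)

    truth = {r.read_id: r.truth_mods[site] for r in reads}
    calls = []
    correct = total = 0
    for e in events:
        if e.position != kpos:
            continue
        call = classify_read(
            e.event_mean, table.lookup(e.model_kmer), read_id=e.read_id,
            reference_id=e.reference_id, position=e.position,
        )
        calls.append(call)
        want = "modified" if truth[e.read_id] else "unmodified"
        correct += call.state == want
        total += 1
    site_call = site_mod_rate(calls, "tx1", kpos, ref[kpos:kpos + 5])
    true_rate = float(np.mean([truth[c.read_id] for c in calls]))
    return {
        "read_accuracy": correct / total,
        "site_mod_rate": site_call.mod_rate,
        "true_site_rate": true_rate,
        "site_rate_error": abs(site_call.mod_rate - true_rate),
        "site_coverage": site_call.coverage,
    }


def reestimation_benchmark(
    n_reads: int = 120,
    mod_rate: float = 0.5,
    delta: float = 8.0,
    perturb: float = 2.0,
    seed: int = 0,
    table_seed: int = 7,
    max_rounds: int = 5,
) -> dict:
    """Recover perturbed modified-state means by iterated re-estimation."""
    base = synthetic_table(seed=table_seed)
    table = with_modification(base, delta=delta, omega_mod=mod_rate)
    ref = single_drach_reference()
    refs = {"tx1": ref}
    cfg = SimConfig(table=table, seed=seed, mod_rate=mod_rate)
    reads, _ = simulate_dataset(refs, n_reads, cfg)
    processed, _ = run_sim_pipeline(reads, refs, table)

    start = with_modification(base, delta=delta, omega_mod=mod_rate)
    for kmer, p in list(start.entries.items()):
        if p.mod_enabled:
            start.entries[kmer] = replace(p, mu_mod=p.mu_mod + perturb)

    final, diag = iterate_workflow(
        processed, refs, start, max_rounds=max_rounds,
        min_coverage=max(50, int(0.6 * n_reads)), min_sep=5.0, seed=seed,
    )
    target = ref[10:15]  # the single DRACH k-mer
    err = abs(final.lookup(target).mu_mod - table.lookup(target).mu_mod)
    return {
        "rounds": int(diag["round"].iloc[-1]),
        "converged": bool(diag["converged"].iloc[-1]),
        "final_change_pA": float(diag["mean_abs_change_pA"].iloc[-1]),
        "mu_mod_recovery_error_pA": float(err),
    }


def metrics_direction(
    n_reads: int = 12,
    seed: int = 0,
    table_seed: int = 7,
    ref_length: int = 30,
) -> dict:
    """Paired avg-std / avg-log-p comparison against the equal-width baseline."""
    table = synthetic_table(seed=table_seed)
    refs = random_references(2, ref_length, seed)
    cfg = SimConfig(table=table, seed=seed)
    reads, _ = simulate_dataset(refs, n_reads, cfg)
    pipeline_events = []
    baseline_events = []
    for read in reads:
        rec = standardize_read(sim_to_record(read), table)
        from squigseg.pipeline import process_read

        _, events = process_read(rec, read.reference_id, refs[read.reference_id], table)
        pipeline_events.extend(events)
        seq = RefKmerSeq.from_sequence(
            read.reference_id, refs[read.reference_id], table.k
        )
        baseline_events.extend(
            equal_width_baseline(rec.transcript_signal, seq, read_id=read.read_id)
        )
    rep_p = segment_metrics(pipeline_events, table, trim=0)
    rep_b = segment_metrics(baseline_events, table, trim=3)
    return {
        "pipeline_avg_std": rep_p.avg_std,
        "baseline_avg_std": rep_b.avg_std,
        "pipeline_avg_logp": rep_p.avg_logp,
        "baseline_avg_logp": rep_b.avg_logp,
        "n_pipeline_events": rep_p.n_events,
        "n_baseline_events": rep_b.n_events,
    }
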