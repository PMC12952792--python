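import math

import numpy as np
import pytest

from squigseg.align import (
    RefKmerSeq,
    align_full,
    align_partial,
    assemble_events,
    events_to_frame,
    frame_to_events,
    indel_score,
    m6anet_features,
    pooled_mean_std,
    read_eventalign,
    score,
    write_eventalign,
)
from squigseg.errors import ValidationError
from squigseg.hhmm import Block, Segmentation
from squigseg.kmer_table import KmerParams, KmerTable
from squigseg.pipeline import run_sim_pipeline
from squigseg.simulate import SimConfig, simulate_dataset
from tests.oracles import align_full_bruteforce, align_partial_bruteforce, norm_logpdf


def separated_table(levels, sigma=1.0):
    """k=1 style table on 5-mer keys with prescribed levels, for DP tests."""
    bases = "ACGT"
    entries = {}
    kmers = []
    for i, lv in enumerate(levels):
        kmer = f"{bases[i % 4]}{bases[(i // 4) % 4]}AAA"  # unique for i < 16
        kmers.append(kmer)
        entries[kmer] = KmerParams(kmer=kmer, mu_un=float(lv), sigma_un=sigma)
    table = KmerTable(k=5, entries=entries)
    seq = RefKmerSeq("ref", kmers, list(range(len(kmers) - 1, -1, -1)))
    return table, seq


class TestScore:
    def test_unmodified_mode_closed_form(self, tiny_table):
        got = score(100.0, "AAAAA", tiny_table)
        assert got == pytest.approx(-math.log(math.sqrt(2 * math.pi) * 2.0), abs=1e-12)

    def test_modified_component_dominates_when_separated(self, mod_table):
        p = mod_table.lookup("GGACT")
        got = score(p.mu_mod, "GGACT", mod_table)
        assert got == pytest.approx(norm_logpdf(p.mu_mod, p.mu_mod, p.sigma_mod), abs=1e-9)

    def test_equals_bruteforce_max_of_two_densities(self, mod_table):
        rng = np.random.default_rng(1)
        kmers = mod_table.kmers()
        for _ in range(50):
            kmer = kmers[rng.integers(len(kmers))]
            mu = float(rng.uniform(70, 140))
            p = mod_table.lookup(kmer)
            want = norm_logpdf(mu, p.mu_un, p.sigma_un)
            if p.mod_enabled:
                want = max(want, norm_logpdf(mu, p.mu_mod, p.sigma_mod))
            assert score(mu, kmer, mod_table) == pytest.approx(want, abs=1e-12)

    def test_unknown_kmer_named(self, tiny_table):
        with pytest.raises(ValidationError, match="GGGGG"):
            score(100.0, "GGGGG", tiny_table)


class TestIndelScore:
    def test_constant_and_negative(self, table):
        g = indel_score(table)
        assert g < 0
        assert indel_score(table) == g

    def test_doubling_range_lowers_by_log2(self, table):
        g3 = indel_score(table, pad_sigmas=3.0)
        mus = [p.mu_un for p in table.entries.values()]
        sigmas = [p.sigma_un for p in table.entries.values()]
        span3 = (max(mus) - min(mus)) + 6 * max(sigmas)
        # choose pad so the span doubles, then the log-density drops by log 2
        pad = (2 * span3 - (max(mus) - min(mus))) / (2 * max(sigmas))
        g6 = indel_score(table, pad_sigmas=pad)
        assert g6 == pytest.approx(g3 - math.log(2), abs=1e-9)

    def test_gap_never_beats_perfect_match(self, table):
        g = indel_score(table)
        for kmer in list(table.entries)[::37]:
            assert g < score(table.lookup(kmer).mu_un, kmer, table)


class TestAlignFull:
    def test_one_by_one_single_match(self):
        table, seq = separated_table([100.0])
        res = align_full(np.array([100.3]), RefKmerSeq("ref", seq.kmers[:1], seq.positions[:1]), table)
        assert [s[0] for s in res.path] == ["match"]
        assert res.score == pytest.approx(score(100.3, seq.kmers[0], table), abs=1e-12)

    def test_many_to_one_pattern(self):
        # two means on the first baseline, one on the second: mu1, mu2 -> A1, mu3 -> A2
        table, seq = separated_table([100.0, 115.0])
        res = align_full(np.array([100.2, 99.7, 115.1]), seq, table)
        assert res.kmer_of_mean() == {1: 1, 2: 1, 3: 2}
        kinds = [s[0] for s in res.path]
        assert kinds == ["match", "stay", "match"]

    def test_dp_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            m = int(rng.integers(1, 7))
            n = int(rng.integers(1, 7))
            levels = rng.uniform(80, 130, n)
            table, seq = separated_table(levels)
            means = rng.uniform(80, 130, m)
            res = align_full(means, seq, table)
            want = align_full_bruteforce(
                means, levels, [1.0] * n, indel_score(table)
            )
            assert res.score == pytest.approx(want, abs=1e-9)

    def test_path_monotone_and_consumes_everything(self):
        rng = np.random.default_rng(3)
        levels = rng.uniform(80, 130, 5)
        table, seq = separated_table(levels)
        means = rng.uniform(80, 130, 7)
        res = align_full(means, seq, table)
        consumed_i = [i for k, i, j in res.path if k in ("match", "stay", "ins")]
        consumed_j = [j for k, i, j in res.path if k in ("match", "del")]
        assert consumed_i == list(range(1, 8))
        assert consumed_j == sorted(set(consumed_j))
        assert set(consumed_j) <= set(range(1, 6))

    def test_empty_inputs_rejected(self, table):
        seq = RefKmerSeq.from_sequence("r", "ACGTACG", 5)
        with pytest.raises(ValidationError):
            align_full(np.array([]), seq, table)


class TestAlignPartial:
    def test_prefix_only_consumption(self):
        levels = [100.0, 112.0, 88.0, 124.0, 95.0, 105.0, 80.0, 119.0, 99.0, 90.0]
        table, seq = separated_table(levels)
        means = np.array([100.1, 112.2, 87.6])
        res = align_partial(means, seq, table)
        assert res.kmer_of_mean() == {1: 1, 2: 2, 3: 3}
        assert res.variant == "partial"

    def test_single_mean_goes_to_first_kmer(self):
        levels = [100.0, 90.0]
        table, seq = separated_table(levels)
        res = align_partial(np.array([90.0]), seq, table)
        # all means must align to a prefix, so the sole mean sits on s_1
        assert res.kmer_of_mean() == {1: 1}

    def test_no_indels_in_path(self):
        rng = np.random.default_rng(4)
        levels = rng.uniform(80, 130, 5)
        table, seq = separated_table(levels)
        res = align_partial(rng.uniform(80, 130, 6), seq, table)
        assert {s[0] for s in res.path} <= {"match", "stay"}

    def test_dp_matches_bruteforce_prefix_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            m = int(rng.integers(1, 7))
            n = int(rng.integers(1, 7))
            levels = rng.uniform(80, 130, n)
            table, seq = separated_table(levels)
            means = rng.uniform(80, 130, m)
            res = align_partial(means, seq, table)
            want = align_partial_bruteforce(means, levels, [1.0] * n)
            assert res.score == pytest.approx(want, abs=1e-9)


class TestAssembleEvents:
    def make_seg(self, blocks):
        return Segmentation("r1", blocks, 0.0)

    def test_single_block_identity(self):
        rng = np.random.default_rng(6)
        y = rng.normal(100, 1, 20)
        blocks = [Block(0, 20, "B", float(np.mean(y)), float(np.std(y)))]
        table, seq = separated_table([100.0])
        res = align_full(np.array([blocks[0].mean]), seq, table)
        events = assemble_events(res, self.make_seg(blocks), y, seq)
        assert len(events) == 1
        assert events[0].event_mean == pytest.approx(float(np.mean(y)), abs=1e-9)
        assert events[0].event_std == pytest.approx(float(np.std(y)), abs=1e-9)
        assert events[0].dwell == 20

    def test_pooled_moments_match_concatenation(self):
        rng = np.random.default_rng(7)
        a = rng.normal(100, 1, 10)
        a = (a - a.mean()) / a.std() * 1.0 + 100.0  # exactly (100, 1)
        b = rng.normal(104, 1, 30)
        b = (b - b.mean()) / b.std() * 1.0 + 104.0  # exactly (104, 1)
        mean, std = pooled_mean_std([(10, 100.0, 1.0), (30, 104.0, 1.0)])
        assert mean == pytest.approx(103.0, abs=1e-12)
        concat = np.concatenate([a, b])
        assert std == pytest.approx(float(np.std(concat)), abs=1e-9)

    def test_transition_samples_excluded_and_stays_merged(self):
        rng = np.random.default_rng(8)
        b1 = rng.normal(100, 1, 10)
        ramp = np.full(4, 500.0)  # wild values that must not leak into the event
        b2 = rng.normal(100.5, 1, 12)
        y = np.concatenate([b1, ramp, b2])
        blocks = [
            Block(0, 10, "B", float(np.mean(b1)), float(np.std(b1))),
            Block(10, 14, "T", 500.0, 0.0),
            Block(14, 26, "B", float(np.mean(b2)), float(np.std(b2))),
        ]
        table, seq = separated_table([100.0, 130.0])
        res = align_full(np.array([blocks[0].mean, blocks[2].mean]), seq, table)
        events = assemble_events(res, self.make_seg(blocks), y, seq)
        assert len(events) == 1  # both blocks stay on k-mer 1; k-mer 2 deleted
        merged = np.concatenate([b1, b2])
        assert events[0].event_mean == pytest.approx(float(np.mean(merged)), abs=1e-9)
        assert events[0].event_std == pytest.approx(float(np.std(merged)), abs=1e-9)
        assert events[0].dwell == 22

    def test_event_count_never_exceeds_kmer_count(self, table):
        cfg = SimConfig(table=table, seed=13)
        reads, _ = simulate_dataset({"tx": "ACGTAGGCTTACA"}, 3, cfg)
        _, events = run_sim_pipeline(reads, {"tx": "ACGTAGGCTTACA"}, table)
        n_kmers = len("ACGTAGGCTTACA") - 4
        for rid in {e.read_id for e in events}:
            assert sum(e.read_id == rid for e in events) <= n_kmers

    def test_events_sorted_by_reference_position(self, table):
        cfg = SimConfig(table=table, seed=14)
        reads, _ = simulate_dataset({"tx": "ACGTAGGCTTACA"}, 1, cfg)
        _, events = run_sim_pipeline(reads, {"tx": "ACGTAGGCTTACA"}, table)
        positions = [e.position for e in events]
        assert positions == sorted(positions)


class TestM6anetFeatures:
    def _events(self, table):
        cfg = SimConfig(table=table, seed=15)
        reads, _ = simulate_dataset({"tx": "ACGTAGGCTTACA"}, 1, cfg)
        _, events = run_sim_pipeline(reads, {"tx": "ACGTAGGCTTACA"}, table)
        return events

    def test_projection_order(self, table):
        events = self._events(table)
        by_pos = {e.position: e for e in events}
        pos = sorted(by_pos)[1]
        if not all(p in by_pos for p in (pos - 1, pos, pos + 1)):
            pytest.skip("flank missing in this draw")
        v = m6anet_features(events, pos)
        want = []
        for p in (pos - 1, pos, pos + 1):
            e = by_pos[p]
            want.extend([e.event_mean, e.event_std, float(e.dwell)])
        np.testing.assert_allclose(v, want)

    def test_missing_flank_unavailable(self, table):
        events = self._events(table)
        first = min(e.position for e in events)
        assert m6anet_features(events, first) is None


class TestEventalignIO:
    def test_round_trip(self, table, tmp_path):
        cfg = SimConfig(table=table, seed=16)
        reads, _ = simulate_dataset({"tx": "ACGTAGGCTTACA"}, 2, cfg)
        _, events = run_sim_pipeline(reads, {"tx": "ACGTAGGCTTACA"}, table)
        p = tmp_path / "ea.tsv"
        write_eventalign(events, p)
        df = read_eventalign(p)
        assert len(df) == len(events)
        back = frame_to_events(df)
        for a, b in zip(events, back):
            assert a.position == b.position and a.model_kmer == b.model_kmer
            assert a.event_mean == pytest.approx(b.event_mean, abs=1e-6)
            assert a.event_std == pytest.approx(b.event_std, abs=1e-6)

    def test_empty_events_header_only(self, tmp_path):
        p = tmp_path / "ea.tsv"
        write_eventalign([], p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("contig\t")

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("contig\tposition\nx\t1\n")
        with pytest.raises(ValidationError):
            read_eventalign(p)
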