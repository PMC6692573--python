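"""TSS clustering unit tests, including an independent exhaustive oracle.

The oracle clusters by top-down memoized search over contiguous
partitions of the sorted positions (interval costs computed directly),
then applies the same merge/prune/designation rules — sharing no code
with the package's bottom-up DP.
"""

from functools import lru_cache

import numpy as np
import pytest

from drafts.read_processing import ProcessedRead
from drafts.tss_calling import (
    TssPileup,
    build_pileup,
    build_pileups,
    call_tss,
    cluster_tss,
    tss_concordance,
)


def oracle_cluster_and_call(
    pile: dict,
    k_seed=16,
    merge=10,
    min_frac=0.01,
    primary_frac=0.70,
    primary_min_count=200,
    secondary_frac=0.10,
):
    items = sorted(pile.items())
    xs = [p for p, _ in items]
    ws = [c for _, c in items]
    total = sum(ws)
    n = len(xs)

    def interval_cost(i, j):  # inclusive
        w = sum(ws[i : j + 1])
        m = sum(ws[t] * xs[t] for t in range(i, j + 1)) / w
        return sum(ws[t] * (xs[t] - m) ** 2 for t in range(i, j + 1))

    @lru_cache(None)
    def best(j, k):
        if k == 1:
            return interval_cost(0, j), ()
        out = None
        for i in range(k - 2, j):
            c, s = best(i, k - 1)
            c2 = c + interval_cost(i + 1, j)
            if out is None or c2 < out[0] - 1e-12:
                out = (c2, s + (i + 1,))
        return out

    k = min(k_seed, n)
    while True:
        _, splits = best(n - 1, k)
        bounds = [0] + list(splits) + [n]
        clus = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            mem, cnt = xs[a:b], ws[a:b]
            top = max(cnt)
            rep = min(m for m, c in zip(mem, cnt) if c == top)
            clus.append((rep, sum(cnt), sum(cnt) / total, tuple(mem)))
        if k > 1:
            reps = [c[0] for c in clus]
            close = any(reps[i + 1] - reps[i] <= merge for i in range(len(reps) - 1))
            small = any(c[2] < min_frac for c in clus)
            if close or small:
                k -= 1
                continue
        primary = None
        for rep, cnt, frac, _ in clus:
            if frac > primary_frac and cnt > primary_min_count:
                primary = rep
                break
        secondaries = sorted(
            rep for rep, _, frac, _ in clus if rep != primary and frac > secondary_frac
        )
        return clus, primary, secondaries


def fuzz_pileup(rng, max_distinct=30):
    ndist = int(rng.integers(1, max_distinct + 1))
    pos = rng.choice(np.arange(-165, 0), size=ndist, replace=False)
    style = int(rng.integers(0, 4))
    if style == 0:
        counts = rng.integers(1, 50, size=ndist)
    elif style == 1:
        counts = rng.geometric(0.05, size=ndist)
    elif style == 2:
        counts = rng.integers(1, 10, size=ndist)
        counts[rng.integers(ndist)] += 500
    else:
        counts = rng.integers(1, 20, size=ndist)
        counts[:2] += 300
    return {int(p): int(c) for p, c in zip(pos, counts)}


class TestBuildPileup:
    def test_exact_histogram(self):
        reads = [ProcessedRead("A", "RNA", "rep1", -45, True)] * 3
        assert build_pileup(reads, "A").positions == {-45: 3}

    def test_empty_and_qc_filtered(self):
        reads = [
            ProcessedRead("A", "RNA", "rep1", None, False),
            ProcessedRead("A", "DNA", "rep1"),
        ]
        assert build_pileup(reads, "A").positions == {}

    def test_matches_simulated_jitter_distribution(self, sim_small):
        piles = build_pileups(sim_small["reads"])
        truth = {c: p for c, p in sim_small["sim"].tss_read_counts.items() if p}
        assert {c: p.positions for c, p in piles.items()} == truth


class TestClusterRules:
    def test_single_position(self):
        (c,) = cluster_tss(TssPileup("x", {-45: 300}))
        assert c.representative == -45
        assert c.read_fraction == 1.0

    def test_adjacent_positions_merge_tie_breaks_upstream(self):
        (c,) = cluster_tss(TssPileup("x", {-45: 150, -44: 150}))
        assert c.representative == -45
        assert c.member_positions == (-45, -44)

    def test_one_percent_boundary_not_pruned(self):
        # 3/300 is exactly 1%; the prune rule is strictly "< 1%"
        clusters = cluster_tss(TssPileup("x", {-60: 297, -20: 3}))
        assert len(clusters) == 2
        assert {c.representative for c in clusters} == {-60, -20}

    def test_below_one_percent_pruned_into_neighbour(self):
        clusters = cluster_tss(TssPileup("x", {-60: 298, -20: 2}))
        assert len(clusters) == 1

    def test_empty_pileup_yields_no_clusters(self):
        assert cluster_tss(TssPileup("x", {})) == []

    def test_determinism(self, rng):
        pile = fuzz_pileup(rng)
        a = cluster_tss(TssPileup("x", dict(pile)))
        b = cluster_tss(TssPileup("x", dict(reversed(sorted(pile.items())))))
        assert a == b


class TestCallRules:
    def test_single_cluster_300_reads_has_primary(self):
        cs = call_tss(cluster_tss(TssPileup("x", {-45: 300})))
        assert cs.primary == -45

    def test_fraction_one_but_200_reads_gives_none(self):
        # the count rule is strict: > 200 reads required
        cs = call_tss(cluster_tss(TssPileup("x", {-45: 200})))
        assert cs.primary is None

    def test_secondary_threshold_is_strict(self):
        clusters = cluster_tss(
            TssPileup("x", {-80: 750, -40: 150, -15: 100})
        )
        cs = call_tss(clusters)
        assert cs.primary == -80
        assert cs.secondaries == [-40]  # 0.10 is not > 0.10

    def test_callset_invariants_on_fuzzed_pileups(self, rng):
        for _ in range(100):
            pile = fuzz_pileup(rng)
            total = sum(pile.values())
            cs = call_tss(cluster_tss(TssPileup("x", pile)))
            reps = sorted(c.representative for c in cs.clusters)
            assert all(b - a > 10 for a, b in zip(reps, reps[1:]))
            if len(cs.clusters) > 1:
                assert all(c.read_fraction >= 0.01 for c in cs.clusters)
            for c in cs.clusters:
                assert c.representative in c.member_positions
                assert c.read_fraction == pytest.approx(c.read_count / total)
            if cs.primary is not None:
                pc = cs.primary_cluster
                assert pc.read_fraction > 0.70 and pc.read_count > 200


class TestOracleEquivalence:
    def test_matches_exhaustive_partition_oracle(self, rng):
        for _ in range(100):
            pile = fuzz_pileup(rng)
            cs = call_tss(cluster_tss(TssPileup("x", dict(pile))))
            _, oprimary, osecondaries = oracle_cluster_and_call(pile)
            assert cs.primary == oprimary
            assert cs.secondaries == osecondaries


class TestConcordance:
    def test_identical_sets(self):
        calls = {"A": call_tss(cluster_tss(TssPileup("A", {-45: 300})), "A")}
        assert tss_concordance(calls, calls) == (1.0, 1)

    def test_two_bp_shift_fails_one_bp_tolerance(self):
        a = {"A": call_tss(cluster_tss(TssPileup("A", {-45: 300})), "A")}
        b = {"A": call_tss(cluster_tss(TssPileup("A", {-47: 300})), "A")}
        assert tss_concordance(a, b, tol_bp=1) == (0.0, 1)

    def test_no_shared_primaries_errors(self):
        a = {"A": call_tss(cluster_tss(TssPileup("A", {-45: 300})), "A")}
        b = {"A": call_tss(cluster_tss(TssPileup("A", {-45: 100})), "A")}
        with pytest.raises(ValueError):
            tss_concordance(a, b)

    def test_replicate_concordance_on_jittered_simulation(self):
        from drafts import synthetic_data as sd
        from drafts.tss_calling import call_all

        lib, truth = sd.generate_library(40, seed=31)
        sd.assign_truth(lib, truth, noise_sd=0.2, seed=32)
        reps = []
        for seed in (33, 34):
            counts = {}
            rng = np.random.default_rng(seed)
            for c in lib:
                tss = truth.true_tss[c.construct_id]
                pos = np.rint(rng.normal(tss, 0.5, size=400)).astype(int)
                pos = np.clip(pos, -c.length, -1)
                vals, cnts = np.unique(pos, return_counts=True)
                counts[c.construct_id] = TssPileup(
                    c.construct_id, dict(zip(vals.tolist(), cnts.tolist()))
                )
            reps.append(call_all(counts))
        frac, n = tss_concordance(reps[0], reps[1], tol_bp=1)
        assert n >= 30
        assert frac >= 0.90
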