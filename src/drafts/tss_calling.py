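"""Transcription start site calling from RNA 5'-end pileups.

Each QC-passing RNA read contributes one "TSS call": the position (bp
upstream of the ATG, negative) where its 5' end maps on the construct.
Per construct, calls are clustered in one dimension and the clusters
are reduced until they are well separated and well supported:

* start from k = min(16, number of distinct positions) clusters;
* decrement k and re-cluster whenever two cluster representatives lie
  within 10 bp of each other or any cluster holds < 1% of all reads;
* the primary TSS is the representative of the single cluster holding
  > 70% of calls with > 200 reads (else no primary); secondary TSSs
  are representatives of the other clusters holding > 10% of calls.

The per-k clustering is exact: a dynamic program over the sorted
distinct positions minimizes the count-weighted within-cluster sum of
squares (clusters in 1D are contiguous), so the whole procedure is
deterministic and free of initialization effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from drafts.read_processing import ProcessedRead

K_SEED_DEFAULT = 16
MERGE_DIST_BP_DEFAULT = 10
MIN_FRAC_DEFAULT = 0.01
PRIMARY_FRAC_DEFAULT = 0.70
PRIMARY_MIN_COUNT_DEFAULT = 200
SECONDARY_FRAC_DEFAULT = 0.10


@dataclass
class TssPileup:
    construct_id: str
    positions: Dict[int, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.positions.values())

    def add(self, pos: int, count: int = 1) -> None:
        self.positions[pos] = self.positions.get(pos, 0) + count


@dataclass(frozen=True)
class TssCluster:
    member_positions: Tuple[int, ...]
    representative: int
    read_count: int
    read_fraction: float


@dataclass
class TssCallSet:
    construct_id: str
    clusters: List[TssCluster]
    primary: Optional[int]
    secondaries: List[int]
    total_reads: int = 0

    @property
    def primary_cluster(self) -> Optional[TssCluster]:
        for c in self.clusters:
            if c.representative == self.primary:
                return c
        return None


def build_pileup(reads: Iterable[ProcessedRead], construct_id: str) -> TssPileup:
    """Histogram of RNA 5'-end positions for one construct (QC-passing only)."""
    p = TssPileup(construct_id)
    for r in reads:
        if (
            r.construct_id == construct_id
            and r.kind == "RNA"
            and r.pass_qc
            and r.five_prime_pos is not None
        ):
            p.add(r.five_prime_pos)
    return p


def build_pileups(reads: Iterable[ProcessedRead]) -> Dict[str, TssPileup]:
    """One pass over a read stream → pileup per construct encountered."""
    out: Dict[str, TssPileup] = {}
    for r in reads:
        if r.kind == "RNA" and r.pass_qc and r.five_prime_pos is not None:
            out.setdefault(
                r.construct_id, TssPileup(r.construct_id)
            ).add(r.five_prime_pos)
    return out


def _optimal_1d_partition(
    xs: np.ndarray, ws: np.ndarray, k: int
) -> List[Tuple[int, int]]:
    """Exact weighted k-clustering of sorted 1D points.

    Minimizes sum_j w_j (x_j - mean of its cluster)^2; optimal clusters
    are contiguous runs of the sorted positions, so a DP over interval
    costs suffices.  Returns [start, end) index pairs.
    """
    n = len(xs)
    cw = np.concatenate(([0.0], np.cumsum(ws)))
    cwx = np.concatenate(([0.0], np.cumsum(ws * xs)))
    cwx2 = np.concatenate(([0.0], np.cumsum(ws * xs * xs)))

    def cost(i: int, j: int) -> float:  # interval [i, j)
        w = cw[j] - cw[i]
        s = cwx[j] - cwx[i]
        return (cwx2[j] - cwx2[i]) - s * s / w

    INF = float("inf")
    dp = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            best, arg = INF, kk - 1
            for i in range(kk - 1, j):
                v = dp[kk - 1, i] + cost(i, j)
                if v < best - 1e-12:  # ties keep the earliest split
                    best, arg = v, i
            dp[kk, j] = best
            back[kk, j] = arg
    bounds = []
    j = n
    for kk in range(k, 0, -1):
        i = back[kk, j]
        bounds.append((i, j))
        j = i
    return bounds[::-1]


def _make_cluster(xs: np.ndarray, ws: np.ndarray, i: int, j: int, total: int) -> TssCluster:
    members = xs[i:j]
    counts = ws[i:j]
    # representative = modal position; ties break to the most upstream
    # (most negative), matching single-nucleotide initiation biology
    best = int(members[np.argmax(counts)])
    cnt = int(counts.sum())
    return TssCluster(
        member_positions=tuple(int(m) for m in members),
        representative=best,
        read_count=cnt,
        read_fraction=cnt / total,
    )


def cluster_tss(
    pileup: TssPileup,
    k_seed: int = K_SEED_DEFAULT,
    merge_dist_bp: int = MERGE_DIST_BP_DEFAULT,
    min_frac: float = MIN_FRAC_DEFAULT,
) -> List[TssCluster]:
    """Cluster a 5'-end pileup; see module docstring for the rules.

    Two clusters are "within" ``merge_dist_bp`` when their
    representatives are <= that many bp apart, so final representatives
    are strictly farther than ``merge_dist_bp`` from each other; a
    cluster is pruned when its read fraction is strictly below
    ``min_frac``.  Both violations decrement k and re-cluster; k = 1 is
    always accepted.
    """
    if not pileup.positions:
        return []
    items = sorted(pileup.positions.items())
    xs = np.array([p for p, _ in items], dtype=float)
    ws = np.array([c for _, c in items], dtype=float)
    total = int(ws.sum())
    k = min(k_seed, len(xs))
    while True:
        bounds = _optimal_1d_partition(xs, ws, k)
        clusters = [_make_cluster(xs, ws, i, j, total) for i, j in bounds]
        if k == 1:
            return clusters
        reps = [c.representative for c in clusters]
        too_close = any(
            reps[i + 1] - reps[i] <= merge_dist_bp for i in range(len(reps) - 1)
        )
        too_small = any(c.read_fraction < min_frac for c in clusters)
        if not too_close and not too_small:
            return clusters
        k -= 1


def call_tss(
    clusters: List[TssCluster],
    construct_id: str = "",
    primary_frac: float = PRIMARY_FRAC_DEFAULT,
    primary_min_count: int = PRIMARY_MIN_COUNT_DEFAULT,
    secondary_frac: float = SECONDARY_FRAC_DEFAULT,
) -> TssCallSet:
    """Designate primary/secondary TSSs from final clusters.

    Primary: the unique cluster with read fraction > ``primary_frac``
    AND read count > ``primary_min_count`` (both strict); NONE
    otherwise.  Secondaries: representatives of the remaining clusters
    with fraction > ``secondary_frac`` (strict), upstream first.
    """
    total = sum(c.read_count for c in clusters)
    primary = None
    for c in clusters:
        if c.read_fraction > primary_frac and c.read_count > primary_min_count:
            primary = c.representative
            break  # fractions > 0.5 are unique by pigeonhole
    secondaries = sorted(
        c.representative
        for c in clusters
        if c.representative != primary and c.read_fraction > secondary_frac
    )
    return TssCallSet(
        construct_id=construct_id,
        clusters=clusters,
        primary=primary,
        secondaries=secondaries,
        total_reads=total,
    )


def call_all(
    pileups: Dict[str, TssPileup],
    k_seed: int = K_SEED_DEFAULT,
    merge_dist_bp: int = MERGE_DIST_BP_DEFAULT,
    min_frac: float = MIN_FRAC_DEFAULT,
    primary_frac: float = PRIMARY_FRAC_DEFAULT,
    primary_min_count: int = PRIMARY_MIN_COUNT_DEFAULT,
    secondary_frac: float = SECONDARY_FRAC_DEFAULT,
) -> Dict[str, TssCallSet]:
    out = {}
    for cid in sorted(pileups):
        clusters = cluster_tss(pileups[cid], k_seed, merge_dist_bp, min_frac)
        out[cid] = call_tss(
            clusters, cid, primary_frac, primary_min_count, secondary_frac
        )
    return out


def tss_concordance(
    a: Dict[str, TssCallSet], b: Dict[str, TssCallSet], tol_bp: int = 1
) -> Tuple[float, int]:
    """Fraction of constructs (with a primary in both) agreeing within tol_bp."""
    shared = [
        cid
        for cid in a
        if cid in b and a[cid].primary is not None and b[cid].primary is not None
    ]
    if not shared:
        raise ValueError("no constructs with primary TSS calls in both sets")
    hits = sum(abs(a[c].primary - b[c].primary) <= tol_bp for c in shared)
    return hits / len(shared), len(shared)


def write_tss_tsv(calls: Dict[str, TssCallSet], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["construct_id", "primary_tss", "primary_fraction", "primary_count", "secondaries"]
        )
        for cid in sorted(calls):
            cs = calls[cid]
            pc = cs.primary_cluster
            w.writerow(
                [
                    cid,
                    "" if cs.primary is None else cs.primary,
                    "" if pc is None else f"{pc.read_fraction:.6g}",
                    "" if pc is None else pc.read_count,
                    ",".join(str(s) for s in cs.secondaries),
                ]
            )
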