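"""Comparative analytics of activity profiles across species/lysates.

Profiles are compared over "universally active" constructs — those
passing the DNA filter with defined activity in every sample — via
pairwise Pearson correlation, PCA (samples as observations) and
average-linkage hierarchical clustering on correlation distance.
Species-selective promoters (> 10-fold stronger in one sample than any
other, on the raw ratio scale) and restriction-site-driven library
depletion (per-construct binomial test + degenerate 5-mer enrichment)
are called from the same tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from drafts.library_io import Library

SELECTIVE_FOLD_DEFAULT = 10.0
DEPLETION_FC_DEFAULT = 0.5
DEPLETION_ALPHA_DEFAULT = 0.05


def profile_matrix(activities: pd.DataFrame) -> pd.DataFrame:
    """tx_z matrix (constructs x samples) over universally active constructs.

    A construct is included only if it passes the DNA filter and has a
    defined activity in ALL samples of the table.
    """
    samples = list(activities.columns.get_level_values("sample").unique())
    ok = pd.Series(True, index=activities.index)
    for s in samples:
        ok &= activities[(s, "pass_filter")].astype(bool)
        ok &= activities[(s, "tx_z")].notna()
    m = pd.DataFrame(
        {s: activities.loc[ok, (s, "tx_z")] for s in samples}, index=activities.index[ok]
    )
    m.columns.name = "sample"
    return m


def pairwise_correlation(m: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix between sample columns."""
    if m.shape[0] < 3:
        raise ValueError("need >= 3 constructs for correlations")
    sds = m.std(ddof=0)
    const = sds.index[sds == 0].tolist()
    if const:
        raise ValueError(f"constant column(s): {const}")
    return m.corr(method="pearson")


def pca(m: pd.DataFrame, n_components: Optional[int] = None):
    """PCA of samples in construct-activity space.

    Samples are the observations (rows of the transposed matrix);
    constructs are the variables, centered across samples.  Computed by
    SVD; each component's sign is fixed so its largest-magnitude
    loading is positive.  Returns ``(scores, explained_variance_frac)``
    with scores indexed by sample.
    """
    n_samples = m.shape[1]
    max_comp = min(n_samples, m.shape[0])
    if n_components is None:
        n_components = min(n_samples - 1, max_comp) or 1
    if n_components > max_comp:
        raise ValueError(f"n_components {n_components} exceeds min(dims) {max_comp}")
    X = m.T.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U[:, :n_components] * S[:n_components]
    total_var = float((S**2).sum())
    evf = (S[:n_components] ** 2) / total_var if total_var > 0 else S[:n_components] * 0
    scores_df = pd.DataFrame(
        scores,
        index=m.columns,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    return scores_df, evf


def hierarchical_cluster(m: pd.DataFrame, axis: str = "samples") -> str:
    """Average-linkage tree on correlation distance (1 - r), as newick.

    ``axis='samples'`` clusters the columns, ``axis='constructs'`` the
    rows.  Leaf order / tie-breaks follow label order, which scipy's
    linkage on the condensed distance matrix makes deterministic.
    """
    if axis == "samples":
        data = m.T
    elif axis == "constructs":
        data = m
    else:
        raise ValueError("axis must be 'samples' or 'constructs'")
    labels = [str(x) for x in data.index]
    if len(labels) < 2:
        raise ValueError("need >= 2 leaves")
    corr = np.corrcoef(data.to_numpy(dtype=float))
    if np.isnan(corr).any():
        raise ValueError("constant row makes correlation distance undefined")
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(len(labels), k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    return _tree_to_newick(hierarchy.to_tree(Z), labels)


def _tree_to_newick(node, labels: List[str]) -> str:
    def rec(n, parent_dist: float) -> str:
        bl = max(parent_dist - n.dist, 0.0)
        if n.is_leaf():
            return f"{labels[n.id]}:{bl:.6g}"
        return f"({rec(n.left, n.dist)},{rec(n.right, n.dist)}):{bl:.6g}"

    root = f"({rec(node.left, node.dist)},{rec(node.right, node.dist)});"
    return root


def cut_two_clusters(m: pd.DataFrame, axis: str = "constructs") -> pd.Series:
    """Two-group flat clustering (average linkage, correlation distance)."""
    data = m if axis == "constructs" else m.T
    corr = np.corrcoef(data.to_numpy(dtype=float))
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(data.shape[0], k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    return pd.Series(hierarchy.fcluster(Z, 2, criterion="maxclust"), index=data.index)


def species_selective(
    activities: pd.DataFrame, fold: float = SELECTIVE_FOLD_DEFAULT
) -> Dict[str, List[str]]:
    """Constructs with > ``fold``-stronger raw activity in one sample
    than in any other (strict inequality, linear ratio scale).

    Activity that is undefined or filtered in a sample counts as zero
    when it appears in the denominator; constructs inactive everywhere
    are skipped.
    """
    samples = list(activities.columns.get_level_values("sample").unique())
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")
    tx = pd.DataFrame(
        {
            s: activities[(s, "tx_raw")].where(
                activities[(s, "pass_filter")].astype(bool)
            )
            for s in samples
        }
    ).fillna(0.0)
    out: Dict[str, List[str]] = {s: [] for s in samples}
    arr = tx.to_numpy(dtype=float)
    for i, cid in enumerate(tx.index):
        row = arr[i]
        if (row <= 0).all():
            continue
        j = int(np.argmax(row))
        others = np.delete(row, j)
        mx = others.max()
        if (mx == 0 and row[j] > 0) or (mx > 0 and row[j] / mx > fold):
            out[samples[j]].append(cid)
    return out


# ---------------------------------------------------------------------------
# restriction-site depletion


@dataclass
class DepletionReport:
    per_construct: pd.DataFrame  # input_frac, output_frac, log2_fc, p, q, depleted
    enriched_kmers: pd.DataFrame  # kmer, fold_enrichment, p, q
    note: str = ""

    @property
    def depleted_ids(self) -> List[str]:
        return list(self.per_construct.index[self.per_construct["depleted"]])


def _degenerate_kmers_of(seq: str, k: int = 5) -> set:
    """All degenerate k-mers (<= 1 N) matching somewhere in ``seq``."""
    found = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        found.add(w)
        for j in range(k):
            found.add(w[:j] + "N" + w[j + 1 :])
    return found


def detect_depletion(
    dna_in: pd.Series,
    dna_out: pd.Series,
    sequences: Dict[str, str] | Library,
    fc_threshold: float = DEPLETION_FC_DEFAULT,
    alpha: float = DEPLETION_ALPHA_DEFAULT,
    kmer_size: int = 5,
) -> DepletionReport:
    """Flag constructs lost between input and output DNA pools and the
    sequence motifs enriched among them.

    Per construct, the output count is tested against the input
    fraction with an exact binomial test (BH-corrected); "depleted"
    requires q < ``alpha`` AND an output/input fraction ratio below
    ``fc_threshold``.  Degenerate ``kmer_size``-mers (at most one N)
    are then tested for presence/absence enrichment in depleted vs
    retained sequences with a hypergeometric test (BH-corrected),
    ranked by fold-enrichment.
    """
    idx = dna_in.index
    if not idx.equals(dna_out.index):
        raise ValueError("input/output count vectors cover different constructs")
    n_in, n_out = int(dna_in.sum()), int(dna_out.sum())
    if n_in <= 0 or n_out <= 0:
        raise ValueError("zero total counts")
    in_frac = dna_in / n_in
    out_frac = dna_out / n_out
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.log2(out_frac / in_frac)
    pvals = np.ones(len(idx))
    for i, cid in enumerate(idx):
        if dna_in[cid] == 0:
            continue
        pvals[i] = stats.binomtest(
            int(dna_out[cid]), n_out, float(in_frac[cid])
        ).pvalue
    qvals = stats.false_discovery_control(pvals, method="bh")
    ratio = (out_frac / in_frac).replace([np.inf], np.nan)
    depleted = (qvals < alpha) & (ratio < fc_threshold)
    per_construct = pd.DataFrame(
        {
            "input_frac": in_frac,
            "output_frac": out_frac,
            "log2_fc": log2_fc,
            "p": pvals,
            "q": qvals,
            "depleted": depleted,
        },
        index=idx,
    )

    seqs = (
        {c.construct_id: c.reg_seq for c in sequences}
        if isinstance(sequences, Library)
        else dict(sequences)
    )
    dep_ids = [c for c in idx if per_construct.loc[c, "depleted"]]
    ret_ids = [c for c in idx if not per_construct.loc[c, "depleted"]]
    if not dep_ids:
        return DepletionReport(
            per_construct,
            pd.DataFrame(columns=["kmer", "fold_enrichment", "p", "q"]),
            note="no depleted constructs; k-mer enrichment skipped",
        )
    kmer_hits: Dict[str, Tuple[int, int]] = {}
    for group, ids in (("dep", dep_ids), ("ret", ret_ids)):
        gi = 0 if group == "dep" else 1
        for cid in ids:
            for km in _degenerate_kmers_of(seqs[cid], kmer_size):
                a, b = kmer_hits.get(km, (0, 0))
                kmer_hits[km] = (a + 1, b) if gi == 0 else (a, b + 1)
    N = len(dep_ids) + len(ret_ids)
    n_dep = len(dep_ids)
    rows = []
    for km in sorted(kmer_hits):
        x, y = kmer_hits[km]
        m_tot = x + y
        p = float(stats.hypergeom.sf(x - 1, N, m_tot, n_dep))
        fold = (x / n_dep) / (m_tot / N)
        rows.append((km, fold, p, x, m_tot))
    kdf = pd.DataFrame(rows, columns=["kmer", "fold_enrichment", "p", "n_depleted", "n_total"])
    kdf["q"] = stats.false_discovery_control(kdf["p"].to_numpy(), method="bh")
    kdf = kdf.sort_values(
        ["fold_enrichment", "q", "kmer"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return DepletionReport(per_construct, kdf[["kmer", "fold_enrichment", "p", "q"]])
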