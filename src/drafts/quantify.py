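"""Per-construct counting and the transcriptional activity statistic.

Activity (Tx) of a construct is its relative RNA abundance divided by
its relative DNA abundance within a sample, with replicate counts
pooled by summation before the ratio.  Constructs whose summed DNA
count falls below a cutoff (default 15 reads) are excluded as too noisy
to quantify.  log10 activities are converted to Z-scores across the
passing constructs of each sample for cross-sample comparison.
"""

from __future__ import annotations

from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from drafts.library_io import Library
from drafts.read_processing import ProcessedRead, UNASSIGNED

DNA_MIN_READS_DEFAULT = 15

ACTIVITY_FIELDS = ["dna_count", "rna_count", "tx_raw", "tx_log10", "tx_z", "pass_filter"]


def tabulate_counts(
    reads: Iterable[ProcessedRead],
    lib: Library,
    sample: str = "sample1",
    counts_from: str = "barcode",
) -> pd.DataFrame:
    """Count assigned reads per (construct, sample, replicate, kind).

    Every library construct appears as a row (zeros allowed).  With the
    default ``counts_from='barcode'`` any barcode-assigned read counts
    toward abundance even if it failed the regulatory-segment QC (such
    reads are only barred from TSS pileups); ``counts_from='match'``
    restricts counting to QC-passing reads.
    """
    if counts_from not in ("barcode", "match"):
        raise ValueError(f"counts_from must be 'barcode' or 'match', got {counts_from!r}")
    tallies: dict[tuple[str, str, str], dict[str, int]] = {}
    for r in reads:
        if r.construct_id == UNASSIGNED:
            continue
        if counts_from == "match" and not r.pass_qc:
            continue
        col = (sample, r.replicate_id, r.kind)
        d = tallies.setdefault(col, {})
        d[r.construct_id] = d.get(r.construct_id, 0) + 1
    index = pd.Index([c.construct_id for c in lib], name="construct_id")
    cols = sorted(tallies)
    table = pd.DataFrame(
        {col: pd.Series(tallies[col], dtype="int64") for col in cols},
        index=index,
    ).fillna(0).astype("int64")
    table.columns = pd.MultiIndex.from_tuples(
        cols or [], names=["sample", "replicate", "kind"]
    )
    return table


def merge_count_tables(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Column-concatenate per-sample count tables over one library."""
    tables = list(tables)
    out = pd.concat(tables, axis=1)
    if out.columns.duplicated().any():
        dup = out.columns[out.columns.duplicated()].tolist()
        raise ValueError(f"duplicate (sample, replicate, kind) column(s): {dup}")
    return out.fillna(0).astype("int64")


def compute_activity(
    counts: pd.DataFrame,
    dna_min_reads: int = DNA_MIN_READS_DEFAULT,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Compute per-sample transcriptional activities from a count table.

    Returns a frame indexed like ``counts`` with columns
    ``(sample, field)`` for fields dna_count, rna_count, tx_raw,
    tx_log10, tx_z and pass_filter.  Per sample: replicate counts are
    summed per kind; relative abundances are count/total; tx_raw is
    rel_RNA/rel_DNA; constructs with summed DNA < ``dna_min_reads``
    fail the filter; tx_log10/tx_z are defined over passing constructs
    with nonzero RNA (all passing constructs when ``pseudocount`` > 0).
    Z-scores use the population SD (ddof=0).

    Constructs passing the DNA filter but with zero RNA are reported
    inactive (NaN tx_log10/tx_z) rather than assigned an arbitrary
    floor, unless a pseudocount is requested.
    """
    if counts.columns.duplicated().any():
        raise ValueError("count table has duplicated columns")
    if counts.columns.nlevels != 3:
        raise ValueError("count table needs (sample, replicate, kind) columns")
    out: dict[tuple[str, str], pd.Series] = {}
    for sample in counts.columns.get_level_values("sample").unique():
        sub = counts[sample]
        kinds = sub.columns.get_level_values("kind")
        if "DNA" not in set(kinds) or "RNA" not in set(kinds):
            raise ValueError(f"sample {sample!r} lacks a DNA or RNA column")
        dna = sub.loc[:, kinds == "DNA"].sum(axis=1)
        rna = sub.loc[:, kinds == "RNA"].sum(axis=1)
        if dna.sum() == 0:
            raise ValueError(f"sample {sample!r} has all-zero DNA counts")
        dna_a = dna.astype(float) + pseudocount
        rna_a = rna.astype(float) + pseudocount
        rel_dna = dna_a / dna_a.sum()
        rel_rna = rna_a / rna_a.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            tx_raw = rel_rna / rel_dna
        tx_raw = tx_raw.where(rel_dna > 0)
        passing = dna >= dna_min_reads
        defined = passing & (tx_raw > 0)
        tx_log10 = pd.Series(np.nan, index=counts.index)
        tx_log10[defined] = np.log10(tx_raw[defined])
        vals = tx_log10[defined]
        tx_z = pd.Series(np.nan, index=counts.index)
        if defined.any():
            sd = vals.std(ddof=0)
            if sd == 0:
                raise ValueError(f"sample {sample!r}: constant activity, Z undefined")
            tx_z[defined] = (vals - vals.mean()) / sd
        out[(sample, "dna_count")] = dna
        out[(sample, "rna_count")] = rna
        out[(sample, "tx_raw")] = tx_raw
        out[(sample, "tx_log10")] = tx_log10
        out[(sample, "tx_z")] = tx_z
        out[(sample, "pass_filter")] = passing
    res = pd.DataFrame(out, index=counts.index)
    res.columns = pd.MultiIndex.from_tuples(res.columns, names=["sample", "field"])
    return res


def sample_names(acts: pd.DataFrame) -> list[str]:
    return list(acts.columns.get_level_values("sample").unique())


def replicate_concordance(
    acts_a: pd.DataFrame,
    acts_b: pd.DataFrame,
    sample_a: Optional[str] = None,
    sample_b: Optional[str] = None,
) -> Tuple[float, int]:
    """Pearson r of tx_log10 between two activity tables.

    Computed over the constructs passing the DNA filter with defined
    activity in both tables; returns ``(r, n)``.
    """
    sample_a = sample_a or sample_names(acts_a)[0]
    sample_b = sample_b or sample_names(acts_b)[0]
    a = acts_a[sample_a]
    b = acts_b[sample_b]
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    ok = (
        a["pass_filter"].astype(bool)
        & b["pass_filter"].astype(bool)
        & a["tx_log10"].notna()
        & b["tx_log10"].notna()
    )
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"only {n} shared passing constructs (need >= 3)")
    r, _ = stats.pearsonr(a.loc[ok, "tx_log10"], b.loc[ok, "tx_log10"])
    return float(r), n


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_activity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
    df.columns = df.columns.set_names(["sample", "field"])
    return df


def read_count_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=[0, 1, 2], index_col=0)
    df.columns = df.columns.set_names(["sample", "replicate", "kind"])
    return df.astype("int64")
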