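"""Promoter sequence features for activity modeling.

Eight features are extracted per construct with a primary TSS:

====  =========================================================
f1    -35 element match score (log-odds, bits)
f2    -10 element match score (bits)
f3    -35 x -10 interaction (product of standardized f1, f2)
f4    spacer length penalty (0 at 17 bp, -1 per bp of deviation)
f5    spacer GC fraction
f6    TSS-region match score (8 bp downstream of the TSS, bits)
f7    5' mRNA folding pseudo-energy (first 50 nt of transcript)
f8    GC fraction of the full regulatory sequence
====  =========================================================

The -35/-10 position weight matrices are discovered de novo from the
45 bp upstream of the primary TSSs of the most active promoters (top
10% by activity) with a one-occurrence-per-sequence EM; the TSS-region
matrix likewise from the 8 bp downstream.  The -35/-10 elements are
placed by a joint scan that maximizes combined match score plus a
spacer penalty, with the spacer constrained to 17 +/- 2 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from drafts.library_io import Construct, Library

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

MOTIF_WIDTH_DEFAULT = 6
UPSTREAM_WINDOW_DEFAULT = 45
OPTIMAL_SPACER_DEFAULT = 17
SPACER_MAX_DEV_DEFAULT = 2
TSS_REGION_BP_DEFAULT = 8
FOLD_WINDOW_NT_DEFAULT = 50
TOP_ACTIVE_FRAC_DEFAULT = 0.10

FEATURE_NAMES = [
    "f1_minus35_score",
    "f2_minus10_score",
    "f3_interaction",
    "f4_spacer_penalty",
    "f5_spacer_gc",
    "f6_tss_region_score",
    "f7_utr_dG",
    "f8_gc_content",
]


@dataclass(frozen=True)
class Pwm:
    """Position weight matrix: per-position base probabilities.

    ``probs`` has shape (width, 4) over A, C, G, T; scores are
    log2(p/background) summed over positions ("bits").
    """

    probs: np.ndarray
    pseudocount: float = 0.1
    background: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if (p <= 0).any():
            raise ValueError("PWM probabilities must be positive")
        object.__setattr__(self, "probs", p)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / np.asarray(self.background))

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    def information_content(self) -> float:
        bg = np.asarray(self.background)
        return float((self.probs * np.log2(self.probs / bg)).sum())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.probs, columns=list(_BASES)).to_csv(
            path, sep="\t", index_label="position", float_format="%.6g"
        )

    @classmethod
    def from_tsv(cls, path) -> "Pwm":
        df = pd.read_csv(path, sep="\t", index_col="position")
        return cls(df[list(_BASES)].to_numpy())


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_IDX[b] for b in seq), dtype=np.int64, count=len(seq))


def score_pwm(pwm: Pwm, seq: str) -> Tuple[float, int]:
    """Best log-odds score of the PWM over all offsets of ``seq``.

    Returns ``(best_score_bits, best_offset)``; ties take the smallest
    offset.
    """
    w = pwm.width
    if len(seq) < w:
        raise ValueError(f"sequence shorter than PWM width {w}")
    lo = pwm.log_odds
    enc = _encode(seq.upper())
    n = len(seq) - w + 1
    scores = np.zeros(n)
    for j in range(w):
        scores += lo[j, enc[j : j + n]]
    best = int(np.argmax(scores))  # argmax takes the first maximum
    return float(scores[best]), best


def discover_pwm(
    seqs: Sequence[str],
    width: int = MOTIF_WIDTH_DEFAULT,
    region: Optional[Tuple[int, int]] = None,
    pseudocount: float = 0.1,
    max_iter: int = 200,
    tol: float = 1e-8,
    min_seqs: int = 20,
) -> Pwm:
    """One-occurrence-per-sequence EM motif discovery.

    Each sequence is assumed to contain exactly one motif instance at
    an unknown offset (uniform prior); the rest is i.i.d. uniform
    background.  Initialization is deterministic: the most frequent
    width-mer across the input (ties lexicographic) seeds a 0.7/0.1
    profile.  ``region`` optionally slices every sequence first.
    """
    if region is not None:
        seqs = [s[region[0] : region[1]] for s in seqs]
    seqs = [s.upper() for s in seqs]
    if len(seqs) < min_seqs:
        raise ValueError(f"need >= {min_seqs} sequences, got {len(seqs)}")
    if any(len(s) < width for s in seqs):
        raise ValueError("all sequences must be at least motif width long")

    kmer_counts: Dict[str, int] = {}
    for s in seqs:
        for i in range(len(s) - width + 1):
            k = s[i : i + width]
            kmer_counts[k] = kmer_counts.get(k, 0) + 1
    seed = min(kmer_counts, key=lambda k: (-kmer_counts[k], k))
    probs = np.full((width, 4), 0.1)
    for j, b in enumerate(seed):
        probs[j, _BASE_IDX[b]] = 0.7

    encs = [_encode(s) for s in seqs]
    prev_ll = -np.inf
    for _ in range(max_iter):
        lo = np.log2(probs / 0.25)
        counts = np.full((width, 4), pseudocount)
        ll = 0.0
        for enc in encs:
            n = len(enc) - width + 1
            sc = np.zeros(n)
            for j in range(width):
                sc += lo[j, enc[j : j + n]]
            m = sc.max()
            post = np.exp2(sc - m)
            z = post.sum()
            ll += m + np.log2(z) - np.log2(n)
            post /= z
            for j in range(width):
                np.add.at(counts[j], enc[j : j + n], post)
        probs = counts / counts.sum(axis=1, keepdims=True)
        if ll - prev_ll < tol:
            break
        prev_ll = ll
    return Pwm(probs, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# promoter geometry


@dataclass
class PromoterAnnotation:
    """Placement of the -35/-10 elements upstream of a primary TSS.

    ``minus35``/``minus10`` are ``(start, end, score)`` with start/end
    in construct coordinates (negative bp from the ATG, end inclusive);
    ``spacer_len`` is the gap between the -35 end and -10 start.
    """

    construct_id: str
    valid: bool
    minus35: Optional[Tuple[int, int, float]] = None
    minus10: Optional[Tuple[int, int, float]] = None
    spacer_len: Optional[int] = None
    spacer_penalty: Optional[float] = None
    spacer_seq: Optional[str] = None
    truncated: bool = False


def _pos_to_index(construct: Construct, pos: int) -> int:
    """Construct coordinate (negative, -1 = last reg_seq base) → string index."""
    return construct.length + pos


def upstream_window(
    construct: Construct, tss: int, window: int = UPSTREAM_WINDOW_DEFAULT
) -> str:
    """The up-to-``window`` bp of reg_seq immediately upstream of ``tss``."""
    it = _pos_to_index(construct, tss)
    return construct.reg_seq[max(0, it - window) : it]


def downstream_seq(construct: Construct, tss: int, n: int) -> str:
    """Up to ``n`` nt of transcript starting at ``tss`` (runs into the
    constant reporter context if the TSS is close to the ATG)."""
    it = _pos_to_index(construct, tss)
    full = construct.reg_seq + construct.reporter_context
    return full[it : it + n]


def annotate_promoter(
    construct: Construct,
    primary_tss: Optional[int],
    pwm10: Pwm,
    pwm35: Pwm,
    optimal_spacer: int = OPTIMAL_SPACER_DEFAULT,
    max_dev: int = SPACER_MAX_DEV_DEFAULT,
    window: int = UPSTREAM_WINDOW_DEFAULT,
    spacer_penalty_per_bp: float = 1.0,
) -> PromoterAnnotation:
    """Jointly place -35 and -10 elements in the window upstream of the TSS.

    All (-35 offset, -10 offset) pairs with spacer length within
    ``optimal_spacer +/- max_dev`` are scored as
    ``score35 + score10 - spacer_penalty_per_bp * |spacer - optimal|``
    and the maximum wins (ties: most downstream -10, then longest
    spacer).  ``valid=False`` when there is no primary TSS or no
    geometry fits the available window.
    """
    cid = construct.construct_id
    if primary_tss is None:
        return PromoterAnnotation(cid, valid=False)
    win = upstream_window(construct, primary_tss, window)
    truncated = len(win) < window
    w35, w10 = pwm35.width, pwm10.width
    need = w35 + (optimal_spacer - max_dev) + w10
    if len(win) < need:
        return PromoterAnnotation(cid, valid=False, truncated=truncated)
    lo35 = pwm35.log_odds
    lo10 = pwm10.log_odds
    enc = _encode(win)
    n35 = len(win) - w35 + 1
    s35 = np.zeros(n35)
    for j in range(w35):
        s35 += lo35[j, enc[j : j + n35]]
    n10 = len(win) - w10 + 1
    s10 = np.zeros(n10)
    for j in range(w10):
        s10 += lo10[j, enc[j : j + n10]]

    best = None
    for o35 in range(n35):
        for spacer in range(optimal_spacer - max_dev, optimal_spacer + max_dev + 1):
            o10 = o35 + w35 + spacer
            if o10 >= n10:
                continue
            pen = -spacer_penalty_per_bp * abs(spacer - optimal_spacer)
            total = s35[o35] + s10[o10] + pen
            key = (total, o10, spacer)
            if best is None or key > best[0]:
                best = (key, o35, o10, spacer, pen)
    if best is None:
        return PromoterAnnotation(cid, valid=False, truncated=truncated)
    _, o35, o10, spacer, pen = best
    # window ends at TSS: window index 0 is (tss - len(win)) in construct coords
    base = primary_tss - len(win)
    return PromoterAnnotation(
        construct_id=cid,
        valid=True,
        minus35=(base + o35, base + o35 + w35 - 1, float(s35[o35])),
        minus10=(base + o10, base + o10 + w10 - 1, float(s10[o10])),
        spacer_len=spacer,
        spacer_penalty=float(pen),
        spacer_seq=win[o35 + w35 : o10],
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# 5' mRNA folding


def _can_pair(a: str, b: str) -> bool:
    return (a + b) in {"AT", "TA", "GC", "CG", "GT", "TG", "AU", "UA", "GU", "UG"}


def fold_5prime(seq: str, backend: str = "nussinov", min_loop: int = 3) -> float:
    """Pseudo-energy (<= 0) of the 5' transcript end.

    The built-in backend is Nussinov maximum base pairing
    (Watson-Crick + GU wobble, hairpin loops >= ``min_loop`` nt) at -1
    per pair — a structure-propensity score, not a thermodynamic
    energy.  ``backend='external'`` delegates to ViennaRNA's minimum
    free energy (kcal/mol) when available.
    """
    seq = seq.upper().replace("U", "T")
    if set(seq) - set("ACGT"):
        raise ValueError("non-ACGT character in folding input")
    if backend == "external":
        return _fold_external(seq)
    if backend != "nussinov":
        raise ValueError(f"unknown folding backend {backend!r}")
    n = len(seq)
    if n == 0:
        return 0.0
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j - 1] + 1 if _can_pair(seq[i], seq[j]) else 0
            best = max(best, dp[i + 1, j], dp[i, j - 1])
            for k in range(i + 1, j):
                best = max(best, dp[i, k] + dp[k + 1, j])
            dp[i, j] = best
    return -float(dp[0, n - 1])


def _fold_external(seq: str) -> float:
    try:
        import RNA  # ViennaRNA python bindings

        return float(RNA.fold(seq.replace("T", "U"))[1])
    except ImportError:
        import subprocess

        out = subprocess.run(
            ["RNAfold", "--noPS"],
            input=seq.replace("T", "U") + "\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout
        last = out.strip().splitlines()[-1]
        return float(last.rsplit("(", 1)[1].rstrip(")").strip())


# ---------------------------------------------------------------------------
# feature matrix


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else np.nan


def discover_promoter_pwms(
    lib: Library,
    activities: pd.DataFrame,
    tss_calls: Dict,
    sample: Optional[str] = None,
    top_frac: float = TOP_ACTIVE_FRAC_DEFAULT,
    width: int = MOTIF_WIDTH_DEFAULT,
    window: int = UPSTREAM_WINDOW_DEFAULT,
    tss_region_bp: int = TSS_REGION_BP_DEFAULT,
) -> Dict[str, Pwm]:
    """Discover -35, -10 and TSS-region PWMs from the most active promoters.

    The top ``top_frac`` of constructs by tx_z (among those with a
    primary TSS and >= ``window`` bp upstream of it) contribute their
    upstream windows; the -10 matrix is sought in the TSS-proximal half
    of the window and the -35 matrix in the distal half, so the two
    elements do not collapse onto the same site.
    """
    from drafts.quantify import sample_names

    sample = sample or sample_names(activities)[0]
    txz = activities[(sample, "tx_z")].dropna()
    eligible = [
        cid
        for cid in txz.index
        if cid in tss_calls
        and tss_calls[cid].primary is not None
        and len(upstream_window(lib[cid], tss_calls[cid].primary, window)) == window
    ]
    if not eligible:
        raise ValueError("no constructs with a primary TSS and full upstream window")
    ranked = txz.loc[eligible].sort_values(ascending=False)
    n_top = max(20, int(round(top_frac * len(ranked))))
    top = list(ranked.index[:n_top])
    wins = [upstream_window(lib[c], tss_calls[c].primary, window) for c in top]
    half = window // 2
    pwm35 = discover_pwm([w[:half] for w in wins], width=width)
    pwm10 = discover_pwm([w[half:] for w in wins], width=width)
    tss_regions = [
        downstream_seq(lib[c], tss_calls[c].primary, tss_region_bp) for c in top
    ]
    tss_regions = [s for s in tss_regions if len(s) >= width]
    pwm_tss = discover_pwm(tss_regions, width=width)
    return {"minus35": pwm35, "minus10": pwm10, "tss_region": pwm_tss}


@dataclass
class FeatureMatrix:
    """Feature table (rows = constructs with valid promoter annotation)
    plus per-feature Pearson correlation with tx_z."""

    features: pd.DataFrame
    correlations: pd.Series
    sample: str


def build_feature_matrix(
    lib: Library,
    activities: pd.DataFrame,
    tss_calls: Dict,
    pwms: Dict[str, Pwm],
    sample: Optional[str] = None,
    optimal_spacer: int = OPTIMAL_SPACER_DEFAULT,
    max_dev: int = SPACER_MAX_DEV_DEFAULT,
    window: int = UPSTREAM_WINDOW_DEFAULT,
    tss_region_bp: int = TSS_REGION_BP_DEFAULT,
    fold_window_nt: int = FOLD_WINDOW_NT_DEFAULT,
    fold_backend: str = "nussinov",
) -> FeatureMatrix:
    """Assemble the f1..f8 matrix over constructs with a primary TSS.

    Only constructs with a primary TSS, a valid -35/-10 placement and a
    defined tx_z enter the matrix (complete rows only).
    """
    from drafts.quantify import sample_names

    sample = sample or sample_names(activities)[0]
    txz = activities[(sample, "tx_z")]
    rows = {}
    for c in lib:
        cid = c.construct_id
        calls = tss_calls.get(cid)
        if calls is None or calls.primary is None:
            continue
        z = txz.get(cid, np.nan)
        if pd.isna(z):
            continue
        ann = annotate_promoter(
            c, calls.primary, pwms["minus10"], pwms["minus35"],
            optimal_spacer=optimal_spacer, max_dev=max_dev, window=window,
        )
        if not ann.valid:
            continue
        tss_seq = downstream_seq(c, calls.primary, tss_region_bp)
        if len(tss_seq) < pwms["tss_region"].width:
            continue
        f6, _ = score_pwm(pwms["tss_region"], tss_seq)
        utr = downstream_seq(c, calls.primary, fold_window_nt)
        rows[cid] = {
            "f1_minus35_score": ann.minus35[2],
            "f2_minus10_score": ann.minus10[2],
            "f3_interaction": np.nan,  # filled after standardization
            "f4_spacer_penalty": ann.spacer_penalty,
            "f5_spacer_gc": _gc(ann.spacer_seq),
            "f6_tss_region_score": f6,
            "f7_utr_dG": fold_5prime(utr, backend=fold_backend),
            "f8_gc_content": _gc(c.reg_seq),
            "tx_z": z,
        }
    if not rows:
        raise ValueError("no constructs with primary TSS, valid annotation and tx_z")
    df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("construct_id")

    def _std(v: pd.Series) -> pd.Series:
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else v * 0.0

    df["f3_interaction"] = _std(df["f1_minus35_score"]) * _std(df["f2_minus10_score"])
    feats = df[FEATURE_NAMES]
    corr = feats.apply(
        lambda col: col.corr(df["tx_z"]) if col.std(ddof=0) > 0 else np.nan
    )
    return FeatureMatrix(features=feats, correlations=corr, sample=sample)
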