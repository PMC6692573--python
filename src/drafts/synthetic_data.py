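"""Synthetic libraries and sequencing reads with full ground truth.

The simulator emulates the pooled reporter assay end to end: a designed
library of 165-nt regulatory sequences with unique barcodes, a planted
sigma70 promoter (-35/-10 hexamers, 15-19 bp spacer, TSS 7 bp after the
-10 start) in a configurable fraction of constructs, true log10
activities generated as a linear combination of the same eight promoter
features the analysis extracts, and FASTQ reads: DNA reads multinomial
over a Dirichlet-perturbed input pool, RNA reads proportional to DNA
abundance times 10^activity with per-read 5'-end jitter and the common
3' adaptor (plus two random ligation bases) appended.  Every stage's
truth (counts, TSS positions, feature values, coefficients) is recorded
so pipeline output can be scored exactly.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from drafts.library_io import Construct, Library
from drafts.read_processing import AdaptorSpec
from drafts.sequence_features import (
    FEATURE_NAMES,
    Pwm,
    annotate_promoter,
    downstream_seq,
    fold_5prime,
    score_pwm,
)

_BASES = np.array(list("ACGT"))

# constant junction between the regulatory sequence and the barcode
# region of the reporter (an RBS-like spacer; any fixed sequence works)
DEFAULT_REPORTER_CONTEXT = "TTTAAGAAGGAGATATACAT"
DEFAULT_ADAPTOR = AdaptorSpec("AGATCGGAAGAGCACACGTCT", n_random_bases=2)

MINUS35_CONSENSUS = "TTGACA"
MINUS10_CONSENSUS = "TATAAT"

# per-feature generating coefficients (on standardized features) chosen
# to mirror the observed structure: -10/-35 strength dominate
# positively, GC content is the strongest negative predictor
DEFAULT_BETA = np.array([0.5, 0.6, 0.1, 0.2, -0.1, 0.2, 0.2, -0.4])
DEFAULT_NOISE_SD = 0.8


def canonical_pwms(strength: float = 0.7) -> Dict[str, Pwm]:
    """Soft consensus matrices for the sigma70 -35/-10 elements."""

    def soft(consensus: str) -> Pwm:
        probs = np.full((len(consensus), 4), (1 - strength) / 3)
        for j, b in enumerate(consensus):
            probs[j, "ACGT".index(b)] = strength
        return Pwm(probs)

    return {"minus35": soft(MINUS35_CONSENSUS), "minus10": soft(MINUS10_CONSENSUS)}


@dataclass
class PlantedPromoter:
    minus35_start: int  # construct coordinates (negative)
    minus10_start: int
    spacer_len: int
    strength: float


@dataclass
class SimulationTruth:
    """Ground truth for a simulated library."""

    library: Library
    true_tss: Dict[str, int]
    planted: Dict[str, Optional[PlantedPromoter]]
    features: Optional[pd.DataFrame] = None  # raw f1..f8
    features_std: Optional[pd.DataFrame] = None
    activity: Optional[pd.DataFrame] = None  # per-sample true log10 activity
    beta: Dict[str, np.ndarray] = field(default_factory=dict)
    noise_sd: float = DEFAULT_NOISE_SD


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _degrade(rng: np.random.Generator, motif: str, strength: float) -> str:
    out = []
    for b in motif:
        if rng.random() < strength:
            out.append(b)
        else:
            out.append(str(rng.choice([x for x in "ACGT" if x != b])))
    return "".join(out)


def _make_barcodes(
    rng: np.random.Generator, n: int, length: int, min_hamming: int = 3
) -> List[str]:
    codes = np.empty((n, length), dtype=np.int8)
    got = 0
    attempts = 0
    max_attempts = 2000 * n + 1000
    while got < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"barcode space exhausted: {got}/{n} barcodes of length {length} "
                f"at pairwise Hamming >= {min_hamming}"
            )
        cand = rng.integers(0, 4, size=length, dtype=np.int8)
        if got and int((codes[:got] != cand).sum(axis=1).min()) < min_hamming:
            continue
        codes[got] = cand
        got += 1
    return ["".join(_BASES[row]) for row in codes]


def generate_library(
    n: int,
    reg_len: int = 165,
    barcode_len: int = 12,
    motif_plant_frac: float = 0.7,
    gc: float = 0.5,
    seed: int = 0,
    reporter_context: str = DEFAULT_REPORTER_CONTEXT,
    name: str = "simlib",
) -> Tuple[Library, SimulationTruth]:
    """Random designed library with planted promoters and known TSSs.

    A fraction ``motif_plant_frac`` of constructs carries a
    consensus-degraded TTGACA/TATAAT pair (per-construct strength in
    [0.6, 1.0], spacer drawn from 15..19) with the true TSS 7 bp
    downstream of the -10 start; the rest get a TSS at a random
    position.  TSS positions leave >= 45 bp upstream so the promoter
    scan window always fits.  Barcodes are pairwise Hamming >= 3.
    """
    if n < 1:
        raise ValueError("n >= 1 required")
    if reg_len < 66:
        raise ValueError("reg_len too short to host a promoter and TSS window")
    rng = np.random.default_rng(seed)
    barcodes = _make_barcodes(rng, n, barcode_len)
    constructs = []
    true_tss: Dict[str, int] = {}
    planted: Dict[str, Optional[PlantedPromoter]] = {}
    width = max(4, len(str(n)))
    for i in range(n):
        cid = f"C{i:0{width}d}"
        seq = list(_random_seq(rng, reg_len, gc))
        i_tss = int(rng.integers(45, reg_len - 15))  # string index of TSS base
        tss = i_tss - reg_len  # negative construct coordinate
        if rng.random() < motif_plant_frac:
            strength = float(rng.uniform(0.6, 1.0))
            spacer = int(rng.integers(15, 20))
            i10 = i_tss - 7
            i35 = i10 - spacer - 6
            m35 = _degrade(rng, MINUS35_CONSENSUS, strength)
            m10 = _degrade(rng, MINUS10_CONSENSUS, strength)
            seq[i35 : i35 + 6] = list(m35)
            seq[i10 : i10 + 6] = list(m10)
            planted[cid] = PlantedPromoter(
                minus35_start=i35 - reg_len,
                minus10_start=i10 - reg_len,
                spacer_len=spacer,
                strength=strength,
            )
        else:
            planted[cid] = None
        true_tss[cid] = tss
        constructs.append(
            Construct(
                construct_id=cid,
                reg_seq="".join(seq),
                barcode=barcodes[i],
                reporter_context=reporter_context,
            )
        )
    lib = Library(constructs, name=name)
    return lib, SimulationTruth(library=lib, true_tss=true_tss, planted=planted)


def truth_features(lib: Library, truth: SimulationTruth) -> pd.DataFrame:
    """f1..f8 computed from the TRUE TSS with canonical -35/-10 matrices
    (no TSS calling involved)."""
    pwms = canonical_pwms()
    rows = {}
    for c in lib:
        tss = truth.true_tss[c.construct_id]
        ann = annotate_promoter(c, tss, pwms["minus10"], pwms["minus35"])
        if not ann.valid:
            continue
        tss_seq = downstream_seq(c, tss, 8)
        f6, _ = score_pwm(pwms["minus10"], tss_seq) if len(tss_seq) >= 6 else (0.0, 0)
        gc = lambda s: (s.count("G") + s.count("C")) / len(s) if s else 0.0
        rows[c.construct_id] = {
            "f1_minus35_score": ann.minus35[2],
            "f2_minus10_score": ann.minus10[2],
            "f3_interaction": np.nan,
            "f4_spacer_penalty": ann.spacer_penalty,
            "f5_spacer_gc": gc(ann.spacer_seq),
            "f6_tss_region_score": f6,
            "f7_utr_dG": fold_5prime(downstream_seq(c, tss, 50)),
            "f8_gc_content": gc(c.reg_seq),
        }
    df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("construct_id")

    def _std(v):
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else v * 0.0

    df["f3_interaction"] = _std(df["f1_minus35_score"]) * _std(df["f2_minus10_score"])
    return df[FEATURE_NAMES]


def assign_truth(
    lib: Library,
    truth: SimulationTruth,
    beta: Optional[np.ndarray | Dict[str, np.ndarray]] = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    samples: Sequence[str] = ("sample1",),
) -> SimulationTruth:
    """Draw true log10 activities: beta . standardized-features + noise.

    ``beta`` may be one length-8 vector (shared) or a per-sample dict,
    enabling cross-species simulations with species-specific feature
    weights.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    feats = truth_features(lib, truth)
    mu = feats.mean()
    sd = feats.std(ddof=0).replace(0, 1.0)
    Z = (feats - mu) / sd
    rng = np.random.default_rng(seed)
    if beta is None:
        beta = DEFAULT_BETA
    if isinstance(beta, dict):
        beta_map = {s: np.asarray(beta[s], dtype=float) for s in samples}
    else:
        beta_map = {s: np.asarray(beta, dtype=float) for s in samples}
    act = {}
    for s in samples:
        b = beta_map[s]
        if b.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"beta for {s!r} must have length {len(FEATURE_NAMES)}")
        act[s] = Z.to_numpy() @ b + rng.normal(0.0, noise_sd, size=len(Z))
    truth.features = feats
    truth.features_std = Z
    truth.activity = pd.DataFrame(act, index=feats.index)
    truth.beta = beta_map
    truth.noise_sd = noise_sd
    return truth


@dataclass
class SimReads:
    """Rendered reads plus the bookkeeping truth for one sample."""

    sample: str
    fastq: Dict[Tuple[str, str], Path]  # (kind, replicate) -> path
    dna_counts: pd.DataFrame  # constructs x replicates
    rna_counts: pd.DataFrame
    tss_read_counts: Dict[str, Dict[int, int]]  # cid -> pos -> reads (all reps)
    dna_pool_frac: pd.Series  # post-depletion input pool fractions


def _matches_motif(seq: str, motif: str) -> bool:
    k = len(motif)
    for i in range(len(seq) - k + 1):
        if all(m == "N" or m == c for m, c in zip(motif, seq[i : i + k])):
            return True
    return False


def _write_fastq(path: Path, names: List[str], seqs: List[str]) -> None:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(
            "".join(
                f"@{n}\n{s}\n+\n{'I' * len(s)}\n" for n, s in zip(names, seqs)
            )
        )


def simulate_reads(
    lib: Library,
    truth: SimulationTruth,
    outdir: str | Path,
    sample: str = "sample1",
    depth_dna: int = 100_000,
    depth_rna: int = 100_000,
    replicates: int = 2,
    tss_jitter_sd: float = 0.5,
    adaptor: AdaptorSpec = DEFAULT_ADAPTOR,
    depletion: Optional[Tuple[str, float]] = None,
    dirichlet_alpha: float = 20.0,
    fitness_lognormal_sd: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
    gzip_fastq: bool = False,
) -> SimReads:
    """Render DNA and RNA FASTQ files for one sample with known counts.

    The DNA pool is Dirichlet-perturbed uniform (concentration
    ``dirichlet_alpha``); a ``depletion=(motif, factor)`` divides the
    pool weight of motif-containing constructs by ``factor`` (degenerate
    N allowed in the motif).  RNA pool weights are DNA fraction times
    10^activity.  Each replicate is an independent multinomial draw of
    depth/replicates reads.  RNA 5' ends are the true TSS plus rounded
    Gaussian jitter (clipped to the regulatory sequence); reads are
    payload + random ligation bases + adaptor.  All randomness flows
    from ``seed``.
    """
    if truth.activity is None:
        raise ValueError("run assign_truth first")
    if depletion is not None and depletion[1] <= 0:
        raise ValueError("depletion factor must be > 0")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cids = [c.construct_id for c in lib]
    n = len(cids)
    L = lib.constructs[0].length

    pool = rng.dirichlet(np.full(n, dirichlet_alpha))
    if fitness_lognormal_sd > 0:
        pool = pool * rng.lognormal(0.0, fitness_lognormal_sd, size=n)
    if depletion is not None:
        motif, factor = depletion
        hit = np.array([_matches_motif(lib[c].reg_seq, motif) for c in cids])
        pool = np.where(hit, pool / factor, pool)
    pool = pool / pool.sum()
    act = truth.activity[sample].reindex(cids).to_numpy()
    rna_w = pool * np.power(10.0, act)
    rna_w = rna_w / rna_w.sum()

    ext = ".fastq.gz" if gzip_fastq else ".fastq"
    fastq: Dict[Tuple[str, str], Path] = {}
    dna_counts = {}
    rna_counts = {}
    tss_read_counts: Dict[str, Dict[int, int]] = {c: {} for c in cids}
    dna_payload = [c.reg_seq + c.reporter_context + c.barcode for c in lib]
    rna_suffix = [c.reporter_context + c.barcode for c in lib]

    def maybe_errors(seqs: List[str]) -> List[str]:
        if error_rate <= 0:
            return seqs
        out = []
        for s in seqs:
            arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
            hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
            for h in hits:
                arr[h] = ord(str(rng.choice([b for b in "ACGT" if b != chr(arr[h])])))
            out.append(arr.tobytes().decode())
        return out

    for rep in range(1, replicates + 1):
        rep_id = f"rep{rep}"
        dcount = rng.multinomial(depth_dna // replicates, pool)
        dna_counts[rep_id] = dcount
        names, seqs = [], []
        ridx = 0
        for i in np.nonzero(dcount)[0]:
            for _ in range(int(dcount[i])):
                names.append(f"D{rep}_{ridx}")
                seqs.append(dna_payload[i])
                ridx += 1
        p = outdir / f"{sample}_dna_{rep_id}{ext}"
        _write_fastq(p, names, maybe_errors(seqs))
        fastq[("DNA", rep_id)] = p

        rcount = rng.multinomial(depth_rna // replicates, rna_w)
        rna_counts[rep_id] = rcount
        names, seqs = [], []
        ridx = 0
        for i in np.nonzero(rcount)[0]:
            cid = cids[i]
            c = lib.constructs[i]
            m = int(rcount[i])
            tss = truth.true_tss[cid]
            if tss_jitter_sd > 0:
                pos = np.rint(rng.normal(tss, tss_jitter_sd, size=m)).astype(int)
                pos = np.clip(pos, -L, -1)
            else:
                pos = np.full(m, tss)
            rand_bases = _BASES[rng.integers(0, 4, size=(m, adaptor.n_random_bases))]
            for jj in range(m):
                pj = int(pos[jj])
                tss_read_counts[cid][pj] = tss_read_counts[cid].get(pj, 0) + 1
                payload = c.reg_seq[L + pj :] + rna_suffix[i]
                names.append(f"R{rep}_{ridx}")
                seqs.append(
                    payload + "".join(rand_bases[jj]) + adaptor.adaptor_seq
                )
                ridx += 1
        p = outdir / f"{sample}_rna_{rep_id}{ext}"
        _write_fastq(p, names, maybe_errors(seqs))
        fastq[("RNA", rep_id)] = p

    index = pd.Index(cids, name="construct_id")
    return SimReads(
        sample=sample,
        fastq=fastq,
        dna_counts=pd.DataFrame(dna_counts, index=index),
        rna_counts=pd.DataFrame(rna_counts, index=index),
        tss_read_counts=tss_read_counts,
        dna_pool_frac=pd.Series(pool, index=index),
    )


def simulate_count_tables(
    lib: Library,
    truth: SimulationTruth,
    samples: Sequence[str] = ("sample1",),
    depth_dna: int = 1_000_000,
    depth_rna: int = 1_000_000,
    replicates: int = 2,
    dirichlet_alpha: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Count table straight from the generative model (no read rendering).

    Same sampling scheme as :func:`simulate_reads` minus FASTQ
    rendering — useful for large multi-sample comparative simulations.
    """
    if truth.activity is None:
        raise ValueError("run assign_truth first")
    rng = np.random.default_rng(seed)
    cids = [c.construct_id for c in lib]
    n = len(cids)
    cols = {}
    for s in samples:
        pool = rng.dirichlet(np.full(n, dirichlet_alpha))
        act = truth.activity[s].reindex(cids).to_numpy()
        rna_w = pool * np.power(10.0, act)
        rna_w = rna_w / rna_w.sum()
        for rep in range(1, replicates + 1):
            cols[(s, f"rep{rep}", "DNA")] = rng.multinomial(
                depth_dna // replicates, pool
            )
            cols[(s, f"rep{rep}", "RNA")] = rng.multinomial(
                depth_rna // replicates, rna_w
            )
    out = pd.DataFrame(cols, index=pd.Index(cids, name="construct_id"))
    out.columns = pd.MultiIndex.from_tuples(
        out.columns, names=["sample", "replicate", "kind"]
    )
    return out


def simulate_depletion_counts(
    lib: Library,
    motif: str = "CCNGG",
    factor: float = 20.0,
    depth_in: int = 200_000,
    depth_out: int = 200_000,
    dirichlet_alpha: float = 20.0,
    seed: int = 0,
) -> Tuple[pd.Series, pd.Series, List[str]]:
    """Input vs post-reaction DNA counts with motif-bearing constructs
    depleted ``factor``-fold; returns (in_counts, out_counts, hit_ids)."""
    if factor <= 0:
        raise ValueError("depletion factor must be > 0")
    rng = np.random.default_rng(seed)
    cids = [c.construct_id for c in lib]
    n = len(cids)
    pool = rng.dirichlet(np.full(n, dirichlet_alpha))
    hit = np.array([_matches_motif(lib[c].reg_seq, motif) for c in cids])
    out_pool = np.where(hit, pool / factor, pool)
    out_pool = out_pool / out_pool.sum()
    idx = pd.Index(cids, name="construct_id")
    in_counts = pd.Series(rng.multinomial(depth_in, pool), index=idx)
    out_counts = pd.Series(rng.multinomial(depth_out, out_pool), index=idx)
    return in_counts, out_counts, [c for c, h in zip(cids, hit) if h]
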