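"""Read merging, adaptor trimming and barcode demultiplexing.

The assay sequences two pools per sample: the input DNA library, and
cDNA made from reporter mRNA with a common adaptor (carrying two random
ligation bases) ligated at the cDNA 3' end — which corresponds to the
mRNA 5' end, so the position where a trimmed RNA read starts inside the
regulatory sequence IS the transcription start site of that molecule.

Processed reads are streamed as :class:`ProcessedRead`; every input
read ends up in exactly one of {assigned, unassigned, rejected}, which
the :class:`QcTally` asserts.
"""

from __future__ import annotations

import csv
import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from drafts.library_io import Library

UNASSIGNED = "UNASSIGNED"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AdaptorSpec:
    """Common 3'-ligated adaptor: its sequence plus the random bases
    (default 2) that sit between the biological payload and the adaptor."""

    adaptor_seq: str
    n_random_bases: int = 2

    def __post_init__(self) -> None:
        if self.n_random_bases < 0:
            raise ValueError("n_random_bases must be >= 0")


@dataclass
class ProcessedRead:
    construct_id: str
    kind: str  # "DNA" | "RNA"
    replicate_id: str
    five_prime_pos: Optional[int] = None  # RNA only; bp from ATG, negative
    pass_qc: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("DNA", "RNA"):
            raise ValueError(f"kind must be DNA or RNA, got {self.kind!r}")
        if self.kind == "DNA" and self.five_prime_pos is not None:
            raise ValueError("DNA reads never carry five_prime_pos")


@dataclass
class QcTally:
    """Per-run bookkeeping; assigned + unassigned + rejected == total."""

    total: int = 0
    assigned: int = 0
    unassigned: int = 0
    rejected_merge: int = 0
    rejected_trim: int = 0
    qc_failed: int = 0  # assigned but excluded from TSS pileups
    extra: dict = field(default_factory=dict)

    @property
    def rejected(self) -> int:
        return self.rejected_merge + self.rejected_trim

    def assert_conserved(self) -> None:
        if self.assigned + self.unassigned + self.rejected != self.total:
            raise AssertionError(
                f"read conservation violated: {self.assigned}+{self.unassigned}"
                f"+{self.rejected} != {self.total}"
            )


def merge_pairs(
    r1,
    r2,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> Optional[str]:
    """Merge a read pair by overlap consensus; return None on reject.

    ``r1``/``r2`` are sequences or ``(sequence, quality)`` tuples; r2 is
    reverse-complemented internally.  The unique offset with the highest
    number of matching overlap bases (overlap >= ``min_overlap``,
    mismatch fraction <= ``max_mismatch_frac``) wins; a tie between two
    candidate offsets is ambiguous and rejects the pair.  Disagreeing
    bases take the higher-quality call (r1 wins ties).
    """
    s1, q1 = (r1, None) if isinstance(r1, str) else r1
    s2raw, q2raw = (r2, None) if isinstance(r2, str) else r2
    if not s1 or not s2raw:
        raise ValueError("empty read")
    s2 = revcomp(s2raw)
    q2 = q2raw[::-1] if q2raw is not None else None

    best: list[tuple[int, int, int]] = []  # (matches, overlap, offset)
    # offset = index in s1 where s2's first base aligns
    for off in range(0, len(s1) - min_overlap + 1):
        ov = min(len(s1) - off, len(s2))
        if ov < min_overlap:
            continue
        m = sum(a == b for a, b in zip(s1[off : off + ov], s2[:ov]))
        if (ov - m) / ov > max_mismatch_frac:
            continue
        best.append((m, ov, off))
    if not best:
        return None
    best.sort(key=lambda t: (-t[0], t[2]))
    if len(best) > 1 and best[0][0] == best[1][0]:
        return None  # ambiguous overlap
    _, ov, off = best[0]
    cons = list(s1[:off])
    for i in range(ov):
        a, b = s1[off + i], s2[i]
        if a == b:
            cons.append(a)
        else:
            qa = ord(q1[off + i]) if q1 else 0
            qb = ord(q2[i]) if q2 else -1
            cons.append(a if qa >= qb else b)
    cons.append(s2[ov:])
    return "".join(cons)


def trim_adaptor(
    seq: str, spec: AdaptorSpec, max_mismatches: int = 0
) -> Optional[str]:
    """Strip the 3' common adaptor plus its random bases; None on reject.

    Layout: ``payload + <n_random_bases> + adaptor``.  The adaptor is
    located by Hamming scan over end offsets (fewest mismatches wins,
    ties to the read end); absence, or a payload that would be negative
    length, rejects the read.
    """
    if not seq:
        raise ValueError("empty sequence")
    ad = spec.adaptor_seq
    alen = len(ad)
    if len(seq) < alen + spec.n_random_bases:
        return None
    # fast path: exact at the very end
    if seq.endswith(ad):
        start = len(seq) - alen
    else:
        start = None
        best_mm = max_mismatches + 1
        for i in range(len(seq) - alen, -1, -1):
            mm = sum(a != b for a, b in zip(seq[i : i + alen], ad))
            if mm < best_mm:
                best_mm, start = mm, i
        if start is None or best_mm > max_mismatches:
            return None
    cut = start - spec.n_random_bases
    if cut < 0:
        return None
    return seq[:cut]


def assign_read(
    seq: str,
    lib: Library,
    kind: str,
    replicate_id: str = "rep1",
    max_reg_mismatches: int = 1,
) -> ProcessedRead:
    """Demultiplex one adaptor-trimmed read to a construct by barcode.

    Reads end with the barcode, preceded by the constant reporter
    context, preceded by a suffix of the regulatory sequence.  Barcode
    matching is exact.  For RNA reads the regulatory segment is checked
    against the construct's reg_seq suffix (<= ``max_reg_mismatches``
    tolerated); its first base gives ``five_prime_pos`` in bp from the
    ATG.  A segment that does not match (or would fall upstream of the
    designed sequence) keeps the barcode assignment but fails QC, so it
    counts toward abundance yet never enters a TSS pileup.
    """
    bl = lib.barcode_length
    if len(seq) < bl:
        return ProcessedRead(UNASSIGNED, kind, replicate_id, None, False)
    cid = lib.barcode_index.get(seq[-bl:])
    if cid is None:
        return ProcessedRead(UNASSIGNED, kind, replicate_id, None, False)
    if kind == "DNA":
        return ProcessedRead(cid, "DNA", replicate_id, None, True)
    construct = lib[cid]
    seg = seq[:-bl]
    ctx = construct.reporter_context
    if ctx:
        if not seg.endswith(ctx):
            return ProcessedRead(cid, "RNA", replicate_id, None, False)
        seg = seg[: -len(ctx)]
    n = len(seg)
    if n == 0 or n > construct.length:
        # 5' end at/inside ATG or upstream of the designed sequence:
        # impossible for a well-formed construct, flagged as QC failure
        return ProcessedRead(cid, "RNA", replicate_id, None, False)
    ref_suffix = construct.reg_seq[-n:]
    if seg != ref_suffix:
        mm = sum(a != b for a, b in zip(seg, ref_suffix))
        if mm > max_reg_mismatches:
            return ProcessedRead(cid, "RNA", replicate_id, None, False)
    return ProcessedRead(cid, "RNA", replicate_id, -n, True)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) from a (possibly gzipped) FASTQ."""
    with _open_maybe_gzip(path) as fh:
        yield from FastqGeneralIterator(fh)


def process_fastq(
    lib: Library,
    path: str | Path,
    kind: str,
    replicate_id: str,
    adaptor: Optional[AdaptorSpec] = None,
    mate_path: Optional[str | Path] = None,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    adaptor_max_mismatches: int = 1,
    tally: Optional[QcTally] = None,
) -> Iterator[ProcessedRead]:
    """Stream ProcessedReads from FASTQ (merging pairs if a mate is given).

    RNA reads are adaptor-trimmed before demultiplexing; DNA reads are
    used as-is (the input library is sequenced without the ligation
    adaptor).
    """
    if tally is None:
        tally = QcTally()
    if mate_path is not None:
        pairs = zip(iter_fastq(path), iter_fastq(mate_path))
        seqs: Iterable[Optional[str]] = (
            merge_pairs((s1, q1), (s2, q2), min_overlap, max_mismatch_frac)
            for (_, s1, q1), (_, s2, q2) in pairs
        )
    else:
        seqs = (s for _, s, _ in iter_fastq(path))
    trim = kind == "RNA" and adaptor is not None
    for seq in seqs:
        tally.total += 1
        if seq is None:
            tally.rejected_merge += 1
            continue
        if trim:
            seq = trim_adaptor(seq, adaptor, adaptor_max_mismatches)
            if seq is None:
                tally.rejected_trim += 1
                continue
        read = assign_read(seq, lib, kind, replicate_id)
        if read.construct_id == UNASSIGNED:
            tally.unassigned += 1
        else:
            tally.assigned += 1
            if not read.pass_qc:
                tally.qc_failed += 1
        yield read


_TSV_HEADER = ["construct_id", "kind", "replicate", "five_prime_pos", "pass_qc"]


def write_reads_tsv(reads: Iterable[ProcessedRead], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_HEADER)
        for r in reads:
            w.writerow(
                [
                    r.construct_id,
                    r.kind,
                    r.replicate_id,
                    "" if r.five_prime_pos is None else r.five_prime_pos,
                    int(r.pass_qc),
                ]
            )
    return path


def read_reads_tsv(path: str | Path) -> Iterator[ProcessedRead]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pos = row["five_prime_pos"]
            yield ProcessedRead(
                row["construct_id"],
                row["kind"],
                row["replicate"],
                int(pos) if pos else None,
                bool(int(row["pass_qc"])),
            )
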