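"""Designed-library data model and I/O.

A library member ("construct") is a regulatory sequence placed
immediately upstream of a reporter ATG, identified in pooled sequencing
by a unique barcode inside the reporter coding region.  Coordinates are
1-based with the ATG "A" at +1; upstream positions are negative with no
zero, so the last base of the regulatory sequence is -1.  All
transcription start sites are therefore negative integers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

_VALID_BASES = frozenset("ACGT")


class LibraryError(ValueError):
    """Raised when a library file violates the data-model invariants."""


def _check_dna(seq: str, what: str, where: str, allow_empty: bool = False) -> str:
    seq = seq.strip().upper()
    if not seq and not allow_empty:
        raise LibraryError(f"{where}: empty {what}")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise LibraryError(
            f"{where}: {what} contains non-ACGT character(s) {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class Construct:
    """One designed library member.

    Parameters
    ----------
    construct_id : str
        Unique identifier.
    reg_seq : str
        Regulatory sequence (default design length 165 nt) upstream of
        the reporter ATG; its last base sits at position -1.
    barcode : str
        Unique DNA barcode (constant length per library).
    reporter_context : str
        Constant sequence joining the regulatory sequence to the
        barcode region of the reporter (may be empty).
    metadata : mapping
        Free-form annotations (donor phylum, gene class, ...).
    """

    construct_id: str
    reg_seq: str
    barcode: str
    reporter_context: str = ""
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "reg_seq", _check_dna(self.reg_seq, "reg_seq", self.construct_id)
        )
        object.__setattr__(
            self, "barcode", _check_dna(self.barcode, "barcode", self.construct_id)
        )
        object.__setattr__(
            self,
            "reporter_context",
            _check_dna(
                self.reporter_context, "reporter_context", self.construct_id, True
            ),
        )

    @property
    def length(self) -> int:
        return len(self.reg_seq)


class Library:
    """Ordered collection of constructs with a barcode index."""

    def __init__(
        self,
        constructs: Iterable[Construct],
        name: str = "library",
        variable_length: bool = False,
    ) -> None:
        self.name = name
        self.constructs: list[Construct] = list(constructs)
        self.barcode_index: dict[str, str] = {}
        dup: dict[str, list[str]] = {}
        for c in self.constructs:
            if c.barcode in self.barcode_index:
                dup.setdefault(c.barcode, [self.barcode_index[c.barcode]]).append(
                    c.construct_id
                )
            self.barcode_index[c.barcode] = c.construct_id
        if dup:
            offenders = "; ".join(
                f"{bc}: {', '.join(ids)}" for bc, ids in sorted(dup.items())
            )
            raise LibraryError(f"duplicate barcode(s) — {offenders}")
        ids = [c.construct_id for c in self.constructs]
        if len(set(ids)) != len(ids):
            raise LibraryError("duplicate construct_id")
        if self.constructs:
            bl = {len(c.barcode) for c in self.constructs}
            if len(bl) != 1:
                raise LibraryError(f"barcode lengths differ: {sorted(bl)}")
            if not variable_length:
                rl = {c.length for c in self.constructs}
                if len(rl) != 1:
                    raise LibraryError(
                        f"reg_seq lengths differ: {sorted(rl)} "
                        "(pass variable_length=True to allow)"
                    )
        self._by_id = {c.construct_id: c for c in self.constructs}

    def __len__(self) -> int:
        return len(self.constructs)

    def __iter__(self):
        return iter(self.constructs)

    def __getitem__(self, construct_id: str) -> Construct:
        return self._by_id[construct_id]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Library)
            and self.name == other.name
            and self.constructs == other.constructs
        )

    @property
    def barcode_length(self) -> int:
        if not self.constructs:
            raise LibraryError("empty library has no barcode length")
        return len(self.constructs[0].barcode)

    def min_pairwise_barcode_hamming(self) -> int:
        """Smallest pairwise Hamming distance among barcodes (O(n^2))."""
        bcs = [c.barcode for c in self.constructs]
        best = len(bcs[0]) if bcs else 0
        for i in range(len(bcs)):
            for j in range(i + 1, len(bcs)):
                d = sum(a != b for a, b in zip(bcs[i], bcs[j]))
                if d < best:
                    best = d
                    if best == 0:
                        return 0
        return best


_TSV_COLUMNS = ["construct_id", "reg_seq", "barcode", "reporter_context"]


def load_library(
    path: str | Path, format: str | None = None, variable_length: bool = False
) -> Library:
    """Load a designed library from TSV or FASTA.

    TSV needs columns ``construct_id``, ``reg_seq``, ``barcode`` and
    optionally ``reporter_context``.  FASTA headers are
    ``construct_id|barcode`` and the record sequence is
    ``reg_seq + reporter_context`` (context taken as empty on load).
    Input is case-insensitive; sequences are uppercased.
    """
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".fna"} else "tsv"
    if format == "tsv":
        return _load_tsv(path, variable_length)
    if format == "fasta":
        return _load_fasta(path, variable_length)
    raise ValueError(f"unknown library format: {format!r}")


def _load_tsv(path: Path, variable_length: bool = False) -> Library:
    constructs = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise LibraryError(f"{path}: empty file")
        missing = {"construct_id", "reg_seq", "barcode"} - set(reader.fieldnames)
        if missing:
            raise LibraryError(f"{path}: missing column(s) {sorted(missing)}")
        extra = [
            f for f in reader.fieldnames if f not in _TSV_COLUMNS
        ]  # extra columns become metadata
        for lineno, row in enumerate(reader, start=2):
            try:
                constructs.append(
                    Construct(
                        construct_id=row["construct_id"],
                        reg_seq=row["reg_seq"],
                        barcode=row["barcode"],
                        reporter_context=row.get("reporter_context") or "",
                        metadata={k: row[k] for k in extra if row.get(k)},
                    )
                )
            except LibraryError as e:
                raise LibraryError(f"{path}:{lineno}: {e}") from None
    return Library(constructs, name=path.stem, variable_length=variable_length)


def _load_fasta(path: Path, variable_length: bool = False) -> Library:
    constructs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise LibraryError(f"{path}: FASTA header {rec.id!r} not 'construct_id|barcode'")
        cid, barcode = rec.id.split("|", 1)
        constructs.append(
            Construct(construct_id=cid, reg_seq=str(rec.seq), barcode=barcode)
        )
    return Library(constructs, name=path.stem, variable_length=variable_length)


def write_library(lib: Library, path: str | Path, format: str | None = None) -> Path:
    """Write a library; output is bit-stable and round-trips via load_library."""
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".fna"} else "tsv"
    if format == "tsv":
        meta_keys = sorted({k for c in lib for k in c.metadata})
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(_TSV_COLUMNS + meta_keys)
            for c in lib:
                w.writerow(
                    [c.construct_id, c.reg_seq, c.barcode, c.reporter_context]
                    + [c.metadata.get(k, "") for k in meta_keys]
                )
    elif format == "fasta":
        with open(path, "w") as fh:
            for c in lib:
                fh.write(f">{c.construct_id}|{c.barcode}\n")
                fh.write(c.reg_seq + c.reporter_context + "\n")
    else:
        raise ValueError(f"unknown library format: {format!r}")
    return path
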