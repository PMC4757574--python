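"""Domain types, coordinate conventions, and FASTA/FASTQ readers/writers.

Coordinates are 0-based half-open everywhere inside the package; every
user-facing table reports 1-based inclusive positions and says so in its
header.  Sequence comparisons between reads (DNA, sequencer output) and
references (typically RNA substrates) are done in a canonical T-alphabet;
results that describe motifs on an RNA reference are rendered with U.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FormatError",
    "Reference",
    "ReferenceSet",
    "SequencedRead",
    "PreparedRead",
    "Mapping",
    "canonical",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
]

PHRED_OFFSET = 33  # Sanger / modern Illumina; no autodetection by design

_VALID_REF_CHARS = frozenset("ACGTU")
_VALID_READ_CHARS = frozenset("ACGTUN")

_DNA_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")
_RNA_COMPLEMENT = str.maketrans("ACGTUN", "UGCAAN")
_TO_CANONICAL = str.maketrans("acgtun", "ACGTTN")
_U_TO_T = str.maketrans("Uu", "Tt")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def canonical(sequence: str) -> str:
    """Upper-case, T-alphabet form used for all exact comparisons."""
    return sequence.upper().translate(_U_TO_T)


def reverse_complement(sequence: str, alphabet: str = "DNA") -> str:
    """Reverse complement over {A,C,G,T,U,N}.

    ``alphabet`` selects the letter used for the complement of A ("DNA" -> T,
    "RNA" -> U); N maps to N.  An involution on sequences written purely in
    the chosen alphabet.
    """
    table = _RNA_COMPLEMENT if alphabet == "RNA" else _DNA_COMPLEMENT
    return sequence.upper().translate(table)[::-1]


@dataclass(frozen=True)
class Reference:
    """One named substrate sequence."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceSet:
    """Named substrate sequences plus an alphabet flag ("DNA" or "RNA").

    Invariants enforced on construction: ids unique, sequences non-empty,
    no ambiguity codes (the substrates are fully defined synthetic RNAs).
    """

    references: list[Reference]
    alphabet: str = "DNA"
    _canonical: dict[str, str] = field(default_factory=dict, repr=False)
    _by_id: dict[str, Reference] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.alphabet not in ("DNA", "RNA"):
            raise ValueError(f"alphabet must be DNA or RNA, got {self.alphabet!r}")
        seen: set[str] = set()
        for ref in self.references:
            if ref.id in seen:
                raise FormatError(f"duplicate reference id: {ref.id!r}")
            seen.add(ref.id)
            if not ref.sequence:
                raise FormatError(f"reference {ref.id!r} has an empty sequence")
            bad = set(ref.sequence.upper()) - _VALID_REF_CHARS
            if bad:
                raise FormatError(
                    f"reference {ref.id!r} contains non-ACGTU characters: "
                    f"{sorted(bad)}"
                )
            self._by_id[ref.id] = ref
            self._canonical[ref.id] = canonical(ref.sequence)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], alphabet: str | None = None
    ) -> "ReferenceSet":
        refs = [Reference(i, s) for i, s in pairs]
        if alphabet is None:
            alphabet = "RNA" if any("U" in r.sequence.upper() for r in refs) else "DNA"
        return cls(refs, alphabet)

    def __iter__(self) -> Iterator[Reference]:
        return iter(self.references)

    def __len__(self) -> int:
        return len(self.references)

    def ids(self) -> list[str]:
        return [r.id for r in self.references]

    def get(self, ref_id: str) -> Reference:
        return self._by_id[ref_id]

    def canonical_sequence(self, ref_id: str) -> str:
        return self._canonical[ref_id]


@dataclass(frozen=True)
class SequencedRead:
    """A raw read: sequence (may contain N) plus per-base Phred qualities.

    Qualities are stored as the Phred+33 string; :attr:`qualities` decodes
    them on demand.  ``mate`` is 1 or 2 for paired data, 0 when unknown.
    """

    id: str
    sequence: str
    quality_string: str
    mate: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality_string):
            raise FormatError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality_string)}"
            )

    @property
    def qualities(self) -> np.ndarray:
        return (
            np.frombuffer(self.quality_string.encode("ascii"), dtype=np.uint8)
            .astype(np.int32)
            - PHRED_OFFSET
        )

    @classmethod
    def from_scores(
        cls, id: str, sequence: str, scores: Iterable[int], mate: int = 0
    ) -> "SequencedRead":
        qual = "".join(chr(int(q) + PHRED_OFFSET) for q in scores)
        return cls(id, sequence, qual, mate)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PreparedRead:
    """A quality-trimmed, barcode-stripped 5' fragment.

    The first base is the putative cleavage-derived 5' nucleotide.
    ``source_orientation`` records whether the barcode anchor was found on
    the read as sequenced ("forward") or on its reverse complement
    ("reverse").
    """

    id: str
    sequence: str
    source_orientation: str = "forward"


@dataclass(frozen=True)
class Mapping:
    """An exact, full-length, zero-mismatch placement of a prepared read."""

    read_id: str
    ref_id: str
    start: int  # 0-based on the reference
    length: int


# ---------------------------------------------------------------------------
# file I/O


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: str | Path) -> ReferenceSet:
    """Read a multi-record FASTA into a :class:`ReferenceSet`.

    U and T are both accepted and stored as given; the alphabet is
    auto-detected (any U anywhere -> RNA).  Empty files, duplicate ids and
    non-IUPAC characters raise :class:`FormatError` naming the record.
    """
    with _open_text(path) as handle:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return ReferenceSet.from_pairs(records)


def write_fasta(refs: ReferenceSet, path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for ref in refs:
            out.write(f">{ref.id}\n")
            for i in range(0, len(ref.sequence), width):
                out.write(ref.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path, mate: int = 0) -> Iterator[SequencedRead]:
    """Stream Sanger-encoded (Phred+33) FASTQ records; gzip transparent.

    Raises :class:`FormatError` (with the offending record's position and,
    when known, title) on malformed records such as sequence/quality length
    mismatches.
    """
    with _open_text(path) as handle:
        n = 0
        last_title = ""
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                n += 1
                last_title = title
                if len(seq) != len(qual):
                    raise FormatError(
                        f"{path}: record {title!r} (#{n}): sequence and "
                        f"quality lengths differ"
                    )
                bad = set(seq.upper()) - _VALID_READ_CHARS
                if bad:
                    raise FormatError(
                        f"{path}: record {title!r} (#{n}): non-IUPAC "
                        f"characters {sorted(bad)}"
                    )
                yield SequencedRead(title, seq, qual, mate)
        except ValueError as err:
            if isinstance(err, FormatError):
                raise
            where = f"after record {last_title!r} (#{n})" if n else "at start"
            raise FormatError(f"{path}: invalid FASTQ {where}: {err}") from err


def write_fastq(reads: Iterable[SequencedRead], path: str | Path) -> None:
    with _open_text(path, "wt") as out:
        for read in reads:
            out.write(f"@{read.id}\n{read.sequence}\n+\n{read.quality_string}\n")


def format_fastq_record(read: SequencedRead) -> str:
    return f"@{read.id}\n{read.sequence}\n+\n{read.quality_string}\n"
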