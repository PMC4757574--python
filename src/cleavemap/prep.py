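"""Read preparation: quality trimming, barcode-anchor stripping, length filter.

The library chemistry ligates a 45-nt barcode RNA to cleavage-derived 5'
ends; its 3'-terminal 15 nt (the *anchor*) therefore appear in a read
immediately upstream of the first nucleotide of the cleaved fragment.
Preparation keeps exactly the reads that carry the anchor and returns the
sequence strictly 3' of it.

Anchor matching is exact substring search.  Under the score model used by
the original workflow (match +1, mismatch and gap cost 5, minimum match
score 15) a 15-nt anchor with any single edit scores at most 14 - 5 = 9,
so exact matching is provably equivalent; the test suite asserts this by
brute force over all single-edit anchor variants.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .io import PreparedRead, SequencedRead, canonical, reverse_complement

__all__ = [
    "DEFAULT_ANCHOR",
    "PrepConfig",
    "PrepStatus",
    "PrepResult",
    "PrepReport",
    "quality_trim",
    "strip_barcode",
    "prepare_read",
    "prepare_stream",
]

# 3'-terminal 15 nt of the barcode oligonucleotide
DEFAULT_ANCHOR = "CTGGCTTTGATGAAA"


@dataclass(frozen=True)
class PrepConfig:
    """Parameters of the read-preparation stage.

    quality_limit is the per-base error-probability limit of modified-Mott
    trimming; max_ambiguities caps N bases surviving the trim;
    min_length_after_trim discards fragments too short to map uniquely.
    """

    quality_limit: float = 0.05
    max_ambiguities: int = 0
    anchor: str = DEFAULT_ANCHOR
    min_length_after_trim: int = 15
    search_both_orientations: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.quality_limit < 1.0):
            raise ValueError("quality_limit must be in (0, 1)")
        if len(self.anchor) < 8:
            raise ValueError("anchor must be at least 8 nt")
        if self.min_length_after_trim < 1:
            raise ValueError("min_length_after_trim must be >= 1")
        if self.max_ambiguities < 0:
            raise ValueError("max_ambiguities must be >= 0")


class PrepStatus(str, enum.Enum):
    OK = "ok"
    LOW_QUALITY = "quality_rejected"
    TOO_MANY_N = "ambiguity_rejected"
    NO_ANCHOR = "no_anchor"
    TOO_SHORT = "too_short"


@dataclass(frozen=True)
class PrepResult:
    status: PrepStatus
    read: PreparedRead | None = None


def _best_window(scores: np.ndarray) -> tuple[int, int, float]:
    """Maximal-sum contiguous window of ``scores``.

    Returns (start, end_exclusive, total).  Ties are broken toward the
    earliest end, then the earliest start; the brute-force oracle in the
    test suite applies the same rule independently.
    """
    n = len(scores)
    pref = np.concatenate(([0.0], np.cumsum(scores)))
    mins = np.minimum.accumulate(pref[:-1])  # min of pref[0..e]
    # earliest index attaining the running minimum (strict improvements only)
    strict_new = pref[:-1] < np.concatenate(([np.inf], mins[:-1]))
    start_idx = np.maximum.accumulate(np.where(strict_new, np.arange(n), -1))
    sums = pref[1:] - mins
    e = int(np.argmax(sums))  # first occurrence -> earliest end
    return int(start_idx[e]), e + 1, float(sums[e])


def quality_trim(
    read: SequencedRead, limit: float = 0.05, max_ambiguities: int = 0
) -> SequencedRead | None:
    """Modified-Mott quality trimming.

    Each base scores ``limit - 10**(-Q/10)``; the retained subread is the
    contiguous window maximizing the score sum (empty when every window is
    non-positive).  Returns ``None`` (rejection) when the window is empty or
    the trimmed sequence still contains more than ``max_ambiguities`` N
    bases.  Idempotent: trimming a trimmed read returns it unchanged.
    """
    scores = limit - 10.0 ** (-read.qualities / 10.0)
    start, end, total = _best_window(scores)
    if total <= 0.0:
        return None
    seq = read.sequence[start:end]
    if seq.upper().count("N") > max_ambiguities:
        return None
    if start == 0 and end == len(read.sequence):
        return read
    return SequencedRead(
        read.id, seq, read.quality_string[start:end], read.mate
    )


def strip_barcode(
    sequence: str, cfg: PrepConfig
) -> tuple[str, str] | PrepStatus:
    """Locate the anchor and return everything strictly 3' of it.

    Searches the sequence as given and, if configured, its reverse
    complement; the first orientation with a hit wins (forward first) and
    within an orientation the leftmost occurrence wins.  Returns
    ``(downstream_sequence, orientation)`` on success, otherwise the
    rejecting :class:`PrepStatus`.
    """
    anchor = canonical(cfg.anchor)
    searched = canonical(sequence)
    orientation = "forward"
    pos = searched.find(anchor)
    if pos < 0 and cfg.search_both_orientations:
        searched = reverse_complement(searched, "DNA")
        orientation = "reverse"
        pos = searched.find(anchor)
    if pos < 0:
        return PrepStatus.NO_ANCHOR
    downstream = searched[pos + len(anchor) :]
    # ligation can produce barcode concatemers: consume consecutive anchors so
    # the returned fragment never begins with one
    while downstream.startswith(anchor):
        downstream = downstream[len(anchor) :]
    if len(downstream) < cfg.min_length_after_trim:
        return PrepStatus.TOO_SHORT
    return downstream, orientation


def prepare_read(read: SequencedRead, cfg: PrepConfig) -> PrepResult:
    """Quality-trim, ambiguity-filter, anchor-strip and length-filter one read."""
    trimmed = quality_trim(read, cfg.quality_limit, cfg.max_ambiguities)
    if trimmed is None:
        # distinguish empty-after-trim from ambiguity rejection for the report
        scores = cfg.quality_limit - 10.0 ** (-read.qualities / 10.0)
        _, _, total = _best_window(scores)
        status = PrepStatus.LOW_QUALITY if total <= 0 else PrepStatus.TOO_MANY_N
        return PrepResult(status)
    stripped = strip_barcode(trimmed.sequence, cfg)
    if isinstance(stripped, PrepStatus):
        return PrepResult(stripped)
    downstream, orientation = stripped
    return PrepResult(
        PrepStatus.OK, PreparedRead(read.id, downstream, orientation)
    )


@dataclass
class PrepReport:
    """Per-run tally of preparation outcomes (weighted by read multiplicity)."""

    input: int = 0
    quality_rejected: int = 0
    ambiguity_rejected: int = 0
    no_anchor: int = 0
    too_short: int = 0
    surviving: int = 0

    _STATUS_FIELD = {
        PrepStatus.LOW_QUALITY: "quality_rejected",
        PrepStatus.TOO_MANY_N: "ambiguity_rejected",
        PrepStatus.NO_ANCHOR: "no_anchor",
        PrepStatus.TOO_SHORT: "too_short",
        PrepStatus.OK: "surviving",
    }

    def add(self, status: PrepStatus, weight: int = 1) -> None:
        self.input += weight
        name = self._STATUS_FIELD[status]
        setattr(self, name, getattr(self, name) + weight)

    def to_tsv(self) -> str:
        lines = ["category\tcount"]
        for name in (
            "input",
            "quality_rejected",
            "ambiguity_rejected",
            "no_anchor",
            "too_short",
            "surviving",
        ):
            lines.append(f"{name}\t{getattr(self, name)}")
        return "\n".join(lines) + "\n"


def prepare_stream(
    reads: Iterable[SequencedRead],
    cfg: PrepConfig,
    report: PrepReport | None = None,
) -> Iterator[PreparedRead]:
    """Prepare a stream of reads, yielding survivors and tallying a report."""
    if report is None:
        report = PrepReport()
    for read in reads:
        result = prepare_read(read, cfg)
        report.add(result.status)
        if result.read is not None:
            yield result.read
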