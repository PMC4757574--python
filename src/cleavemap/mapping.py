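"""Exact mapping of prepared fragments and coverage/RCI profile construction.

Prepared fragments must match a reference substring over their full length
with zero mismatches or indels (length and similarity fractions of one).
Fragments matching more than one location — across or within references —
are *multimapped* and excluded from coverage, a deterministic and
conservative choice for a step-detection statistic (the substrates' shared
poly(A) tails are the main source of multimapping).

The relative coverage increase (RCI) at position n is
``coverage[n] / coverage[n-1]``; a large value means many reads begin at n,
i.e. n is a candidate cleavage-derived 5' end.  RCI is undefined (NaN)
where the preceding position has zero coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Mapping, PreparedRead, ReferenceSet, canonical

__all__ = [
    "MapResult",
    "MappingSummary",
    "CoverageProfile",
    "find_occurrences",
    "map_exact",
    "build_profiles",
    "profiles_to_frame",
]


class IntegrityError(RuntimeError):
    """A mapping lies outside its reference: indicates an upstream bug."""


def find_occurrences(
    query: str, refs: ReferenceSet, limit: int | None = None
) -> list[tuple[str, int]]:
    """All (ref_id, start) exact occurrences of ``query`` (canonical T-alphabet).

    Stops early once ``limit`` occurrences are found.
    """
    q = canonical(query)
    hits: list[tuple[str, int]] = []
    for ref in refs:
        s = refs.canonical_sequence(ref.id)
        pos = s.find(q)
        while pos != -1:
            hits.append((ref.id, pos))
            if limit is not None and len(hits) >= limit:
                return hits
            pos = s.find(q, pos + 1)
    return hits


@dataclass(frozen=True)
class MapResult:
    status: str  # "mapped" | "unmapped" | "multimapped"
    mapping: Mapping | None = None


def map_exact(fragment: PreparedRead, refs: ReferenceSet) -> MapResult:
    """Classify a fragment as mapped (unique exact hit), unmapped or multimapped."""
    hits = find_occurrences(fragment.sequence, refs, limit=2)
    if not hits:
        return MapResult("unmapped")
    if len(hits) > 1:
        return MapResult("multimapped")
    ref_id, start = hits[0]
    return MapResult(
        "mapped", Mapping(fragment.id, ref_id, start, len(fragment.sequence))
    )


@dataclass
class MappingSummary:
    total: int = 0
    mapped: int = 0
    unmapped: int = 0
    multimapped: int = 0

    def add(self, status: str, weight: int = 1) -> None:
        self.total += weight
        setattr(self, status, getattr(self, status) + weight)

    @property
    def percent_mapped(self) -> float:
        return 100.0 * self.mapped / self.total if self.total else 0.0

    def to_tsv(self) -> str:
        return (
            "total\tmapped\tunmapped\tmultimapped\tpercent_mapped\n"
            f"{self.total}\t{self.mapped}\t{self.unmapped}\t"
            f"{self.multimapped}\t{self.percent_mapped:.2f}\n"
        )


@dataclass
class CoverageProfile:
    """Per-position depth, 5'-start events and relative coverage increase."""

    ref_id: str
    coverage: np.ndarray  # int, length == reference length
    start_counts: np.ndarray  # int, 5'-start events per position

    @property
    def rci(self) -> np.ndarray:
        """rci[n] = coverage[n] / coverage[n-1]; NaN where undefined.

        Undefined at n = 0 and wherever coverage[n-1] == 0 (no pseudocounts:
        such positions can never become candidates).
        """
        out = np.full(len(self.coverage), np.nan)
        prev = self.coverage[:-1].astype(float)
        ok = prev > 0
        out[1:][ok] = self.coverage[1:][ok] / prev[ok]
        return out

    def __len__(self) -> int:
        return len(self.coverage)


def build_profiles(
    mappings: Iterable[Mapping],
    refs: ReferenceSet,
    weights: Sequence[int] | None = None,
) -> dict[str, CoverageProfile]:
    """Accumulate coverage and start counts per reference from mappings.

    ``weights`` gives a multiplicity per mapping (default 1 each); the sum
    of coverage over all profiles equals the weighted sum of mapped
    fragment lengths.
    """
    diff = {r.id: np.zeros(len(r) + 1, dtype=np.int64) for r in refs}
    starts = {r.id: np.zeros(len(r), dtype=np.int64) for r in refs}
    for i, m in enumerate(mappings):
        w = 1 if weights is None else int(weights[i])
        ref_len = len(refs.get(m.ref_id))
        if m.start < 0 or m.start + m.length > ref_len:
            raise IntegrityError(
                f"mapping of {m.read_id!r} at {m.ref_id}:{m.start}+{m.length} "
                f"exceeds reference length {ref_len}"
            )
        diff[m.ref_id][m.start] += w
        diff[m.ref_id][m.start + m.length] -= w
        starts[m.ref_id][m.start] += w
    return {
        rid: CoverageProfile(rid, np.cumsum(d[:-1]), starts[rid])
        for rid, d in diff.items()
    }


def profiles_to_frame(profiles: dict[str, CoverageProfile]) -> pd.DataFrame:
    """Long-format per-position table; positions reported 1-based inclusive."""
    frames = []
    for rid, prof in profiles.items():
        rci = prof.rci
        frames.append(
            pd.DataFrame(
                {
                    "ref_id": rid,
                    "pos_1based": np.arange(1, len(prof) + 1),
                    "coverage": prof.coverage,
                    "starts": prof.start_counts,
                    "rci_or_NA": [
                        "NA" if np.isnan(v) else f"{v:.6g}" for v in rci
                    ],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
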