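"""Substrate k-mer diversity and motif-free transcript scanning.

A cleavage motif can only be detected if the substrate pool contains it;
k-mer saturation (the fraction of the 4**k possible words present) bounds
the recognition-site lengths an assay built on a given substrate set can
resolve.  Counting is forward-strand only: the enzymes act on
single-stranded RNA as synthesized.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .io import ReferenceSet, canonical

__all__ = [
    "KmerCoverageReport",
    "kmer_coverage",
    "occurrence_table",
    "MotifFreeReport",
    "motif_free_sequences",
]


@dataclass
class KmerCoverageReport:
    """Distinct k-mers observed in a sequence set versus the 4**k possible."""

    k: int
    distinct_observed: int
    possible: int
    per_sequence_counts: dict[str, Counter]  # ref_id -> kmer -> occurrences

    @property
    def percent(self) -> float:
        return 100.0 * self.distinct_observed / self.possible

    @property
    def percent_display(self) -> float:
        """Percent rounded to one decimal, as printed in reports."""
        return round(self.percent, 1)

    def summary_row(self) -> dict:
        return {
            "k": self.k,
            "distinct_observed": self.distinct_observed,
            "possible": self.possible,
            "percent": self.percent_display,
        }


def _display_kmer(kmer: str, rna: bool) -> str:
    return kmer.replace("T", "U") if rna else kmer


def kmer_coverage(refs: ReferenceSet, k: int) -> KmerCoverageReport:
    """Count every overlapping k-mer of every sequence (forward strand).

    k-mers are reported in the set's own alphabet (U for RNA).  Raises
    ``ValueError`` when k exceeds the length of every sequence.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if all(len(r) < k for r in refs):
        raise ValueError(
            f"k={k} is longer than every sequence in the set"
        )
    rna = refs.alphabet == "RNA"
    per_seq: dict[str, Counter] = {}
    observed: set[str] = set()
    for ref in refs:
        seq = canonical(ref.sequence)
        counts: Counter = Counter(
            seq[i : i + k] for i in range(len(seq) - k + 1)
        )
        per_seq[ref.id] = Counter(
            {_display_kmer(km, rna): n for km, n in counts.items()}
        )
        observed.update(counts)
    return KmerCoverageReport(
        k=k,
        distinct_observed=len(observed),
        possible=4**k,
        per_sequence_counts=per_seq,
    )


def occurrence_table(report: KmerCoverageReport) -> pd.DataFrame:
    """k-mer x sequence occurrence table (rows: observed k-mers, sorted)."""
    df = pd.DataFrame(report.per_sequence_counts).fillna(0).astype(int)
    df = df.sort_index()
    df.index.name = f"{report.k}mer"
    df["total"] = df.sum(axis=1)
    return df


@dataclass
class MotifFreeReport:
    motif: str
    n_sequences: int
    free_ids: list[str]

    @property
    def n_free(self) -> int:
        return len(self.free_ids)


def motif_free_sequences(
    transcripts: ReferenceSet, motif: str
) -> MotifFreeReport:
    """Ids of sequences containing zero occurrences of ``motif`` (exact,
    canonical alphabet), plus summary counts."""
    if not motif:
        raise ValueError("motif must be non-empty")
    if len(transcripts) == 0:
        raise ValueError("transcript set is empty")
    needle = canonical(motif)
    free = [
        ref.id
        for ref in transcripts
        if needle not in transcripts.canonical_sequence(ref.id)
    ]
    return MotifFreeReport(motif=motif, n_sequences=len(transcripts), free_ids=free)
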