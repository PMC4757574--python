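"""Generative model of the digestion / barcode-ligation / sequencing protocol.

A pool of synthetic substrate molecules (GGG head + near-uniform diverse
region + poly(A) tail) is digested by a sequence-specific endoribonuclease:
every motif occurrence is cut, independently per molecule, with probability
``p_cleave`` at a fixed offset inside the motif, and every internucleotide
bond additionally breaks with a small background probability.  Each
resulting fragment receives the 45-nt barcode at its 5' end with
probability ``ligation_efficiency`` (the kinase step is modelled as always
successful).  Read pairs are then drawn uniformly from the fragment pool:
R1 is the first ``read_length`` bases of the (possibly barcoded) fragment
and R2 the reverse complement of its last ``read_length`` bases, with
uniform Q36 qualities and an optional per-base substitution error rate.

Every randomized event is recorded, so downstream metrics are checkable
against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from .io import (
    Reference,
    ReferenceSet,
    SequencedRead,
    canonical,
    format_fastq_record,
    reverse_complement,
    write_fasta,
)
from .prep import DEFAULT_ANCHOR

__all__ = [
    "DEFAULT_BARCODE",
    "SimulationConfig",
    "nonspecific_control_config",
    "CleavageSite",
    "Fragment",
    "Library",
    "SimulationResult",
    "generate_references",
    "digest_molecule",
    "digest",
    "make_library",
    "simulate_library",
]

# 45-nt barcode whose 3'-terminal 15 nt are the anchor (DNA alphabet, as read
# by the sequencer)
DEFAULT_BARCODE = "GCTGATGGCGATGAATGAACACTGCGTTTG" + DEFAULT_ANCHOR

_Q36_CHAR = chr(36 + 33)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated digestion/sequencing experiment.

    ``motif=None`` models a sequence-nonspecific digestion (negative
    control); see :func:`nonspecific_control_config`.  ``cut_offset`` is the
    index within the motif before which the cut falls (0 = 5' of the first
    motif base, 1 = between bases 0 and 1).  ``n_molecules`` is the number
    of substrate copies digested per reference; digestion is stochastic per
    molecule, which is what yields partial-digest fragment diversity.
    """

    n_refs: int = 5
    ref_length: int = 1000
    head: str = "GGG"
    tail_length: int = 30
    motif: str | None = "ACA"
    cut_offset: int = 0
    p_cleave: float = 0.9
    background_break_rate: float = 1e-4
    ligation_efficiency: float = 0.1
    barcode: str = DEFAULT_BARCODE
    read_length: int = 250
    n_read_pairs: int = 750_000
    n_molecules: int = 1000
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_cleave", "background_break_rate", "ligation_efficiency", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.motif is not None and not (0 <= self.cut_offset < len(self.motif)):
            raise ValueError("cut_offset must lie within the motif")
        if len(self.barcode) < 15:
            raise ValueError("barcode must be at least 15 nt")
        if self.n_refs < 1 or self.ref_length < 1:
            raise ValueError("need at least one reference of positive length")

    @property
    def anchor(self) -> str:
        """The 3'-terminal 15 nt of the barcode, searched for during prep."""
        return canonical(self.barcode)[-15:]

    @property
    def reference_length(self) -> int:
        return len(self.head) + self.ref_length + self.tail_length


def nonspecific_control_config(**overrides) -> SimulationConfig:
    """Configuration emulating a sequence-nonspecific nuclease digest.

    No motif-directed cleavage; the background break rate is raised to 0.01
    per bond (~10 breaks per 1033-nt molecule) so the substrates fragment on
    the same scale as in a motif-directed digest.
    """
    params: dict = {"motif": None, "background_break_rate": 0.01}
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass(frozen=True)
class CleavageSite:
    """Ground truth: one motif occurrence with its cut coordinate."""

    ref_id: str
    motif_start: int  # 0-based
    cut_pos: int  # bond index: cut falls 5' of this reference position


@dataclass(frozen=True)
class Fragment:
    """A maximal uncut interval of one digested molecule."""

    ref_id: str
    start: int
    end: int  # exclusive
    five_prime_is_cleavage: bool

    def __len__(self) -> int:
        return self.end - self.start


def generate_references(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[ReferenceSet, list[CleavageSite]]:
    """Draw diverse regions uniformly over {A,C,G,U}, append head/tail, and
    record every motif occurrence with its cut coordinate.

    Regions are redrawn in the (practically impossible at these lengths)
    event that any ``read_length``-mer repeats within or across references,
    which would create avoidable multimapping outside the poly(A) tail.
    """
    bases = np.array(list("ACGU"))
    refs: list[Reference] = []
    seen_windows: set[str] = set()
    k = cfg.read_length
    for i in range(cfg.n_refs):
        for _attempt in range(50):
            body = "".join(rng.choice(bases, size=cfg.ref_length))
            seq = cfg.head + body + "A" * cfg.tail_length
            windows = {seq[j : j + k] for j in range(max(1, len(seq) - k + 1))}
            if seen_windows & windows and len(seq) > k:
                continue
            seen_windows |= windows
            refs.append(Reference(f"synthetic-{i + 1}", seq))
            break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not generate repeat-free references")
    refset = ReferenceSet(refs, alphabet="RNA")

    sites: list[CleavageSite] = []
    if cfg.motif is not None:
        needle = canonical(cfg.motif)
        for ref in refset:
            s = refset.canonical_sequence(ref.id)
            pos = s.find(needle)
            while pos != -1:
                cut = pos + cfg.cut_offset
                if 0 < cut < len(s):  # a cut at either end severs nothing
                    sites.append(CleavageSite(ref.id, pos, cut))
                pos = s.find(needle, pos + 1)  # overlapping occurrences count
    return refset, sites


def digest_molecule(
    ref: Reference,
    site_cuts: list[int],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[Fragment]:
    """Digest a single molecule: motif cuts with ``p_cleave`` each, plus
    background breaks at ``background_break_rate`` per bond.

    The returned fragments tile the molecule exactly (sequence is
    conserved).  ``five_prime_is_cleavage`` marks fragments whose 5' end
    arises from a motif-directed cut.
    """
    L = len(ref)
    motif_cuts: set[int] = set()
    if site_cuts:
        chosen = np.asarray(site_cuts)[rng.random(len(site_cuts)) < cfg.p_cleave]
        motif_cuts = {int(c) for c in chosen}
    background: set[int] = set()
    if cfg.background_break_rate > 0 and L > 1:
        k = rng.binomial(L - 1, cfg.background_break_rate)
        if k:
            background = {
                int(b) for b in rng.choice(np.arange(1, L), size=k, replace=False)
            }
    bounds = [0, *sorted(motif_cuts | background), L]
    return [
        Fragment(ref.id, a, b, a in motif_cuts)
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def digest(
    refs: ReferenceSet,
    sites: list[CleavageSite],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[Fragment]:
    """Digest ``cfg.n_molecules`` copies of every reference."""
    cuts_by_ref: dict[str, list[int]] = {r.id: [] for r in refs}
    for site in sites:
        cuts_by_ref[site.ref_id].append(site.cut_pos)
    fragments: list[Fragment] = []
    for ref in refs:
        cuts = sorted(set(cuts_by_ref[ref.id]))
        for _ in range(cfg.n_molecules):
            fragments.extend(digest_molecule(ref, cuts, cfg, rng))
    return fragments


@dataclass
class Library:
    """A sequencing-ready library: fragments, ligation outcomes, and the
    sampled read pairs, with lazy read materialization."""

    refs: ReferenceSet
    fragments: list[Fragment]
    cfg: SimulationConfig
    barcoded: np.ndarray  # bool per fragment
    sample: np.ndarray  # fragment index per read pair
    error_seed: int | None = None
    _seq_cache: dict[int, str] = field(default_factory=dict, repr=False)

    # -- read construction ------------------------------------------------

    def _full_sequence(self, frag_idx: int) -> str:
        seq = self._seq_cache.get(frag_idx)
        if seq is None:
            frag = self.fragments[frag_idx]
            seq = self.refs.canonical_sequence(frag.ref_id)[frag.start : frag.end]
            if self.barcoded[frag_idx]:
                seq = canonical(self.cfg.barcode) + seq
            self._seq_cache[frag_idx] = seq
        return seq

    def _pair_sequences(self, frag_idx: int) -> tuple[str, str]:
        full = self._full_sequence(frag_idx)
        r1 = full[: self.cfg.read_length]
        r2 = reverse_complement(full[-self.cfg.read_length :], "DNA")
        return r1, r2

    def iter_pairs(self) -> Iterator[tuple[SequencedRead, SequencedRead, int]]:
        """Yield (R1, R2, fragment_index) per sampled pair, in sampling order.

        Deterministic for a fixed configuration, including sequencing
        errors (the error stream has its own seed).
        """
        err_rng = (
            np.random.default_rng(self.error_seed)
            if self.cfg.error_rate > 0
            else None
        )
        for n, frag_idx in enumerate(self.sample):
            r1, r2 = self._pair_sequences(int(frag_idx))
            if err_rng is not None:
                r1 = _apply_errors(r1, self.cfg.error_rate, err_rng)
                r2 = _apply_errors(r2, self.cfg.error_rate, err_rng)
            yield (
                SequencedRead(f"sim.{n}/1", r1, _Q36_CHAR * len(r1), 1),
                SequencedRead(f"sim.{n}/2", r2, _Q36_CHAR * len(r2), 2),
                int(frag_idx),
            )

    def aggregated_pairs(self) -> list[tuple[SequencedRead, SequencedRead, int]]:
        """Read pairs grouped by identical (fragment interval, barcode) type,
        as (R1, R2, multiplicity).  Only valid without sequencing errors."""
        if self.cfg.error_rate > 0:
            raise ValueError(
                "aggregation is only exact at error_rate 0; use iter_pairs()"
            )
        ref_index = {r.id: i for i, r in enumerate(self.refs)}
        rows = np.empty((len(self.sample), 4), dtype=np.int64)
        for col, getter in enumerate(
            (
                lambda f: ref_index[f.ref_id],
                lambda f: f.start,
                lambda f: f.end,
                None,
            )
        ):
            if getter is not None:
                values = np.fromiter(
                    (getter(f) for f in self.fragments),
                    dtype=np.int64,
                    count=len(self.fragments),
                )
                rows[:, col] = values[self.sample]
        rows[:, 3] = self.barcoded[self.sample]
        uniq, first_idx, counts = np.unique(
            rows, axis=0, return_index=True, return_counts=True
        )
        out = []
        for (ref_i, start, end, bc), idx, count in zip(uniq, first_idx, counts):
            frag_idx = int(self.sample[idx])
            r1, r2 = self._pair_sequences(frag_idx)
            rid = f"type.{ref_i}.{start}.{end}.{bc}"
            out.append(
                (
                    SequencedRead(f"{rid}/1", r1, _Q36_CHAR * len(r1), 1),
                    SequencedRead(f"{rid}/2", r2, _Q36_CHAR * len(r2), 2),
                    int(count),
                )
            )
        return out

    # -- persistence -------------------------------------------------------

    def write(self, out_dir: str | Path, gzip_out: bool = False) -> dict[str, Path]:
        """Write R1/R2 FASTQ, references FASTA, ground-truth TSVs and the
        resolved configuration; returns the path of every artifact."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        suffix = ".fastq.gz" if gzip_out else ".fastq"
        paths = {
            "r1": out / f"reads_R1{suffix}",
            "r2": out / f"reads_R2{suffix}",
            "references": out / "references.fasta",
            "truth": out / "truth.tsv",
            "config": out / "simulation_config.yaml",
        }
        import gzip as _gzip

        opener = (lambda p: _gzip.open(p, "wt")) if gzip_out else (lambda p: open(p, "wt"))
        with opener(paths["r1"]) as f1, opener(paths["r2"]) as f2, open(
            paths["truth"], "wt"
        ) as ft:
            ft.write(
                "# fragment coordinates are 0-based half-open\n"
                "read_pair\tref_id\tfrag_start\tfrag_end\tbarcoded\t"
                "five_prime_is_cleavage\n"
            )
            for r1, r2, frag_idx in self.iter_pairs():
                f1.write(format_fastq_record(r1))
                f2.write(format_fastq_record(r2))
                frag = self.fragments[frag_idx]
                ft.write(
                    f"{r1.id[:-2]}\t{frag.ref_id}\t{frag.start}\t{frag.end}\t"
                    f"{int(self.barcoded[frag_idx])}\t"
                    f"{int(frag.five_prime_is_cleavage)}\n"
                )
        write_fasta(self.refs, paths["references"])
        with open(paths["config"], "wt") as fc:
            yaml.safe_dump(dataclasses.asdict(self.cfg), fc, sort_keys=True)
        return paths


def make_library(
    refs: ReferenceSet,
    fragments: list[Fragment],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> Library:
    """Ligate barcodes (per fragment, probability ``ligation_efficiency``)
    and sample ``n_read_pairs`` pairs uniformly from the fragment pool."""
    barcoded = rng.random(len(fragments)) < cfg.ligation_efficiency
    sample = rng.integers(0, len(fragments), size=cfg.n_read_pairs)
    error_seed = int(rng.integers(2**31)) if cfg.error_rate > 0 else None
    return Library(refs, fragments, cfg, barcoded, sample, error_seed)


@dataclass
class SimulationResult:
    refs: ReferenceSet
    sites: list[CleavageSite]
    library: Library


def simulate_library(cfg: SimulationConfig) -> SimulationResult:
    """Run the full generative model from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    refs, sites = generate_references(cfg, rng)
    fragments = digest(refs, sites, cfg, rng)
    if not fragments:
        raise RuntimeError("digestion produced no fragments")
    library = make_library(refs, fragments, cfg, rng)
    return SimulationResult(refs, sites, library)


_OTHER_BASES = {
    "A": "CGT",
    "C": "AGT",
    "G": "ACT",
    "T": "ACG",
    "N": "ACGT",
}


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    flips = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(flips) == 0:
        return seq
    chars = list(seq)
    for i in flips:
        alternatives = _OTHER_BASES.get(chars[i], "ACGT")
        chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)
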