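"""End-to-end orchestration: prep -> map -> profiles -> candidates -> motif.

Two entry points share the same stage code: :func:`run_pipeline` consumes
FASTQ/FASTA files and writes every stage artifact, while
:func:`analyze_weighted_reads` consumes in-memory (read, multiplicity)
pairs — the form the simulator produces — without touching the filesystem.
Read preparation and mapping are memoized per distinct (sequence, quality)
pair, which is exact: identical inputs yield identical outcomes.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .io import Mapping, ReferenceSet, SequencedRead, read_fasta, read_fastq
from .mapping import (
    CoverageProfile,
    MappingSummary,
    MapResult,
    build_profiles,
    map_exact,
    profiles_to_frame,
)
from .prep import PrepConfig, PrepReport, PrepResult, prepare_read
from .simulate import SimulationConfig, SimulationResult, simulate_library
from .sites import (
    CleavageCandidate,
    MotifModel,
    SiteCallConfig,
    build_motif,
    call_candidates,
    candidates_to_frame,
    export_logo,
    export_pfm,
)

__all__ = [
    "PipelineError",
    "PipelineResult",
    "analyze_weighted_reads",
    "run_pipeline",
    "run_simulated",
]

logger = logging.getLogger(__name__)

LOG_EVERY = 100_000


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineResult:
    prep_report: PrepReport
    map_summary: MappingSummary
    profiles: dict[str, CoverageProfile]
    candidates: list[CleavageCandidate]
    motif: MotifModel | None

    @property
    def report_line(self) -> str:
        if self.motif is None:
            return "no candidate cleavage positions"
        return self.motif.report_line()

    def summary_dict(self) -> dict:
        return {
            "prep": {
                "input": self.prep_report.input,
                "surviving": self.prep_report.surviving,
            },
            "mapping": {
                "total": self.map_summary.total,
                "mapped": self.map_summary.mapped,
                "percent_mapped": round(self.map_summary.percent_mapped, 2),
            },
            "candidates": len(self.candidates),
            "motif": None if self.motif is None else self.motif.motif,
            "report": self.report_line,
        }


def analyze_weighted_reads(
    weighted_reads: Iterable[tuple[SequencedRead, int]],
    refs: ReferenceSet,
    prep_cfg: PrepConfig | None = None,
    site_cfg: SiteCallConfig | None = None,
) -> PipelineResult:
    """Run every analysis stage over (read, multiplicity) pairs.

    Raises :class:`PipelineError` when the input contains zero reads.
    """
    prep_cfg = prep_cfg or PrepConfig()
    site_cfg = site_cfg or SiteCallConfig()

    prep_cache: dict[tuple[str, str], PrepResult] = {}
    map_cache: dict[str, MapResult] = {}
    report = PrepReport()
    summary = MappingSummary()
    mappings: list[Mapping] = []
    weights: list[int] = []
    seen = 0
    for read, weight in weighted_reads:
        seen += weight
        if seen // LOG_EVERY != (seen - weight) // LOG_EVERY:
            logger.info("processed %d reads", seen)
        key = (read.sequence, read.quality_string)
        prep = prep_cache.get(key)
        if prep is None:
            prep = prepare_read(read, prep_cfg)
            prep_cache[key] = prep
        report.add(prep.status, weight)
        if prep.read is None:
            continue
        mres = map_cache.get(prep.read.sequence)
        if mres is None:
            mres = map_exact(prep.read, refs)
            map_cache[prep.read.sequence] = mres
        summary.add(mres.status, weight)
        if mres.mapping is not None:
            mappings.append(mres.mapping)
            weights.append(weight)
    if seen == 0:
        raise PipelineError("input contains zero reads")

    profiles = build_profiles(mappings, refs, weights)
    rna = refs.alphabet == "RNA"
    candidates: list[CleavageCandidate] = []
    for ref in refs:
        candidates.extend(
            call_candidates(profiles[ref.id], ref, site_cfg, rna=rna)
        )
    motif = build_motif(candidates, site_cfg.flank) if candidates else None
    return PipelineResult(report, summary, profiles, candidates, motif)


def _weighted_from_files(
    r1: str | Path, r2: str | Path | None
) -> Iterator[tuple[SequencedRead, int]]:
    streams = [read_fastq(r1, mate=1)]
    if r2 is not None:
        streams.append(read_fastq(r2, mate=2))
    for read in itertools.chain(*streams):
        yield read, 1


def run_pipeline(
    r1: str | Path,
    refs_path: str | Path,
    out_dir: str | Path,
    r2: str | Path | None = None,
    prep_cfg: PrepConfig | None = None,
    site_cfg: SiteCallConfig | None = None,
) -> PipelineResult:
    """File-based pipeline run; writes every stage artifact to ``out_dir``.

    R1 and R2 are processed independently through the identical path and
    their surviving fragments pooled.
    """
    refs = read_fasta(refs_path)
    result = analyze_weighted_reads(
        _weighted_from_files(r1, r2), refs, prep_cfg, site_cfg
    )
    write_artifacts(result, Path(out_dir))
    return result


def write_artifacts(result: PipelineResult, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "prep_report": out_dir / "prep_report.tsv",
        "mapping_summary": out_dir / "mapping_summary.tsv",
        "coverage": out_dir / "coverage.tsv",
        "candidates": out_dir / "candidates.tsv",
        "summary": out_dir / "summary.json",
        "motif_report": out_dir / "motif.txt",
    }
    paths["prep_report"].write_text(result.prep_report.to_tsv())
    paths["mapping_summary"].write_text(result.map_summary.to_tsv())
    with open(paths["coverage"], "wt") as fh:
        fh.write("# positions are 1-based inclusive\n")
        profiles_to_frame(result.profiles).to_csv(fh, sep="\t", index=False)
    with open(paths["candidates"], "wt") as fh:
        fh.write("# zero positions are 1-based inclusive\n")
        candidates_to_frame(result.candidates).to_csv(fh, sep="\t", index=False)
    if result.motif is not None:
        paths["pfm"] = out_dir / "pfm.tsv"
        export_pfm(result.motif, paths["pfm"])
        paths["logo"] = out_dir / "logo.png"
        export_logo(result.motif, paths["logo"])
    paths["motif_report"].write_text(result.report_line + "\n")
    paths["summary"].write_text(
        json.dumps(result.summary_dict(), indent=2) + "\n"
    )
    return paths


def _weighted_from_simulation(sim: SimulationResult) -> Iterator[tuple[SequencedRead, int]]:
    if sim.library.cfg.error_rate > 0:
        for r1, r2, _ in sim.library.iter_pairs():
            yield r1, 1
            yield r2, 1
    else:
        for r1, r2, count in sim.library.aggregated_pairs():
            yield r1, count
            yield r2, count


def run_simulated(
    sim_cfg: SimulationConfig,
    prep_cfg: PrepConfig | None = None,
    site_cfg: SiteCallConfig | None = None,
) -> tuple[PipelineResult, SimulationResult]:
    """Simulate a library and analyze it fully in memory."""
    sim = simulate_library(sim_cfg)
    if prep_cfg is None:
        prep_cfg = PrepConfig(anchor=sim_cfg.anchor)
    result = analyze_weighted_reads(
        _weighted_from_simulation(sim), sim.refs, prep_cfg, site_cfg
    )
    return result, sim
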