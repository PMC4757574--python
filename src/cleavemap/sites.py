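"""Cleavage-candidate calling, motif construction, and logo export.

A candidate is a reference position n where coverage steps up sharply:
coverage[n] exceeds the depth threshold and the relative coverage increase
rci[n] = coverage[n] / coverage[n-1] ranks among the top k in its
reference.  The candidate position is numbered zero; the enzymatic cut
falls between positions -1 and 0.  Windows of ``flank`` bases either side
of zero from all references are stacked into a position frequency matrix,
and per-column information content (2 + sum_b f_b log2 f_b, in bits)
identifies conserved positions.

The consensus rule: a column is *called* when its information content is at
least ``ic_min`` bits and the modal base frequency is at least
``modal_min``; the reported motif is the maximal contiguous run of called
columns containing position 0 (or position -1 when 0 is uncalled).  When no
such run exists the model reports "no conserved motif".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Reference
from .mapping import CoverageProfile

__all__ = [
    "SiteCallConfig",
    "CleavageCandidate",
    "MotifModel",
    "call_candidates",
    "build_motif",
    "export_pfm",
    "load_pfm",
    "export_logo",
    "candidates_to_frame",
]

logger = logging.getLogger(__name__)

_RNA_ROWS = "ACGU"


@dataclass(frozen=True)
class SiteCallConfig:
    """Candidate-calling parameters.

    min_coverage: depth the zero position itself must exceed (strictly, by
    default) for a step to be trusted.  top_k_per_ref: candidates kept per
    reference after ranking by RCI.  flank: bases extracted either side of
    the zero position.
    """

    min_coverage: int = 1000
    top_k_per_ref: int = 5
    flank: int = 5
    strict_coverage: bool = True  # coverage > min_coverage (vs >=)

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.top_k_per_ref < 1:
            raise ValueError("top_k_per_ref must be >= 1")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass(frozen=True)
class CleavageCandidate:
    """A zero position with its step statistics and sequence window.

    ``window`` has length 2*flank + 1 with the zero-position base at index
    ``flank``; N marks positions overhanging a reference edge.
    """

    ref_id: str
    zero_pos: int  # 0-based reference position of the coverage step
    rci_value: float
    coverage_at_zero: int
    window: str


def _extract_window(sequence: str, pos: int, flank: int, rna: bool) -> str:
    lo, hi = pos - flank, pos + flank + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(sequence))
    core = sequence[max(0, lo) : min(len(sequence), hi)].upper()
    core = core.replace("T", "U") if rna else core
    return "N" * left_pad + core + "N" * right_pad


def call_candidates(
    profile: CoverageProfile,
    reference: Reference,
    cfg: SiteCallConfig,
    rna: bool = True,
) -> list[CleavageCandidate]:
    """Top-k coverage-step candidates for one reference.

    Filter first (rci defined, coverage above threshold at the zero
    position), then rank by rci descending; ties broken by larger coverage
    at zero, then smaller position.
    """
    cov = profile.coverage
    rci = profile.rci
    if cfg.strict_coverage:
        deep = cov > cfg.min_coverage
    else:
        deep = cov >= cfg.min_coverage
    qualifying = np.nonzero(~np.isnan(rci) & deep)[0]
    ranked = sorted(
        (int(n) for n in qualifying),
        key=lambda n: (-rci[n], -int(cov[n]), n),
    )
    top = ranked[: cfg.top_k_per_ref]
    if len(top) < cfg.top_k_per_ref:
        logger.warning(
            "%s: only %d of %d requested candidate positions qualify",
            profile.ref_id,
            len(top),
            cfg.top_k_per_ref,
        )
    return [
        CleavageCandidate(
            ref_id=profile.ref_id,
            zero_pos=n,
            rci_value=float(rci[n]),
            coverage_at_zero=int(cov[n]),
            window=_extract_window(reference.sequence, n, cfg.flank, rna),
        )
        for n in top
    ]


@dataclass
class MotifModel:
    """Position frequency matrix with information content and consensus call.

    Rows follow A, C, G, U; columns are window positions -flank..+flank.
    Information content per column is ``2 + sum_b f_b log2 f_b`` bits with
    frequencies taken over non-N counts (no small-sample correction by
    default; see ``small_sample_correction`` of :func:`build_motif`).  The
    cut site sits between window positions -1 and 0 by construction.
    """

    pfm: np.ndarray  # (4, W) integer counts
    flank: int
    n_windows: int
    ic_min: float = 1.0
    modal_min: float = 0.8
    small_sample_correction: bool = False

    rows: str = _RNA_ROWS

    @property
    def width(self) -> int:
        return self.pfm.shape[1]

    @property
    def column_totals(self) -> np.ndarray:
        return self.pfm.sum(axis=0)

    def frequencies(self) -> np.ndarray:
        totals = self.column_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(totals > 0, self.pfm / totals, 0.0)
        return f

    def information_content(self) -> np.ndarray:
        """Per-column IC in bits; 0 for empty columns."""
        f = self.frequencies()
        with np.errstate(invalid="ignore", divide="ignore"):
            plogp = np.where(f > 0, f * np.log2(f), 0.0)
        ic = 2.0 + plogp.sum(axis=0)
        ic[self.column_totals == 0] = 0.0
        if self.small_sample_correction:
            n = np.maximum(self.column_totals, 1)
            ic = ic - 3.0 / (2.0 * np.log(2) * n)
        return np.clip(ic, 0.0, 2.0)

    def positions(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def called_columns(self) -> np.ndarray:
        ic = self.information_content()
        f = self.frequencies()
        modal = f.max(axis=0)
        return (ic >= self.ic_min) & (modal >= self.modal_min) & (
            self.column_totals > 0
        )

    def _motif_run(self) -> tuple[int, int] | None:
        """Column index range [lo, hi) of the called run containing position
        0, or position -1 when 0 is uncalled; None when neither is called."""
        called = self.called_columns()
        for anchor_col in (self.flank, self.flank - 1):
            if 0 <= anchor_col < self.width and called[anchor_col]:
                lo = anchor_col
                while lo > 0 and called[lo - 1]:
                    lo -= 1
                hi = anchor_col + 1
                while hi < self.width and called[hi]:
                    hi += 1
                return lo, hi
        return None

    @property
    def motif(self) -> str | None:
        """The called motif string (e.g. "ACA"), or None."""
        run = self._motif_run()
        if run is None:
            return None
        modal = np.argmax(self.pfm, axis=0)
        return "".join(self.rows[modal[j]] for j in range(*run))

    @property
    def motif_span(self) -> tuple[int, int] | None:
        """Window positions (inclusive) spanned by the motif, e.g. (-1, 1)."""
        run = self._motif_run()
        if run is None:
            return None
        return run[0] - self.flank, run[1] - 1 - self.flank

    @property
    def consensus(self) -> str:
        """Full-width consensus; uncalled columns render as the middle dot."""
        called = self.called_columns()
        modal = np.argmax(self.pfm, axis=0)
        return "".join(
            self.rows[modal[j]] if called[j] else "·"
            for j in range(self.width)
        )

    def report_line(self) -> str:
        if self.motif is None:
            return f"no conserved motif (support {self.n_windows} windows)"
        lo, hi = self.motif_span
        return (
            f"consensus={self.motif}, span {lo:+d}..{hi:+d}, "
            f"cut between -1 and 0, support {self.n_windows} windows"
        )


def build_motif(
    candidates: list[CleavageCandidate],
    flank: int,
    ic_min: float = 1.0,
    modal_min: float = 0.8,
    small_sample_correction: bool = False,
) -> MotifModel:
    """Stack candidate windows into a PFM-based motif model.

    N columns at reference edges reduce that column's total rather than
    being imputed.  Raises ``ValueError`` on an empty candidate list.
    """
    if not candidates:
        raise ValueError("cannot build a motif from zero candidates")
    width = 2 * flank + 1
    pfm = np.zeros((4, width), dtype=np.int64)
    index = {b: i for i, b in enumerate(_RNA_ROWS)}
    for cand in candidates:
        if len(cand.window) != width:
            raise ValueError(
                f"window {cand.window!r} has length {len(cand.window)}, "
                f"expected {width}"
            )
        for j, base in enumerate(cand.window.upper().replace("T", "U")):
            if base in index:
                pfm[index[base], j] += 1
    return MotifModel(
        pfm=pfm,
        flank=flank,
        n_windows=len(candidates),
        ic_min=ic_min,
        modal_min=modal_min,
        small_sample_correction=small_sample_correction,
    )


def candidates_to_frame(candidates: list[CleavageCandidate]) -> pd.DataFrame:
    """Candidate table; zero positions reported 1-based inclusive."""
    return pd.DataFrame(
        {
            "ref_id": [c.ref_id for c in candidates],
            "zero_pos_1based": [c.zero_pos + 1 for c in candidates],
            "rci": [c.rci_value for c in candidates],
            "coverage": [c.coverage_at_zero for c in candidates],
            "window": [c.window for c in candidates],
        }
    )


def export_pfm(motif: MotifModel, path: str | Path) -> None:
    """Write the PFM as TSV: rows A/C/G/U, columns labelled -flank..+flank."""
    cols = [f"{p:+d}" for p in motif.positions()]
    df = pd.DataFrame(motif.pfm, index=list(motif.rows), columns=cols)
    df.index.name = "base"
    df.to_csv(path, sep="\t")


def load_pfm(path: str | Path) -> np.ndarray:
    """Re-read a PFM written by :func:`export_pfm` (exact round trip)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.loc[list(_RNA_ROWS)].to_numpy(dtype=np.int64)


_LOGO_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728"}


def export_logo(motif: MotifModel, path: str | Path) -> bool:
    """Best-effort information-content sequence logo (PNG/SVG via matplotlib).

    Stack heights are f_b * IC per column.  Returns True when the image was
    written; failures are logged, not raised (the PFM TSV is the contract).
    """
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.font_manager import FontProperties
        from matplotlib.patches import PathPatch
        from matplotlib.textpath import TextPath
        from matplotlib.transforms import Affine2D

        freqs = motif.frequencies()
        ic = motif.information_content()
        fig, ax = plt.subplots(
            figsize=(max(2.5, 0.55 * motif.width + 1.2), 2.8)
        )
        font = FontProperties(family="DejaVu Sans", weight="bold")
        for j in range(motif.width):
            y = 0.0
            order = np.argsort(freqs[:, j])  # smallest at the bottom
            for b in order:
                h = freqs[b, j] * ic[j]
                if h <= 0:
                    continue
                letter = motif.rows[b]
                tp = TextPath((0, 0), letter, size=1.0, prop=font)
                bbox = tp.get_extents()
                transform = (
                    Affine2D()
                    .translate(-bbox.x0, -bbox.y0)
                    .scale(0.9 / bbox.width, h / bbox.height)
                    .translate(j + 0.05, y)
                )
                ax.add_patch(
                    PathPatch(
                        transform.transform_path(tp),
                        facecolor=_LOGO_COLORS.get(letter, "grey"),
                        edgecolor="none",
                    )
                )
                y += h
        ax.set_xlim(-0.2, motif.width + 0.2)
        ax.set_ylim(0, 2.05)
        ax.set_xticks(np.arange(motif.width) + 0.5)
        ax.set_xticklabels([f"{p:+d}" for p in motif.positions()])
        ax.set_ylabel("bits")
        ax.set_xlabel("position relative to cleavage-derived 5' base")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return True
    except Exception:  # pragma: no cover - environment dependent
        logger.exception("sequence-logo rendering failed; PFM TSV still written")
        return False
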