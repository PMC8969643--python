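"""Cell-level QC: removing doublet and diploid cells.

Two filters, applied after the first phasing pass:

- conflict filter: cells whose fraction of both-allele observations
  exceeds ``conflict_rate_max`` are removed as likely diploid (both
  haplotypes present at every covered site);
- breakpoint filter: cells whose haplotype-switch rate across adjacent
  informative bin pairs exceeds ``cell_breakpoint_max`` (default 5%,
  strict >) are removed as non-haploid — a barcode holding two gametes
  shows apparent recombination wherever the gametes' haplotypes differ.

The pipeline is two-pass: phasing and QC on all cells, then a full rerun
with identical parameters on the kept cells only.  Cells are never removed
for low coverage alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import Config
from .ioforms import CellAlleleMatrix
from .phasing import H_NA, ContigPhase

VERDICT_HAPLOID = "haploid"
VERDICT_CONFLICT = "removed_conflict"
VERDICT_BREAKPOINT = "removed_breakpoint"


def conflict_filter(
    matrix: CellAlleleMatrix, conflict_rate_max: float
) -> tuple[list[str], pd.DataFrame]:
    """Remove cells whose both-allele observation fraction is too high.

    A cell is removed iff n_both / n_observed > ``conflict_rate_max``.
    Cells with zero observations are kept by this filter (vacuous rate)
    and flagged low-coverage.
    """
    df = matrix.per_cell_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(
            df["n_observed"] > 0,
            df["n_both"] / np.maximum(df["n_observed"], 1),
            0.0,
        )
    df["conflict_fraction"] = frac
    df["low_coverage"] = df["n_observed"] == 0
    df["removed_conflict"] = frac > conflict_rate_max
    kept = [b for b, rm in zip(matrix.barcodes, df["removed_conflict"]) if not rm]
    return kept, df


def switch_counts(
    phases: dict[str, ContigPhase] | list[ContigPhase],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (switches, informative adjacent pairs) pooled over contigs.

    For each contig, a cell's ordered non-NA H-sequence over phased bins
    is scanned; every adjacent pair in that compressed sequence counts as
    an informative pair, every unequal one as a switch.  Pairs never span
    contigs.
    """
    tracks = phases.values() if isinstance(phases, dict) else phases
    switches = pairs = None
    for phase in tracks:
        H = phase.switch_track()
        if H.size == 0:
            if switches is None and H.ndim == 2:
                switches = np.zeros(H.shape[1], dtype=np.int64)
                pairs = np.zeros(H.shape[1], dtype=np.int64)
            continue
        m, n_cells = H.shape
        if switches is None:
            switches = np.zeros(n_cells, dtype=np.int64)
            pairs = np.zeros(n_cells, dtype=np.int64)
        last = np.full(n_cells, H_NA, dtype=np.int8)
        seen = np.zeros(n_cells, dtype=bool)
        for i in range(m):
            cur = H[i]
            cur_v = cur != H_NA
            pair = cur_v & seen
            pairs += pair
            switches += pair & (cur != last)
            last = np.where(cur_v, cur, last)
            seen |= cur_v
    if switches is None:
        switches = np.zeros(0, dtype=np.int64)
        pairs = np.zeros(0, dtype=np.int64)
    return switches, pairs


def breakpoint_rate(phases, cell_index: int | None = None) -> np.ndarray | float:
    """Per-cell breakpoint rate (switches / informative adjacent pairs,
    0 when a cell has no pairs).  With ``cell_index`` returns a scalar."""
    switches, pairs = switch_counts(phases)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(pairs > 0, switches / np.maximum(pairs, 1), 0.0)
    if cell_index is not None:
        return float(rate[cell_index])
    return rate


def build_cell_qc(
    matrix: CellAlleleMatrix,
    phases: dict[str, ContigPhase],
    cfg: Config,
) -> pd.DataFrame:
    """Combined per-cell QC report with verdicts.

    Conflict removal takes precedence over breakpoint removal in the
    reported verdict; both criteria are evaluated for every cell.
    """
    _, conflict_df = conflict_filter(matrix, cfg.conflict_rate_max)
    switches, pairs = switch_counts(phases)
    if len(switches) == 0:
        switches = np.zeros(matrix.n_cells, dtype=np.int64)
        pairs = np.zeros(matrix.n_cells, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(pairs > 0, switches / np.maximum(pairs, 1), 0.0)
    report = conflict_df.copy()
    report["n_informative_adjacent_pairs"] = pairs
    report["n_switches"] = switches
    report["breakpoint_rate"] = rate
    removed_bp = rate > cfg.cell_breakpoint_max
    verdict = np.where(
        report["removed_conflict"],
        VERDICT_CONFLICT,
        np.where(removed_bp, VERDICT_BREAKPOINT, VERDICT_HAPLOID),
    )
    report["verdict"] = verdict
    return report


def filter_cells(
    report: pd.DataFrame, cell_breakpoint_max: float | None = None
) -> list[str]:
    """Barcodes that survive both filters.

    Removal by breakpoint rate is a strict inequality: a cell exactly at
    the threshold is kept.  ``cell_breakpoint_max`` re-applies the
    breakpoint rule with a different threshold if given.
    """
    if cell_breakpoint_max is not None:
        removed_bp = report["breakpoint_rate"] > cell_breakpoint_max
        removed = report["removed_conflict"].to_numpy() | removed_bp.to_numpy()
    else:
        removed = (report["verdict"] != VERDICT_HAPLOID).to_numpy()
    return [b for b, rm in zip(report["barcode"], removed) if not rm]
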