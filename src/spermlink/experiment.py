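"""Cell-count downsampling experiment.

How much of the genome can be placed and oriented as a function of the
number of sperm cells?  Cells are subsampled without replacement from the
input matrix, the full two-pass pipeline is rerun per subsample, and the
placed/oriented base fractions are tabulated per count (mean +/- sd over
replicates).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import Config
from .errors import ParameterError
from .ioforms import CellAlleleMatrix
from .model import SpermLinkageModel


def cell_count_experiment(
    matrix: CellAlleleMatrix,
    contig_lengths: Mapping[str, int],
    cell_counts: Sequence[int],
    replicates: int = 1,
    seed: int = 0,
    config: Config | None = None,
) -> pd.DataFrame:
    """Run the pipeline on random cell subsets of increasing size.

    Returns one row per (n_cells, replicate) with placed_pct,
    oriented_pct, n50 and the kept-cell count after QC.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    for n in cell_counts:
        if n < 1:
            raise ParameterError(f"cell count must be >= 1, got {n}")
        if n > matrix.n_cells:
            raise ParameterError(
                f"cell count {n} exceeds available cells ({matrix.n_cells})"
            )
    rng = np.random.default_rng(seed)
    rows = []
    for n in cell_counts:
        for rep in range(replicates):
            chosen = rng.choice(matrix.n_cells, size=n, replace=False)
            chosen.sort()
            sub = matrix.subset_cells([matrix.barcodes[i] for i in chosen])
            res = SpermLinkageModel(sub, contig_lengths, config).fit()
            rows.append(
                {
                    "n_cells": n,
                    "replicate": rep,
                    "n_cells_kept": len(res.kept_cells),
                    "placed_pct": res.stats["placed_pct"],
                    "oriented_pct": res.stats["oriented_pct"],
                    "n50": res.stats["n50"],
                }
            )
    return pd.DataFrame(rows)


def summarize_experiment(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of placed/oriented percentages per cell count."""
    return (
        table.groupby("n_cells")
        .agg(
            placed_mean=("placed_pct", "mean"),
            placed_sd=("placed_pct", "std"),
            oriented_mean=("oriented_pct", "mean"),
            oriented_sd=("oriented_pct", "std"),
            n_replicates=("replicate", "count"),
        )
        .reset_index()
    )
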