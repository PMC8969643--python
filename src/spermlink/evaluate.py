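"""Recovery metrics against simulation ground truth.

Quantifies how well a fitted linkage map recovers the simulated truth:
fraction of contig bases placed in the right chromosome's group, Kendall
tau of within-group order (up to whole-group reversal), and orientation
recall/accuracy among contigs with enough internal crossovers to be
orientable in principle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .model import LinkageMapResults
from .synthdata import SimTruth


def _truth_frame(truth: SimTruth) -> pd.DataFrame:
    return truth.contig_assignment.set_index("contig")


def match_groups(results: LinkageMapResults, truth: SimTruth) -> dict[str, str]:
    """Map each true chromosome to the linkage group holding the
    plurality of its contig bases."""
    ta = _truth_frame(truth)
    df = results.map.df
    best: dict[str, str] = {}
    for chrom in ta["chrom"].unique():
        contigs = ta.index[ta["chrom"] == chrom]
        sub = df[df["contig"].isin(contigs)]
        if len(sub) == 0:
            continue
        by_group = sub.groupby("group")["length"].sum().sort_values(
            ascending=False
        )
        best[chrom] = by_group.index[0]
    return best


def placement_accuracy(results: LinkageMapResults, truth: SimTruth) -> float:
    """Fraction of all contig bases placed in the true chromosome's group
    (unplaced contigs count as misplaced)."""
    ta = _truth_frame(truth)
    chrom_to_group = match_groups(results, truth)
    df = results.map.df.set_index("contig")
    total = 0
    correct = 0
    for contig, row in ta.iterrows():
        length = row["end_bp"] - row["start_bp"] + 1
        total += length
        if contig in df.index and df.loc[contig, "group"] == chrom_to_group.get(
            row["chrom"]
        ):
            correct += length
    return correct / total if total else 0.0


def order_tau(results: LinkageMapResults, truth: SimTruth) -> pd.DataFrame:
    """Per-group |Kendall tau| between recovered order and true physical
    start positions (absolute value: whole-group reversal is
    unidentifiable from linkage)."""
    ta = _truth_frame(truth)
    chrom_to_group = match_groups(results, truth)
    rows = []
    for chrom, group in chrom_to_group.items():
        sub = results.map.group_contigs(group)
        sub = sub[sub["contig"].isin(ta.index[ta["chrom"] == chrom])]
        sub = sub.sort_values("order_index")
        if len(sub) < 2:
            continue
        true_start = ta.loc[sub["contig"], "start_bp"].to_numpy()
        tau, _ = kendalltau(np.arange(len(sub)), true_start)
        rows.append({"chrom": chrom, "group": group, "n": len(sub), "tau": abs(tau)})
    return pd.DataFrame(rows)


def internal_crossover_counts(
    truth: SimTruth, cells: list[str] | None = None
) -> pd.Series:
    """Simulated crossovers falling strictly inside each contig, summed
    over cells (restricted to ``cells`` when given)."""
    ta = _truth_frame(truth)
    counts = {c: 0 for c in ta.index}
    wanted = set(cells) if cells is not None else None
    for cell, per_chrom in truth.cell_crossovers.items():
        if wanted is not None and cell not in wanted:
            continue
        for chrom, xos in per_chrom.items():
            if len(xos) == 0:
                continue
            sub = ta[ta["chrom"] == chrom]
            starts = sub["start_bp"].to_numpy()
            ends = sub["end_bp"].to_numpy()
            for contig, s, e in zip(sub.index, starts, ends):
                counts[contig] += int(((xos > s) & (xos < e)).sum())
    return pd.Series(counts, name="internal_crossovers")


def orientation_scores(
    results: LinkageMapResults,
    truth: SimTruth,
    min_internal_crossovers: int = 5,
) -> dict:
    """Orientation recall and accuracy among orientable contigs.

    A contig is orientable when at least ``min_internal_crossovers``
    simulated crossovers fall inside it across the kept cells.  Accuracy
    is judged up to whole-group reversal: the reversal gauge per group is
    the majority agreement between recovered and true orientations.
    """
    ta = _truth_frame(truth)
    xo = internal_crossover_counts(truth, results.kept_cells)
    df = results.map.df
    eligible = [c for c in ta.index if xo[c] >= min_internal_crossovers]
    placed = df[df["contig"].isin(eligible)]
    oriented = placed[placed["orientation"] != "?"]
    recall = len(oriented) / len(eligible) if eligible else float("nan")

    n_correct = 0
    n_checked = 0
    for group in placed["group"].unique():
        sub = df[(df["group"] == group) & (df["orientation"] != "?")]
        sub = sub[sub["contig"].isin(ta.index)]
        if len(sub) == 0:
            continue
        agree = (
            sub["orientation"].to_numpy()
            == ta.loc[sub["contig"], "orientation"].to_numpy()
        )
        flip = agree.sum() < (~agree).sum()  # group reversal gauge
        ok = ~agree if flip else agree
        mask = sub["contig"].isin(eligible).to_numpy()
        n_correct += int(ok[mask].sum())
        n_checked += int(mask.sum())
    accuracy = n_correct / n_checked if n_checked else float("nan")
    return {
        "n_eligible": len(eligible),
        "n_oriented_eligible": len(oriented),
        "orientation_recall": recall,
        "n_orientation_checked": n_checked,
        "orientation_accuracy": accuracy,
    }


def qc_operating_characteristics(results: LinkageMapResults, truth: SimTruth) -> dict:
    """Doublet-removal sensitivity and haploid false-removal rate of the
    cell QC, measured against true cell classes."""
    qc = results.qc.set_index("barcode")
    cls = pd.Series(truth.cell_class)
    cls = cls.reindex(qc.index)
    removed = qc["verdict"] != "haploid"
    is_doublet = cls == "doublet"
    is_diploid = cls == "diploid"
    is_haploid = cls == "haploid"
    out = {
        "n_doublets": int(is_doublet.sum()),
        "doublet_sensitivity": float(
            removed[is_doublet].mean() if is_doublet.any() else np.nan
        ),
        "n_diploids": int(is_diploid.sum()),
        "diploid_sensitivity": float(
            removed[is_diploid].mean() if is_diploid.any() else np.nan
        ),
        "n_haploids": int(is_haploid.sum()),
        "haploid_false_removal": float(
            removed[is_haploid].mean() if is_haploid.any() else np.nan
        ),
    }
    return out
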