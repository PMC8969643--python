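"""Marker selection, window binning and marker-level QC.

Sparse per-cell allele observations are aggregated into fixed, left-aligned,
non-overlapping windows of width ``r`` bp per contig ("bins", the
meta-markers all linkage computation runs on).

The assembly reference collapses a heterozygous diploid to an arbitrary
haplotype per site, so within a window the raw ref/alt labels of member
markers carry no common phase.  Member markers are therefore phased
against each other across cells before aggregation (greedy consensus,
minimum 2 shared informative cells); markers without cross-cell support
keep the provisional ref-as-A labelling.  A cell's bin call is then the
strict majority of its phase-aligned observed members, CONFLICT on a
tie or when any member shows both alleles, and NA when no member was
observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .config import Config
from .errors import ParameterError
from .ioforms import ALT, BOTH, REF, CellAlleleMatrix

# bin-call codes
NA, A, B, CONFLICT = 0, 1, 2, 3


@dataclass
class BinnedGenotypes:
    """Window-aggregated per-cell calls.

    ``bins``: DataFrame with (contig, window_index, start, end, n_markers),
    sorted by (contig, window_index).  ``calls``: dense int8 array of shape
    (n_bins, n_cells) with codes NA=0, A=1, B=2, CONFLICT=3.
    """

    bins: pd.DataFrame
    calls: np.ndarray
    barcodes: list[str]
    member_obs: np.ndarray | None = None  # observed member count per bin-cell

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def contig_slices(self) -> dict[str, slice]:
        """Row slice per contig (bins are grouped and ordered per contig)."""
        out: dict[str, slice] = {}
        contigs = self.bins["contig"].to_numpy()
        if len(contigs) == 0:
            return out
        change = np.flatnonzero(contigs[1:] != contigs[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(contigs)]])
        for s, e in zip(starts, ends):
            out[contigs[s]] = slice(int(s), int(e))
        return out

    def to_tsv(self, path) -> None:
        """Long-format dump (bin id, cell, call) for debugging."""
        codes = np.array(["NA", "A", "B", "CONFLICT"])
        idx, cell = np.nonzero(self.calls)
        df = pd.DataFrame(
            {
                "contig": self.bins["contig"].to_numpy()[idx],
                "window_index": self.bins["window_index"].to_numpy()[idx],
                "cell": np.asarray(self.barcodes, dtype=object)[cell],
                "call": codes[self.calls[idx, cell]],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def call_het_sites(
    bulk_counts: pd.DataFrame, min_depth: int = 20, maf_min: float = 0.2
) -> pd.DataFrame:
    """Select usable het sites from bulk per-site allele counts.

    ``bulk_counts`` needs columns ``ref_count`` and ``alt_count``.  A site
    is kept iff ref+alt >= ``min_depth`` and min(ref,alt)/(ref+alt) >=
    ``maf_min`` (boundaries kept).
    """
    ref = bulk_counts["ref_count"].to_numpy()
    alt = bulk_counts["alt_count"].to_numpy()
    if (ref < 0).any() or (alt < 0).any():
        raise ParameterError("allele counts must be non-negative")
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(depth > 0, np.minimum(ref, alt) / np.maximum(depth, 1), 0.0)
    keep = (depth >= min_depth) & (maf >= maf_min)
    return bulk_counts.loc[keep].reset_index(drop=True)


# minimum shared informative cells to phase a member marker within its window
_WINDOW_PHASE_MIN_SUPPORT = 2
_WINDOW_PHASE_PASSES = 3


def _phase_window(V: np.ndarray) -> np.ndarray:
    """Phase a window's member markers against each other across cells.

    ``V``: dense (m, n_cells) raw values (0 missing, 1 ref, 2 alt,
    3 both).  Returns a sign per marker: +1 keeps ref = A, -1 flips.
    The most-observed marker seeds the phase; remaining markers join by
    majority agreement with the per-cell consensus of already-phased
    members, needing >= 2 shared informative cells.  Markers that never
    gain support keep the provisional ref-as-A labelling (sign +1), so a
    window seen in a single cell reduces to the raw ref/alt majority.
    """
    m = V.shape[0]
    sign = np.ones(m, dtype=np.int8)
    if m == 1:
        return sign
    usable = (V == REF) | (V == ALT)
    val = (V == ALT).astype(np.int8)
    sign[:] = 0
    order = np.argsort(-usable.sum(axis=1), kind="stable")
    sign[order[0]] = 1
    for _ in range(_WINDOW_PHASE_PASSES):
        changed = False
        ph = sign != 0
        aligned = np.where(sign[:, None] == -1, 1 - val, val)
        n1 = ((aligned == 1) & usable & ph[:, None]).sum(axis=0)
        n0 = ((aligned == 0) & usable & ph[:, None]).sum(axis=0)
        cons = np.where(n1 > n0, 1, np.where(n0 > n1, 0, -1)).astype(np.int8)
        for i in order:
            if sign[i]:
                continue
            shared = usable[i] & (cons >= 0)
            n = int(shared.sum())
            if n < _WINDOW_PHASE_MIN_SUPPORT:
                continue
            n_s = int((val[i, shared] == cons[shared]).sum())
            sign[i] = 1 if 2 * n_s >= n else -1
            changed = True
        if not changed:
            break
    sign[sign == 0] = 1  # fallback: provisional ref labelling
    return sign


def bin_markers(matrix: CellAlleleMatrix, r: int) -> BinnedGenotypes:
    """Aggregate marker observations into fixed windows of width ``r`` bp.

    Windows start at position 1 of each contig; a bin exists only if it
    contains at least one marker.  Binning conserves coverage: every
    observed (marker, cell) entry contributes to exactly one bin's
    ``member_obs`` count.
    """
    if r <= 0:
        raise ParameterError(f"bin width r must be positive, got {r!r}")
    mk = matrix.markers
    win = (mk["pos"].to_numpy() - 1) // r
    key = pd.DataFrame({"contig": mk["contig"], "window_index": win})
    # bins in (contig, window) order; markers are sorted so groups are
    # contiguous runs of marker rows
    grouped = key.groupby(["contig", "window_index"], sort=True)
    bin_of_marker = grouped.ngroup().to_numpy()
    bins = grouped.size().rename("n_markers").reset_index()
    bins["start"] = bins["window_index"] * r + 1
    bins["end"] = (bins["window_index"] + 1) * r
    bins = bins[["contig", "window_index", "start", "end", "n_markers"]]

    n_bins = len(bins)
    n_cells = matrix.n_cells
    boundaries = np.searchsorted(bin_of_marker, np.arange(n_bins + 1))
    X = matrix.X.tocsr()
    calls = np.zeros((n_bins, n_cells), dtype=np.int8)
    member_obs = np.zeros((n_bins, n_cells), dtype=np.int32)
    for bidx in range(n_bins):
        lo, hi = boundaries[bidx], boundaries[bidx + 1]
        V = np.asarray(X[lo:hi].todense())
        sign = _phase_window(V)
        usable = (V == REF) | (V == ALT)
        val = (V == ALT).astype(np.int8)
        aligned = np.where(sign[:, None] == -1, 1 - val, val)
        nA = ((aligned == 0) & usable).sum(axis=0)
        nB = ((aligned == 1) & usable).sum(axis=0)
        n_both = (V == BOTH).sum(axis=0)
        n_obs = usable.sum(axis=0) + n_both
        row = np.full(n_cells, CONFLICT, dtype=np.int8)
        row[nA > nB] = A
        row[nB > nA] = B
        row[n_both > 0] = CONFLICT  # any both-allele member forces CONFLICT
        row[n_obs == 0] = NA
        calls[bidx] = row
        member_obs[bidx] = n_obs
    return BinnedGenotypes(
        bins=bins,
        calls=calls,
        barcodes=list(matrix.barcodes),
        member_obs=member_obs,
    )


def filter_markers(
    binned: BinnedGenotypes, cfg: Config
) -> tuple[BinnedGenotypes, dict[str, int]]:
    """Drop low-information bins.

    A bin is dropped if its non-NA cell fraction is < ``NonZeroSampleRate``
    or its informative (A/B) cell fraction is < ``RateOfNotNASNP``
    (boundaries kept).  Returns the filtered bins and per-rule drop counts.
    Idempotent.
    """
    calls = binned.calls
    n_cells = max(binned.n_cells, 1)
    non_na = (calls != NA).sum(axis=1) / n_cells
    informative = ((calls == A) | (calls == B)).sum(axis=1) / n_cells
    low_sample = non_na < cfg.non_zero_sample_rate
    low_info = informative < cfg.rate_of_not_na_snp
    keep = ~(low_sample | low_info)
    report = {
        "n_bins_in": binned.n_bins,
        "dropped_low_sample_rate": int(low_sample.sum()),
        "dropped_low_informative": int((low_info & ~low_sample).sum()),
        "n_bins_out": int(keep.sum()),
    }
    out = BinnedGenotypes(
        bins=binned.bins.loc[keep].reset_index(drop=True),
        calls=calls[keep],
        barcodes=binned.barcodes,
        member_obs=None if binned.member_obs is None else binned.member_obs[keep],
    )
    return out, report
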