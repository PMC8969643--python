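"""Within-contig phasing, missing-call imputation, and contig-end calls.

Bins on a contig are phased into the two parental haplotypes H0/H1 by
seed-and-extend: walking bins in positional order, each candidate bin is
linked to the nearest previously phased bin whose shared informative cells
support a consistent phase (at least ``cs`` shared cells with a minority
fraction <= ``p``); a candidate failing against the nearest phased bin is
tested against up to ``ldseqnum`` previous phased bins before being left
unphased.  The assignment is gauge-symmetric: flipping every phase sign
and swapping H0/H1 yields an equivalent phasing, and all downstream
recombination fractions are invariant under that swap.

Missing per-cell calls are imputed from the ``ldseqnum`` nearest observed
bins (bin-index distance, ties toward the smaller position) by strict
majority; observed calls are never overwritten, and because imputation
reads only observed calls it is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config
from .errors import ParameterError
from .genotype import A, B, CONFLICT, NA, BinnedGenotypes

# per-cell haplotype codes in int8 arrays
H_NA, H0, H1 = -1, 0, 1


@dataclass
class ContigPhase:
    """Phasing result for one contig.

    ``phase_sign`` per bin: +1 (A maps to H0), -1 (A maps to H1), or 0
    (unphased).  ``h_obs`` holds observed phase-aligned calls (-1 = NA),
    ``h_imp`` the same after imputation with ``imputed`` flagging filled
    entries.  ``cell_calls`` is the per-cell contig-level haplotype;
    ``end_left``/``end_right`` the per-cell end-window calls.
    """

    contig: str
    starts: np.ndarray  # bin start positions (bp)
    phase_sign: np.ndarray  # int8, (n_bins,)
    h_obs: np.ndarray  # int8, (n_bins, n_cells)
    cell_calls: np.ndarray  # int8, (n_cells,)
    h_imp: np.ndarray | None = None
    imputed: np.ndarray | None = None
    end_left: np.ndarray | None = None
    end_right: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.phase_sign)

    @property
    def n_phased(self) -> int:
        return int((self.phase_sign != 0).sum())

    @property
    def call_rate(self) -> float:
        n = len(self.cell_calls)
        return float((self.cell_calls != H_NA).sum() / n) if n else 0.0

    def switch_track(self) -> np.ndarray:
        """Observed H-calls over phased bins only (rows), for breakpoint
        analysis; unphased bins are dropped, not treated as NA."""
        return self.h_obs[self.phase_sign != 0]

    def flipped(self) -> "ContigPhase":
        """The gauge-equivalent phasing with H0 and H1 swapped."""

        def swap(h):
            return None if h is None else np.where(h == H_NA, H_NA, 1 - h).astype(np.int8)

        return ContigPhase(
            contig=self.contig,
            starts=self.starts,
            phase_sign=(-self.phase_sign).astype(np.int8),
            h_obs=swap(self.h_obs),
            cell_calls=swap(self.cell_calls),
            h_imp=swap(self.h_imp),
            imputed=None if self.imputed is None else self.imputed.copy(),
            end_left=swap(self.end_left),
            end_right=swap(self.end_right),
        )


def phase_contig(
    calls: np.ndarray,
    cfg: Config,
    contig: str = "",
    starts: np.ndarray | None = None,
) -> ContigPhase:
    """Phase one contig's bin calls into parental haplotypes.

    ``calls``: int8 (n_bins, n_cells) bin-call codes in positional order.
    A contig where no bin pair meets the ``cs`` support rule comes back
    all-unphased.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_bins, n_cells = calls.shape
    if n_bins < 1:
        raise ParameterError("phase_contig requires at least one bin")
    if starts is None:
        starts = np.arange(n_bins, dtype=np.int64)
    informative = (calls == A) | (calls == B)
    v = (calls == B).astype(np.int8)  # 0 for A, 1 for B

    sign = np.zeros(n_bins, dtype=np.int8)
    phased: list[int] = []
    for j in range(n_bins):
        if not informative[j].any():
            continue
        if not phased:
            sign[j] = 1  # gauge choice for the seed
            phased.append(j)
            continue
        for k in reversed(phased[-cfg.ldseqnum :]):
            shared = informative[j] & informative[k]
            n = int(shared.sum())
            if n < cfg.cs:
                continue
            h_k = v[k, shared] if sign[k] == 1 else 1 - v[k, shared]
            n_o = int((h_k != v[j, shared]).sum())
            n_s = n - n_o
            if min(n_s, n_o) / n > cfg.p:
                continue
            sign[j] = 1 if n_s >= n_o else -1
            phased.append(j)
            break
    if len(phased) <= 1 and n_bins > 1:
        # no bin pair met the support rule: report all-unphased
        sign[:] = 0
        phased = []

    h_obs = np.full((n_bins, n_cells), H_NA, dtype=np.int8)
    for j in phased or ([0] if n_bins == 1 and sign[0] else []):
        row = np.full(n_cells, H_NA, dtype=np.int8)
        hv = v[j] if sign[j] == 1 else 1 - v[j]
        row[informative[j]] = hv[informative[j]]
        h_obs[j] = row

    cell_calls = _consensus_calls(h_obs, sign, cfg.b)
    return ContigPhase(
        contig=contig,
        starts=np.asarray(starts),
        phase_sign=sign,
        h_obs=h_obs,
        cell_calls=cell_calls,
    )


def _consensus_calls(h_obs: np.ndarray, sign: np.ndarray, b: float) -> np.ndarray:
    """Per-cell contig call: majority H over phased bins, NA unless the
    minority fraction is <= ``b`` and the majority is strict."""
    phased_rows = h_obs[sign != 0]
    n_cells = h_obs.shape[1]
    if phased_rows.size == 0:
        return np.full(n_cells, H_NA, dtype=np.int8)
    n1 = (phased_rows == H1).sum(axis=0)
    n0 = (phased_rows == H0).sum(axis=0)
    tot = n0 + n1
    with np.errstate(invalid="ignore", divide="ignore"):
        minority = np.where(tot > 0, np.minimum(n0, n1) / np.maximum(tot, 1), 1.0)
    calls = np.full(n_cells, H_NA, dtype=np.int8)
    ok = (tot > 0) & (n0 != n1) & (minority <= b)
    calls[ok & (n1 > n0)] = H1
    calls[ok & (n0 > n1)] = H0
    return calls


def impute_missing(phase: ContigPhase, ldseqnum: int) -> ContigPhase:
    """Fill missing phase-aligned calls from nearby observed bins.

    For each cell, each NA among the contig's phased bins is assigned the
    strict-majority H of its ``ldseqnum`` nearest observed bins (bin-index
    distance; ties broken toward the smaller position); without a strict
    majority it stays NA.  Sources are observed calls only, so imputation
    never overwrites an observation and re-running it is a no-op.
    """
    if ldseqnum < 1:
        raise ParameterError("ldseqnum must be >= 1")
    h_imp = phase.h_obs.copy()
    imputed = np.zeros_like(h_imp, dtype=bool)
    phased_idx = np.flatnonzero(phase.phase_sign != 0)
    if len(phased_idx) == 0:
        phase.h_imp = h_imp
        phase.imputed = imputed
        return phase
    H = phase.h_obs[phased_idx]  # (m, n_cells)
    m, n_cells = H.shape
    for c in range(n_cells):
        col = H[:, c]
        valid = np.flatnonzero(col != H_NA)
        if len(valid) == 0:
            continue
        missing = np.flatnonzero(col == H_NA)
        if len(missing) == 0:
            continue
        vpos = phased_idx[valid]  # original bin indices of sources
        for q in missing:
            qpos = phased_idx[q]
            ins = np.searchsorted(vpos, qpos)
            lo = max(0, ins - ldseqnum)
            hi = min(len(vpos), ins + ldseqnum)
            cand = np.arange(lo, hi)
            dist = np.abs(vpos[cand] - qpos)
            order = np.lexsort((vpos[cand], dist))
            sel = cand[order[:ldseqnum]]
            vals = col[valid[sel]]
            ones = int((vals == H1).sum())
            zeros = len(vals) - ones
            if ones > zeros:
                h_imp[qpos, c] = H1
            elif zeros > ones:
                h_imp[qpos, c] = H0
            else:
                continue
            imputed[qpos, c] = True
    phase.h_imp = h_imp
    phase.imputed = imputed
    return phase


def end_haplotypes(phase: ContigPhase, end_window_bins: int) -> ContigPhase:
    """Per-cell haplotype calls at the contig's two ends.

    The left (right) end call is the strict-majority H over the first
    (last) ``end_window_bins`` phased bins.  On contigs with fewer than
    2 x ``end_window_bins`` phased bins the window is clamped to half the
    phased bins so that the two end windows never overlap — otherwise
    short contigs would get identical end calls by construction and
    internal recombination inside them could never be seen.  A single-bin
    contig has left = right.  Imputed calls are used when imputation has
    run.
    """
    if end_window_bins < 1:
        raise ParameterError("end_window_bins must be >= 1")
    source = phase.h_imp if phase.h_imp is not None else phase.h_obs
    phased_idx = np.flatnonzero(phase.phase_sign != 0)
    n_cells = phase.h_obs.shape[1]
    if len(phased_idx) == 0:
        phase.end_left = np.full(n_cells, H_NA, dtype=np.int8)
        phase.end_right = np.full(n_cells, H_NA, dtype=np.int8)
        return phase
    if len(phased_idx) == 1:
        w = 1
    else:
        w = min(end_window_bins, max(1, len(phased_idx) // 2))
    phase.end_left = _window_majority(source[phased_idx[:w]])
    phase.end_right = _window_majority(source[phased_idx[-w:]])
    return phase


def _window_majority(rows: np.ndarray) -> np.ndarray:
    n1 = (rows == H1).sum(axis=0)
    n0 = (rows == H0).sum(axis=0)
    out = np.full(rows.shape[1], H_NA, dtype=np.int8)
    out[n1 > n0] = H1
    out[n0 > n1] = H0
    return out


def phase_all_contigs(binned: BinnedGenotypes, cfg: Config) -> dict[str, ContigPhase]:
    """Phase every contig present in the binned calls, in contig order."""
    phases: dict[str, ContigPhase] = {}
    for contig, sl in binned.contig_slices().items():
        phases[contig] = phase_contig(
            binned.calls[sl],
            cfg,
            contig=contig,
            starts=binned.bins["start"].to_numpy()[sl],
        )
    return phases


def phase_report(phases: dict[str, ContigPhase]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": list(phases),
            "n_bins": [p.n_bins for p in phases.values()],
            "n_phased": [p.n_phased for p in phases.values()],
            "call_rate": [p.call_rate for p in phases.values()],
        }
    )
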