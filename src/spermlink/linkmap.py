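"""Two-point linkage between contig ends, grouping, ordering, orientation
and genetic positions.

The recombination fraction between two per-cell haplotype vectors is
computed over cells informative in both: with d disagreements among n
shared cells, r = min(d, n - d) / n — the phase gauge is fixed to the
minimizing alignment, so complementary vectors have r = 0.  Contigs are
clustered into linkage groups on a graph with an edge wherever the best
end-to-end LD = 1 - 2r reaches the ``nl`` threshold; groups are ordered
and oriented by minimizing the total adjacent end-to-end recombination
(greedy chaining with 2-opt refinement, exact for small groups), and
genetic positions accumulate from the adjacent recombination fractions
(cM = 100 r by default; Haldane optional).

A contig's orientation is reported only when flipping it changes the
flanking-adjacency evidence by at least ``cs`` discordant cells; contigs
with no internal recombination observed in any cell (their two end calls
are indistinguishable) are always reported "?", mirroring the unoriented
centromeric blocks real maps show.  Whole-group reversal is not
identifiable from linkage alone; groups are reported with the physically
longer arm first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import Config
from .errors import ParameterError
from .phasing import H_NA, ContigPhase

UNDEFINED_R = 0.5  # cost assigned to end pairs with no usable evidence


# ---------------------------------------------------------------------------
# pairwise statistics


def rec_fraction(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Gauge-fixed two-point recombination fraction between H-call vectors.

    Returns (r, n_shared); r is NaN when no cell is informative in both.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ParameterError("H-call vectors must share the same cell universe")
    shared = (a != H_NA) & (b != H_NA)
    n = int(shared.sum())
    if n == 0:
        return float("nan"), 0
    d = int((a[shared] != b[shared]).sum())
    return min(d, n - d) / n, n


@dataclass
class EndCalls:
    """Per-cell haplotype calls at both ends of every linkage-eligible
    contig, plus contig lengths.  End index 2i is contig i's left end,
    2i+1 its right end."""

    contigs: list[str]
    left: np.ndarray  # int8 (n_contigs, n_cells)
    right: np.ndarray
    lengths: dict[str, int]

    @property
    def n_cells(self) -> int:
        return self.left.shape[1]

    @classmethod
    def from_phases(
        cls, phases: dict[str, ContigPhase], lengths: dict[str, int]
    ) -> "EndCalls":
        contigs = [c for c, p in phases.items() if p.end_left is not None]
        if not contigs:
            raise ParameterError("no contigs with end calls")
        left = np.stack([phases[c].end_left for c in contigs])
        right = np.stack([phases[c].end_right for c in contigs])
        return cls(contigs=contigs, left=left, right=right, lengths=lengths)


@dataclass
class PairStats:
    """Dense end-by-end shared counts, raw disagreements, and gauge-fixed
    recombination fractions (NaN where no shared cell)."""

    contigs: list[str]
    n: np.ndarray  # (2c, 2c) shared informative cells
    d: np.ndarray  # (2c, 2c) gauge-fixed discordant cells min(d, n-d)
    r: np.ndarray  # (2c, 2c)
    n_cells: int

    def end(self, contig_index: int, side: str) -> int:
        return 2 * contig_index + (0 if side == "left" else 1)


def pairwise_end_stats(ends: EndCalls) -> PairStats:
    """All end-by-end (n, d, r) via dense indicator algebra."""
    c = len(ends.contigs)
    E = np.empty((2 * c, ends.n_cells), dtype=np.int8)
    E[0::2] = ends.left
    E[1::2] = ends.right
    M0 = (E == 0).astype(np.float32)
    M1 = (E == 1).astype(np.float32)
    agree = M0 @ M0.T + M1 @ M1.T
    disagree = M0 @ M1.T + M1 @ M0.T
    n = (agree + disagree).astype(np.int64)
    d_raw = disagree.astype(np.int64)
    d = np.minimum(d_raw, n - d_raw)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(n > 0, d / np.maximum(n, 1), np.nan)
    return PairStats(contigs=list(ends.contigs), n=n, d=d, r=r, n_cells=ends.n_cells)


def linkage_pairs(stats: PairStats, cfg: Config) -> pd.DataFrame:
    """Diagnostic dump of best end-to-end linkage per contig pair."""
    rows = []
    c = len(stats.contigs)
    for i in range(c):
        for j in range(i + 1, c):
            best = _best_combo(stats, i, j, cfg)
            if best is None:
                continue
            r, n, ei, ej = best
            rows.append(
                {
                    "contig_i": stats.contigs[i],
                    "contig_j": stats.contigs[j],
                    "end_i": "LR"[ei % 2],
                    "end_j": "LR"[ej % 2],
                    "r": r,
                    "n_shared": n,
                    "ld": 1 - 2 * r,
                }
            )
    return pd.DataFrame(
        rows, columns=["contig_i", "contig_j", "end_i", "end_j", "r", "n_shared", "ld"]
    )


def _best_combo(stats: PairStats, i: int, j: int, cfg: Config):
    """Best (lowest-r) eligible end combination for a contig pair."""
    best = None
    for ei in (2 * i, 2 * i + 1):
        for ej in (2 * j, 2 * j + 1):
            n = stats.n[ei, ej]
            if n < cfg.cs or n < cfg.rate_of_not_na_ld * stats.n_cells:
                continue
            r = stats.r[ei, ej]
            if best is None or r < best[0]:
                best = (float(r), int(n), ei, ej)
    return best


# ---------------------------------------------------------------------------
# clustering


def cluster_groups(
    stats: PairStats, cfg: Config
) -> tuple[list[list[int]], list[int]]:
    """Partition contigs into linkage groups.

    An edge joins two contigs when their best eligible end-to-end LD
    (1 - 2r over >= cs shared cells covering >= RateOfNotNALD of cells)
    reaches ``nl``; groups are the connected components.  Components
    smaller than ``min_group_size`` are reported as unplaced.  Returns
    (groups, unplaced) as contig indices; groups are deterministic
    (members sorted, groups sorted by total length descending then name).
    """
    c = len(stats.contigs)
    G = nx.Graph()
    G.add_nodes_from(range(c))
    for i in range(c):
        for j in range(i + 1, c):
            best = _best_combo(stats, i, j, cfg)
            if best is None:
                continue
            if 1 - 2 * best[0] >= cfg.nl:
                G.add_edge(i, j)
    groups = []
    unplaced = []
    for comp in nx.connected_components(G):
        members = sorted(comp)
        if len(members) < cfg.min_group_size:
            unplaced.extend(members)
        else:
            groups.append(members)
    groups.sort(key=lambda g: (-sum(_length(stats, i) for i in g), stats.contigs[g[0]]))
    return groups, sorted(unplaced)


def _length(stats: PairStats, i: int) -> int:
    lengths = getattr(stats, "lengths_by_index", None)
    return int(lengths[i]) if lengths is not None else 0


# ---------------------------------------------------------------------------
# ordering and orientation


@dataclass
class OrderedGroup:
    """One linkage group: ordered contig indices with working orientations,
    reported orientations (+/-/?), and cM positions."""

    name: str
    contig_idx: list[int]
    working_orient: list[str]  # '+' or '-', used for adjacency geometry
    reported_orient: list[str]  # '+', '-' or '?'
    cm_start: list[float] = field(default_factory=list)
    cm_end: list[float] = field(default_factory=list)
    objective: float = 0.0


def _facing_ends(i: int, oi: str, j: int, oj: str) -> tuple[int, int]:
    """End indices that face each other when contig i (orientation oi)
    precedes contig j (orientation oj)."""
    right_i = 2 * i + 1 if oi == "+" else 2 * i
    left_j = 2 * j if oj == "+" else 2 * j + 1
    return right_i, left_j


def _adjacency_cost(stats: PairStats, i, oi, j, oj, cs: int) -> float:
    ei, ej = _facing_ends(i, oi, j, oj)
    n = stats.n[ei, ej]
    if n < cs:
        return UNDEFINED_R
    return float(stats.r[ei, ej])


def chain_objective(
    stats: PairStats, chain: list[tuple[int, str]], cs: int
) -> float:
    """Total adjacent end-to-end recombination along an ordered, oriented
    chain; end pairs without evidence cost the maximum 0.5."""
    total = 0.0
    for (i, oi), (j, oj) in zip(chain, chain[1:]):
        total += _adjacency_cost(stats, i, oi, j, oj, cs)
    return total


def order_contigs(
    members: list[int], stats: PairStats, cfg: Config
) -> list[tuple[int, str]]:
    """Order and (working-)orient a group by minimizing total adjacent
    recombination: greedy best-edge chaining, then 2-opt segment reversal
    until no improving move.  Deterministic; ties break on contig index.
    """
    if len(members) == 1:
        return [(members[0], "+")]
    chain = _greedy_chain(members, stats, cfg.cs)
    chain = _two_opt(chain, stats, cfg.cs)
    return chain


def _end_pairs_sorted(members, stats: PairStats, cs: int):
    pairs = []
    for i, j in itertools.combinations(members, 2):
        for ei in (2 * i, 2 * i + 1):
            for ej in (2 * j, 2 * j + 1):
                n = stats.n[ei, ej]
                cost = float(stats.r[ei, ej]) if n >= cs else UNDEFINED_R
                pairs.append((cost, i, ei, j, ej))
    pairs.sort(key=lambda t: (t[0], t[1], t[3], t[2], t[4]))
    return pairs


def _greedy_chain(members, stats: PairStats, cs: int) -> list[tuple[int, str]]:
    """Greedy best-edge chaining over contig ends: repeatedly take the
    cheapest end pair joining two different chains at free ends."""
    # each contig starts as its own chain [(idx, '+')]
    chain_of: dict[int, int] = {i: k for k, i in enumerate(members)}
    chains: dict[int, list[tuple[int, str]]] = {
        k: [(i, "+")] for k, i in enumerate(members)
    }
    # an end is free if its contig sits at the matching extremity
    def free_end(end: int) -> tuple[int, bool] | None:
        i = end // 2
        k = chain_of[i]
        ch = chains[k]
        side = "left" if end % 2 == 0 else "right"
        first, last = ch[0], ch[-1]
        if first[0] == i:
            # contig i at chain head: its exposed end is its left end under
            # '+' working orientation, right end under '-'
            exposed = (2 * i) if first[1] == "+" else (2 * i + 1)
            if exposed == end:
                return k, True  # at head
        if last[0] == i:
            exposed = (2 * i + 1) if last[1] == "+" else (2 * i)
            if exposed == end:
                return k, False  # at tail
        return None

    for cost, i, ei, j, ej in _end_pairs_sorted(members, stats, cs):
        ki = chain_of[i]
        kj = chain_of[j]
        if ki == kj:
            continue
        fi = free_end(ei)
        fj = free_end(ej)
        if fi is None or fj is None:
            continue
        # arrange chain of i so that end ei is at its tail,
        # and chain of j so that end ej is at its head, then concatenate
        ci = chains[fi[0]]
        cj = chains[fj[0]]
        if fi[1]:  # ei at head -> reverse chain i
            ci = _reverse_chain(ci)
        if not fj[1]:  # ej at tail -> reverse chain j
            cj = _reverse_chain(cj)
        merged = ci + cj
        chains[ki] = merged
        del chains[kj]
        for idx, _ in merged:
            chain_of[idx] = ki
        if len(chains) == 1:
            break
    # join any remaining chains in deterministic order by best free-end cost
    remaining = sorted(chains.values(), key=lambda ch: ch[0][0])
    chain = remaining[0]
    for nxt in remaining[1:]:
        best = None
        for a in (chain, _reverse_chain(chain)):
            for bvar in (nxt, _reverse_chain(nxt)):
                i, oi = a[-1]
                j, oj = bvar[0]
                cost = _adjacency_cost(stats, i, oi, j, oj, cs)
                if best is None or cost < best[0]:
                    best = (cost, a, bvar)
        chain = best[1] + best[2]
    return chain


def _reverse_chain(chain: list[tuple[int, str]]) -> list[tuple[int, str]]:
    return [(i, "-" if o == "+" else "+") for i, o in reversed(chain)]


def _two_opt(
    chain: list[tuple[int, str]], stats: PairStats, cs: int
) -> list[tuple[int, str]]:
    """Best-improvement 2-opt: reverse (and flip) every contiguous segment,
    including single contigs (an orientation flip), until no move improves
    the objective."""
    n = len(chain)
    best = chain
    best_obj = chain_objective(stats, best, cs)
    improved = True
    while improved:
        improved = False
        for a in range(n):
            for b in range(a, n):
                cand = best[:a] + _reverse_chain(best[a : b + 1]) + best[b + 1 :]
                obj = chain_objective(stats, cand, cs)
                if obj < best_obj - 1e-12:
                    best, best_obj = cand, obj
                    improved = True
        # loop again from the improved chain
    return best


def brute_force_order(
    members: list[int], stats: PairStats, cs: int
) -> tuple[list[tuple[int, str]], float]:
    """Exhaustive search over all orders x orientations (oracle for small
    groups); returns the optimal chain and its objective."""
    best = None
    best_obj = np.inf
    for perm in itertools.permutations(members):
        for orients in itertools.product("+-", repeat=len(members)):
            chain = list(zip(perm, orients))
            obj = chain_objective(stats, chain, cs)
            if obj < best_obj - 1e-12:
                best, best_obj = chain, obj
    return best, best_obj


def canonicalize_group(
    chain: list[tuple[int, str]], stats: PairStats
) -> list[tuple[int, str]]:
    """Report the physically longer arm first (whole-group reversal is not
    identifiable from linkage); ties break on the first contig's name."""
    lengths = [stats.lengths_by_index[i] if hasattr(stats, "lengths_by_index") else 0
               for i, _ in chain]
    half = (len(chain) + 1) // 2
    first = sum(lengths[:half])
    last = sum(lengths[-half:])
    if first > last:
        return chain
    if first < last:
        return _reverse_chain(chain)
    if stats.contigs[chain[0][0]] <= stats.contigs[chain[-1][0]]:
        return chain
    return _reverse_chain(chain)


def orient_contigs(
    chain: list[tuple[int, str]], stats: PairStats, cs: int
) -> list[str]:
    """Reported orientation per chain position.

    For each contig, the flanking-adjacency discordant-cell totals are
    compared between its two orientations; the better orientation is
    reported only when the totals differ by >= ``cs`` cells.  Contigs with
    indistinguishable end calls (no internal recombination in any cell)
    are always '?'.
    """
    reported = []
    for pos, (i, oi) in enumerate(chain):
        n_int = stats.n[2 * i, 2 * i + 1]
        d_int = stats.d[2 * i, 2 * i + 1]
        if n_int == 0 or d_int == 0:
            reported.append("?")
            continue
        flipped = "-" if oi == "+" else "+"
        ev = {}
        for o in (oi, flipped):
            total = 0
            if pos > 0:
                j, oj = chain[pos - 1]
                ej, el = _facing_ends(j, oj, i, o)
                total += int(stats.d[ej, el]) if stats.n[ej, el] > 0 else 0
            if pos < len(chain) - 1:
                j, oj = chain[pos + 1]
                er, ejl = _facing_ends(i, o, j, oj)
                total += int(stats.d[er, ejl]) if stats.n[er, ejl] > 0 else 0
            ev[o] = total
        if abs(ev[oi] - ev[flipped]) < cs:
            reported.append("?")
        else:
            reported.append(oi if ev[oi] <= ev[flipped] else flipped)
    return reported


# ---------------------------------------------------------------------------
# genetic positions and the map container


def _map_cm(r: float, map_function: str) -> float:
    r = min(max(r, 0.0), 0.4999)
    if map_function == "haldane":
        return -50.0 * np.log(1.0 - 2.0 * r)
    return 100.0 * r


def genetic_positions(
    chain: list[tuple[int, str]],
    reported: list[str],
    stats: PairStats,
    cfg: Config,
) -> tuple[list[float], list[float]]:
    """Cumulative cM positions along an ordered group.

    A contig's span is the mapped recombination between its own two ends;
    unoriented contigs are assigned a single shared position (zero span),
    matching the flat centromeric loci of real maps.  Inter-contig
    distances use the working orientations' facing ends.
    """
    cm_start: list[float] = []
    cm_end: list[float] = []
    pos = 0.0
    for k, (i, oi) in enumerate(chain):
        if k > 0:
            j, oj = chain[k - 1]
            r_adj = _adjacency_cost(stats, j, oj, i, oi, cfg.cs)
            if r_adj >= UNDEFINED_R:
                r_adj = 0.0  # no evidence: abut rather than inflate the map
            pos += _map_cm(r_adj, cfg.map_function)
        cm_start.append(pos)
        if reported[k] != "?" and stats.n[2 * i, 2 * i + 1] > 0:
            span = _map_cm(float(stats.r[2 * i, 2 * i + 1]), cfg.map_function)
        else:
            span = 0.0
        cm_end.append(pos + span)
        pos += span
    return cm_start, cm_end


@dataclass
class LinkageGroupMap:
    """Ordered, oriented linkage groups with genetic positions.

    ``df`` has one row per placed contig: group, order_index, contig,
    orientation (+/-/?), working_orientation, length, cM_start, cM_end.
    ``unplaced`` lists contigs outside any group.
    """

    df: pd.DataFrame
    unplaced: list[str]

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.df["group"]))

    def group_contigs(self, name: str) -> pd.DataFrame:
        return self.df[self.df["group"] == name]

    def summary(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            sub = self.group_contigs(g)
            rows.append(
                {
                    "group": g,
                    "n_contigs": len(sub),
                    "n_oriented": int((sub["orientation"] != "?").sum()),
                    "total_bp": int(sub["length"].sum()),
                    "map_length_cM": float(sub["cM_end"].max()),
                }
            )
        return pd.DataFrame(rows)


def build_linkage_map(
    phases: dict[str, ContigPhase],
    contig_lengths: dict[str, int],
    cfg: Config,
) -> tuple[LinkageGroupMap, PairStats]:
    """Full linkage-map construction from phased contigs."""
    eligible = {
        c: p
        for c, p in phases.items()
        if p.call_rate >= cfg.non_zero_phase_rate and p.n_phased > 0
    }
    excluded = [c for c in phases if c not in eligible]
    if not eligible:
        empty = pd.DataFrame(
            columns=[
                "group",
                "order_index",
                "contig",
                "orientation",
                "working_orientation",
                "length",
                "cM_start",
                "cM_end",
            ]
        )
        return LinkageGroupMap(df=empty, unplaced=sorted(phases)), None
    ends = EndCalls.from_phases(eligible, contig_lengths)
    stats = pairwise_end_stats(ends)
    stats.lengths_by_index = [
        contig_lengths.get(c, 0) for c in stats.contigs
    ]  # used by canonicalize_group
    groups, unplaced_idx = cluster_groups(stats, cfg)

    rows = []
    for gnum, members in enumerate(groups, start=1):
        chain = order_contigs(members, stats, cfg)
        chain = canonicalize_group(chain, stats)
        reported = orient_contigs(chain, stats, cfg.cs)
        cm_start, cm_end = genetic_positions(chain, reported, stats, cfg)
        gname = f"lg{gnum}"
        for k, ((i, oi), rep) in enumerate(zip(chain, reported)):
            contig = stats.contigs[i]
            rows.append(
                {
                    "group": gname,
                    "order_index": k,
                    "contig": contig,
                    "orientation": rep,
                    "working_orientation": oi,
                    "length": contig_lengths.get(contig, 0),
                    "cM_start": cm_start[k],
                    "cM_end": cm_end[k],
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "group",
            "order_index",
            "contig",
            "orientation",
            "working_orientation",
            "length",
            "cM_start",
            "cM_end",
        ],
    )
    unplaced = sorted(
        [stats.contigs[i] for i in unplaced_idx] + excluded
    )
    return LinkageGroupMap(df=df, unplaced=unplaced), stats
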