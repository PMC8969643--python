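"""Scaffold plans, assembly statistics, and back-of-envelope calculators.

Linkage groups become chromosome scaffolds: placed contigs in map order,
joined by N-gaps of ``gap_len`` (default 10,000, the pseudo-chromosome
convention).  Contigs whose orientation could not be determined appear in
the chromosome sequence as an N-run of their own length and are emitted
again as separate records named ``<group>_unoriented_<contig>``.

The calculators cover the arithmetic a study design needs: map resolution
from cell count and cM/Mb, mean SNP spacing, and sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .linkmap import LinkageGroupMap


@dataclass
class Component:
    kind: str  # 'contig' or 'gap'
    length: int
    contig: str | None = None
    orientation: str = "+"
    unoriented: bool = False


@dataclass
class ScaffoldGroup:
    name: str
    components: list[Component]

    @property
    def length(self) -> int:
        return sum(c.length for c in self.components)


@dataclass
class ScaffoldPlan:
    groups: list[ScaffoldGroup]
    unplaced: list[str]
    gap_len: int

    def placed_contigs(self) -> list[Component]:
        return [
            c for g in self.groups for c in g.components if c.kind == "contig"
        ]

    def record_lengths(self) -> dict[str, int]:
        """Lengths of every output sequence record: scaffolds, separate
        unoriented-contig records, and unplaced contigs."""
        out: dict[str, int] = {}
        for g in self.groups:
            out[g.name] = g.length
            for c in g.components:
                if c.kind == "contig" and c.unoriented:
                    out[f"{g.name}_unoriented_{c.contig}"] = c.length
        for contig, length in self.unplaced:
            out[contig] = length
        return out


def build_plan(
    lmap: LinkageGroupMap,
    contig_lengths: Mapping[str, int],
    gap_len: int = 10000,
) -> ScaffoldPlan:
    """Deterministic scaffold plan from a linkage map.

    Scaffold length = sum of component lengths + gap_len x (n_components
    - 1) per group.
    """
    if gap_len < 0:
        raise ParameterError("gap_len must be >= 0")
    groups: list[ScaffoldGroup] = []
    for gname in lmap.groups:
        sub = lmap.group_contigs(gname).sort_values("order_index")
        comps: list[Component] = []
        for _, row in sub.iterrows():
            contig = row["contig"]
            if contig not in contig_lengths:
                raise ParameterError(f"no length for contig {contig!r}")
            if comps:
                comps.append(Component(kind="gap", length=gap_len))
            unoriented = row["orientation"] == "?"
            comps.append(
                Component(
                    kind="contig",
                    length=int(contig_lengths[contig]),
                    contig=contig,
                    orientation=row["orientation"] if not unoriented else "+",
                    unoriented=unoriented,
                )
            )
        groups.append(ScaffoldGroup(name=gname, components=comps))
    unplaced = []
    for contig in lmap.unplaced:
        if contig not in contig_lengths:
            raise ParameterError(f"no length for contig {contig!r}")
        unplaced.append((contig, int(contig_lengths[contig])))
    return ScaffoldPlan(groups=groups, unplaced=unplaced, gap_len=gap_len)


def n50(lengths: Sequence[int]) -> int:
    """Length of the shortest sequence at 50% cumulative length:
    sort descending, accumulate, report the length where the running sum
    first reaches half the total."""
    if len(lengths) == 0:
        raise ParameterError("n50 of an empty length list is undefined")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if (arr <= 0).any():
        raise ParameterError("sequence lengths must be positive")
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, half, side="left")])


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def assembly_stats(
    plan: ScaffoldPlan, all_contig_lengths: Mapping[str, int]
) -> dict:
    """Placed/oriented base percentages, N50, and totals.

    Percentages are over contig bases (not counts): placed_pct = bases of
    contigs in any group / total contig bases x 100; oriented_pct counts
    only placed contigs with a determined orientation.  N50 and totals are
    over the output sequence records (scaffolds, separate unoriented
    records, unplaced contigs).
    """
    if not all_contig_lengths:
        raise ParameterError("no contig lengths given")
    total_contig_bp = sum(all_contig_lengths.values())
    placed = plan.placed_contigs()
    placed_bp = sum(c.length for c in placed)
    oriented_bp = sum(c.length for c in placed if not c.unoriented)
    record_lengths = plan.record_lengths()
    return {
        "n_scaffolds": len(plan.groups),
        "n_sequences": len(record_lengths),
        "total_bp": int(sum(record_lengths.values())),
        "total_contig_bp": int(total_contig_bp),
        "n50": n50(list(record_lengths.values())) if record_lengths else 0,
        "placed_pct": _round1(100.0 * placed_bp / total_contig_bp),
        "oriented_pct": _round1(100.0 * oriented_bp / total_contig_bp),
    }


# ---------------------------------------------------------------------------
# calculators


def expected_resolution(n_cells: int, cM_per_Mb: float) -> float:
    """Expected bp between detectable recombination events.

    With ``n_cells`` gametes and a genetic density of ``cM_per_Mb``, one
    recombinant gamete is expected per 10^6 / (n_cells x cM_per_Mb / 100)
    bases: 10,000 cells at 1 cM/Mb resolve one event per 10 kb; 100 cells
    resolve one per 1000 kb.
    """
    if n_cells <= 0 or cM_per_Mb <= 0:
        raise ParameterError("n_cells and cM_per_Mb must be positive")
    return 1e6 / (n_cells * cM_per_Mb / 100.0)


def snp_spacing(genome_bp: int, n_snps: int) -> int:
    """Mean bases per het SNP, rounded to the nearest base."""
    if genome_bp <= 0 or n_snps <= 0:
        raise ParameterError("genome_bp and n_snps must be positive")
    return int(
        Decimal(repr(genome_bp / n_snps)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


def depth(total_bases: float, genome_bp: int) -> float:
    """Fold coverage, rounded to one decimal (half-up)."""
    if genome_bp <= 0:
        raise ParameterError("genome_bp must be positive")
    if total_bases < 0:
        raise ParameterError("total_bases must be non-negative")
    return _round1(total_bases / genome_bp)
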