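"""Meiosis and single-cell observation simulator.

Generates a heterozygous diploid parent genome, fragments its assembly into
contigs of unknown order/orientation, simulates gametes (crossovers with an
optional obligate chiasma and optional centromeric suppression), and samples
sparse single-cell allele observations in the vartrix value convention
(1 = ref, 2 = alt, 3 = both, absent = missing).  Ground truth (contig
placement/orientation, per-cell crossovers, cell class) is retained for
recovery testing.

Default parameters emulate the statistical structure of a 10x Genomics
single-sperm experiment on a small fish genome: one het SNP per ~245 bp,
~0.13x coverage per cell, sub-Mb contigs, 1-2 crossovers per chromosome
per gamete, a small doublet/diploid cell fraction, and a low allele
observation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ParameterError
from .ioforms import CellAlleleMatrix

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SimGenome:
    """A heterozygous diploid parent genome.

    ``het_positions[chrom]`` holds sorted 1-based site positions;
    ``hap0``/``hap1`` the two (distinct) alleles per site; ``ref_is_hap0``
    records which haplotype the collapsed assembly reference shows at each
    site.  ``centromere_pos`` maps chromosome -> centromere position in bp.
    """

    chromosomes: list[tuple[str, int]]
    het_positions: dict[str, np.ndarray]
    hap0: dict[str, np.ndarray]
    hap1: dict[str, np.ndarray]
    ref_is_hap0: dict[str, np.ndarray]
    centromere_pos: dict[str, int] | None = None

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p in self.het_positions.values())


@dataclass
class Contig:
    """One assembly contig with its inherited het sites (contig-local)."""

    id: str
    chrom: str
    start_bp: int  # 1-based start on the chromosome
    length: int
    orientation: str  # '+' or '-': how the emitted sequence relates to chrom
    local_pos: np.ndarray  # sorted ascending, 1-based on the emitted contig
    ref: np.ndarray  # ref allele letters on the emitted strand
    alt: np.ndarray
    site_idx: np.ndarray  # index into the chromosome's site arrays
    ref_hap: np.ndarray  # 0 if the ref allele is hap0, else 1

    @property
    def end_bp(self) -> int:
        return self.start_bp + self.length - 1


@dataclass
class ContigSet:
    contigs: list[Contig]

    def __iter__(self):
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def lengths(self) -> dict[str, int]:
        return {c.id: c.length for c in self.contigs}

    def marker_table(self) -> pd.DataFrame:
        """All contig markers sorted by (contig, pos), 1-based positions."""
        frames = []
        for c in sorted(self.contigs, key=lambda c: c.id):
            frames.append(
                pd.DataFrame(
                    {
                        "contig": c.id,
                        "pos": c.local_pos,
                        "ref": c.ref,
                        "alt": c.alt,
                    }
                )
            )
        if not frames:
            return pd.DataFrame(columns=["contig", "pos", "ref", "alt"])
        return pd.concat(frames, ignore_index=True)


@dataclass
class SimTruth:
    """Ground truth for recovery tests."""

    contig_assignment: pd.DataFrame  # contig, chrom, start_bp, end_bp, orientation
    cell_crossovers: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    cell_class: dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.contig_assignment.to_csv(
            outdir / "truth_contigs.tsv", sep="\t", index=False
        )
        rows = []
        for cell, per_chrom in self.cell_crossovers.items():
            for chrom, pos in per_chrom.items():
                rows.append(
                    {
                        "cell": cell,
                        "chrom": chrom,
                        "crossovers": ",".join(str(int(p)) for p in pos),
                    }
                )
        pd.DataFrame(rows, columns=["cell", "chrom", "crossovers"]).to_csv(
            outdir / "truth_crossovers.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"cell": list(self.cell_class), "class": list(self.cell_class.values())}
        ).to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)


@dataclass
class CrossoverModel:
    """Per-chromosome crossover process.

    ``rate_per_chrom`` is the mean crossover count per chromosome per
    gamete.  With ``obligate`` the count is 1 + Poisson(max(rate - 1, 0)),
    modelling the obligate chiasma of most meioses; otherwise plain
    Poisson(rate).  Crossover positions are uniform on the chromosome with
    zero density inside a window of ``centromere_suppression_width_bp``
    centred on the centromere.
    """

    rate_per_chrom: float = 1.5
    obligate: bool = True
    centromere_suppression_width_bp: int = 0

    def __post_init__(self) -> None:
        if self.rate_per_chrom < 0:
            raise ParameterError("rate_per_chrom must be >= 0")
        if self.centromere_suppression_width_bp < 0:
            raise ParameterError("centromere_suppression_width_bp must be >= 0")


@dataclass
class Gamete:
    """One meiotic product: per-site haplotype indicator and crossovers."""

    haplotype: dict[str, np.ndarray]  # chrom -> 0/1 per het site
    crossovers: dict[str, np.ndarray]  # chrom -> sorted positions (bp)


# ---------------------------------------------------------------------------
# operations


def simulate_parent_genome(
    n_chrom: int,
    chrom_len_bp: int,
    snp_spacing_bp: int,
    seed: int,
    place_centromeres: bool = True,
) -> SimGenome:
    """Simulate a diploid parent with geometric het-site inter-arrivals.

    Mean spacing equals ``snp_spacing_bp``; each site gets two distinct
    alleles, and the assembly reference collapses to either haplotype with
    probability 1/2 per site.
    """
    if n_chrom < 1:
        raise ParameterError("n_chrom must be >= 1")
    if chrom_len_bp <= 0 or snp_spacing_bp <= 0:
        raise ParameterError("chrom_len_bp and snp_spacing_bp must be positive")
    if chrom_len_bp < 10 * snp_spacing_bp:
        raise ParameterError(
            "chrom_len_bp must be at least 10 x snp_spacing_bp "
            f"({chrom_len_bp} < {10 * snp_spacing_bp})"
        )
    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i + 1}", int(chrom_len_bp)) for i in range(n_chrom)]
    het_positions: dict[str, np.ndarray] = {}
    hap0: dict[str, np.ndarray] = {}
    hap1: dict[str, np.ndarray] = {}
    ref_is_hap0: dict[str, np.ndarray] = {}
    centromeres: dict[str, int] = {}
    for chrom, length in chromosomes:
        positions: list[np.ndarray] = []
        last = 0
        # draw geometric gaps in blocks until past the chromosome end
        while last < length:
            block = rng.geometric(1.0 / snp_spacing_bp, size=256)
            pos = last + np.cumsum(block)
            positions.append(pos)
            last = int(pos[-1])
        pos = np.concatenate(positions)
        pos = pos[pos <= length].astype(np.int64)
        n = len(pos)
        a0 = rng.integers(0, 4, size=n)
        a1 = (a0 + rng.integers(1, 4, size=n)) % 4  # always distinct
        het_positions[chrom] = pos
        hap0[chrom] = _BASES[a0]
        hap1[chrom] = _BASES[a1]
        ref_is_hap0[chrom] = rng.random(n) < 0.5
        centromeres[chrom] = int(length * rng.uniform(0.4, 0.6))
    return SimGenome(
        chromosomes=chromosomes,
        het_positions=het_positions,
        hap0=hap0,
        hap1=hap1,
        ref_is_hap0=ref_is_hap0,
        centromere_pos=centromeres if place_centromeres else None,
    )


def fragment_into_contigs(
    genome: SimGenome, mean_contig_len_bp: int, seed: int
) -> tuple[ContigSet, SimTruth]:
    """Partition each chromosome into contigs of ~exponential length.

    A random half of contigs are emitted reverse-complemented (truth
    orientation "-"): their het sites appear in reversed order with
    complemented alleles and contig-local coordinates.
    """
    spacing_est = _mean_spacing(genome)
    if mean_contig_len_bp < 2 * spacing_est:
        raise ParameterError(
            "mean_contig_len_bp must be >= 2 x the het-site spacing "
            f"({mean_contig_len_bp} < {2 * spacing_est:.0f})"
        )
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    rows = []
    k = 0
    for chrom, length in genome.chromosomes:
        pos = genome.het_positions[chrom]
        start = 1
        while start <= length:
            remaining = length - start + 1
            clen = int(max(1, round(rng.exponential(mean_contig_len_bp))))
            clen = min(clen, remaining)
            # avoid a dangling sliver at the chromosome end
            if remaining - clen < max(1, mean_contig_len_bp // 20):
                clen = remaining
            end = start + clen - 1
            orientation = "+" if rng.random() < 0.5 else "-"
            cid = f"ctg{k:05d}"
            k += 1
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            idx = np.arange(lo, hi)
            if orientation == "+":
                local = pos[idx] - start + 1
                ref_letters = np.where(
                    genome.ref_is_hap0[chrom][idx],
                    genome.hap0[chrom][idx],
                    genome.hap1[chrom][idx],
                )
                alt_letters = np.where(
                    genome.ref_is_hap0[chrom][idx],
                    genome.hap1[chrom][idx],
                    genome.hap0[chrom][idx],
                )
            else:
                idx = idx[::-1]
                local = end - pos[idx] + 1
                comp = np.vectorize(_COMPLEMENT.get, otypes=[str]) if len(idx) else None
                r0 = np.where(
                    genome.ref_is_hap0[chrom][idx],
                    genome.hap0[chrom][idx],
                    genome.hap1[chrom][idx],
                )
                a0 = np.where(
                    genome.ref_is_hap0[chrom][idx],
                    genome.hap1[chrom][idx],
                    genome.hap0[chrom][idx],
                )
                ref_letters = comp(r0) if len(idx) else r0
                alt_letters = comp(a0) if len(idx) else a0
            ref_hap = np.where(genome.ref_is_hap0[chrom][idx], 0, 1).astype(np.int8)
            contigs.append(
                Contig(
                    id=cid,
                    chrom=chrom,
                    start_bp=start,
                    length=clen,
                    orientation=orientation,
                    local_pos=local.astype(np.int64),
                    ref=np.asarray(ref_letters, dtype="<U1"),
                    alt=np.asarray(alt_letters, dtype="<U1"),
                    site_idx=idx.astype(np.int64),
                    ref_hap=ref_hap,
                )
            )
            rows.append(
                {
                    "contig": cid,
                    "chrom": chrom,
                    "start_bp": start,
                    "end_bp": end,
                    "orientation": orientation,
                }
            )
            start = end + 1
    truth = SimTruth(contig_assignment=pd.DataFrame(rows))
    return ContigSet(contigs), truth


def simulate_gamete(
    genome: SimGenome,
    crossover_model: CrossoverModel | None = None,
    seed: int | np.random.Generator = 0,
) -> Gamete:
    """Simulate one meiotic product of the parent genome."""
    model = crossover_model or CrossoverModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    haplotype: dict[str, np.ndarray] = {}
    crossovers: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes:
        if model.obligate:
            n_xo = 1 + rng.poisson(max(model.rate_per_chrom - 1.0, 0.0))
        else:
            n_xo = rng.poisson(model.rate_per_chrom)
        xo = _draw_crossover_positions(
            int(n_xo), length, genome, chrom, model, rng
        )
        pos = genome.het_positions[chrom]
        start = int(rng.integers(0, 2))
        parity = np.searchsorted(xo, pos, side="left") % 2
        haplotype[chrom] = ((start + parity) % 2).astype(np.int8)
        crossovers[chrom] = xo
    return Gamete(haplotype=haplotype, crossovers=crossovers)


def _draw_crossover_positions(
    n_xo: int,
    length: int,
    genome: SimGenome,
    chrom: str,
    model: CrossoverModel,
    rng: np.random.Generator,
) -> np.ndarray:
    width = model.centromere_suppression_width_bp
    if width > 0 and genome.centromere_pos is not None:
        c = genome.centromere_pos[chrom]
        win_lo = max(0.0, c - width / 2.0)
        win_hi = min(float(length), c + width / 2.0)
    else:
        win_lo = win_hi = 0.0
    allowed = length - (win_hi - win_lo)
    if allowed <= 0:
        if n_xo > 0:
            raise ParameterError(
                f"centromeric suppression window covers all of {chrom} but "
                "a crossover is required"
            )
        return np.empty(0, dtype=np.float64)
    u = rng.uniform(0.0, allowed, size=n_xo)
    xo = np.where(u < win_lo, u, u + (win_hi - win_lo))
    return np.sort(xo)


def simulate_cell_observations(
    contigs: ContigSet,
    gametes: Sequence[Gamete],
    per_site_hit_rate: float,
    allele_error_rate: float,
    cell_class: str = "haploid",
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one cell's sparse allele observations over the marker list.

    Returns ``(marker_idx, values)`` into the marker order of
    ``contigs.marker_table()``; values follow the vartrix convention
    (1 = ref, 2 = alt, 3 = both).  ``cell_class``:

    - ``haploid``: one gamete, each site hit independently with
      ``per_site_hit_rate``; the observed allele is flipped with
      ``allele_error_rate``.
    - ``doublet``: the union of two gametes' independent observations;
      value 3 where both are hit and disagree.
    - ``diploid``: both alleles observable (value 3) at every hit site.
    """
    if not 0.0 <= per_site_hit_rate <= 1.0 or not 0.0 <= allele_error_rate <= 1.0:
        raise ParameterError("rates must be in [0, 1]")
    if cell_class not in ("haploid", "doublet", "diploid"):
        raise ParameterError(f"unknown cell_class {cell_class!r}")
    if cell_class == "doublet" and len(gametes) < 2:
        raise ParameterError("doublet requires two gametes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    marker_idx_parts: list[np.ndarray] = []
    value_parts: list[np.ndarray] = []
    offset = 0
    for contig in sorted(contigs.contigs, key=lambda c: c.id):
        n = len(contig.local_pos)
        if n == 0:
            continue
        if cell_class == "diploid":
            hit = rng.random(n) < per_site_hit_rate
            vals = np.full(n, 3, dtype=np.int8)
            obs_mask = hit
        else:
            v1, h1 = _gamete_values(contig, gametes[0], per_site_hit_rate,
                                    allele_error_rate, rng)
            if cell_class == "haploid":
                obs_mask, vals = h1, v1
            else:
                v2, h2 = _gamete_values(contig, gametes[1], per_site_hit_rate,
                                        allele_error_rate, rng)
                obs_mask = h1 | h2
                vals = np.where(h1, v1, v2).astype(np.int8)
                both = h1 & h2 & (v1 != v2)
                vals[both] = 3
        idx = np.nonzero(obs_mask)[0]
        marker_idx_parts.append(idx + offset)
        value_parts.append(vals[obs_mask])
        offset += n
    if not marker_idx_parts:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8)
    return (
        np.concatenate(marker_idx_parts),
        np.concatenate(value_parts),
    )


def _gamete_values(
    contig: Contig,
    gamete: Gamete,
    hit_rate: float,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker (value in {1,2}, hit mask) for one gamete on one contig."""
    n = len(contig.local_pos)
    hap = gamete.haplotype[contig.chrom][contig.site_idx]
    if error_rate > 0:
        flip = rng.random(n) < error_rate
        hap = np.where(flip, 1 - hap, hap)
    values = np.where(hap == contig.ref_hap, 1, 2).astype(np.int8)
    hit = rng.random(n) < hit_rate
    return values, hit


# ---------------------------------------------------------------------------
# whole-dataset convenience


@dataclass
class SimulatedDataset:
    matrix: CellAlleleMatrix
    genome: SimGenome
    contigs: ContigSet
    truth: SimTruth
    params: dict


def simulate_dataset(
    n_chrom: int = 4,
    chrom_len_bp: int = 2_000_000,
    snp_spacing_bp: int = 245,
    mean_contig_len_bp: int = 80_000,
    n_cells: int = 1000,
    per_site_hit_rate: float = 0.13,
    allele_error_rate: float = 0.005,
    doublet_fraction: float = 0.05,
    diploid_fraction: float = 0.02,
    crossover_model: CrossoverModel | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate a complete single-sperm experiment with ground truth.

    Defaults emulate the study conditions at desk scale: het-SNP spacing
    245 bp, per-cell hit rate 0.13, allele error 0.005, 5% doublets and
    2% diploid cells, obligate crossover plus Poisson extras (mean 1.5
    per chromosome).
    """
    if not 0 <= doublet_fraction + diploid_fraction <= 1:
        raise ParameterError("cell-class fractions must sum to <= 1")
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    model = crossover_model or CrossoverModel()
    ss = np.random.SeedSequence(seed)
    s_genome, s_frag, s_cells = ss.spawn(3)
    genome = simulate_parent_genome(
        n_chrom, chrom_len_bp, snp_spacing_bp, seed=s_genome
    )
    contigs, truth = fragment_into_contigs(genome, mean_contig_len_bp, seed=s_frag)

    rng = np.random.default_rng(s_cells)
    classes = rng.choice(
        ["haploid", "doublet", "diploid"],
        size=n_cells,
        p=[1 - doublet_fraction - diploid_fraction, doublet_fraction, diploid_fraction],
    )
    barcodes = [f"cell{i:04d}" for i in range(n_cells)]
    markers = ContigSet(sorted(contigs.contigs, key=lambda c: c.id)).marker_table()
    n_markers = len(markers)
    rows_parts, cols_parts, vals_parts = [], [], []
    for j, (barcode, cls) in enumerate(zip(barcodes, classes)):
        gametes = [simulate_gamete(genome, model, rng)]
        if cls == "doublet":
            gametes.append(simulate_gamete(genome, model, rng))
        midx, vals = simulate_cell_observations(
            contigs, gametes, per_site_hit_rate, allele_error_rate, cls, rng
        )
        rows_parts.append(midx)
        cols_parts.append(np.full(len(midx), j, dtype=np.int64))
        vals_parts.append(vals)
        truth.cell_class[barcode] = str(cls)
        truth.cell_crossovers[barcode] = {
            chrom: np.sort(np.concatenate([g.crossovers[chrom] for g in gametes]))
            for chrom, _ in genome.chromosomes
        }
    X = sparse.coo_matrix(
        (
            np.concatenate(vals_parts),
            (np.concatenate(rows_parts), np.concatenate(cols_parts)),
        ),
        shape=(n_markers, n_cells),
        dtype=np.int8,
    ).tocsr()
    matrix = CellAlleleMatrix(markers=markers, barcodes=barcodes, X=X)
    params = dict(
        n_chrom=n_chrom,
        chrom_len_bp=chrom_len_bp,
        snp_spacing_bp=snp_spacing_bp,
        mean_contig_len_bp=mean_contig_len_bp,
        n_cells=n_cells,
        per_site_hit_rate=per_site_hit_rate,
        allele_error_rate=allele_error_rate,
        doublet_fraction=doublet_fraction,
        diploid_fraction=diploid_fraction,
        rate_per_chrom=model.rate_per_chrom,
        obligate=model.obligate,
        centromere_suppression_width_bp=model.centromere_suppression_width_bp,
        seed=seed,
    )
    return SimulatedDataset(
        matrix=matrix, genome=genome, contigs=contigs, truth=truth, params=params
    )


# ---------------------------------------------------------------------------
# writers


def write_contig_fasta(contigs: ContigSet, path: str | Path, seed: int = 0) -> None:
    """Emit contig sequences: random bases with ref alleles at marker sites.

    Sequence content away from het sites is synthetic filler; only the
    marker positions matter to the pipeline.
    """
    ss = np.random.SeedSequence(seed)
    with open(path, "w") as fh:
        for contig, child in zip(
            sorted(contigs.contigs, key=lambda c: c.id),
            ss.spawn(len(contigs.contigs)),
        ):
            rng = np.random.default_rng(child)
            seq = rng.choice(_BASES, size=contig.length)
            if len(contig.local_pos):
                seq[contig.local_pos - 1] = contig.ref
            fh.write(f">{contig.id}\n")
            s = "".join(seq)
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")


def contig_length_table(contigs: ContigSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "contig": [c.id for c in sorted(contigs.contigs, key=lambda c: c.id)],
            "length": [c.length for c in sorted(contigs.contigs, key=lambda c: c.id)],
        }
    ).to_csv(path, sep="\t", index=False)


def _mean_spacing(genome: SimGenome) -> float:
    total_len = sum(length for _, length in genome.chromosomes)
    n = genome.n_sites
    return total_len / max(n, 1)
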