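"""Readers and writers for the on-disk formats the pipeline touches.

Formats: VCF 4.2 (bulk het sites; multi-sample "cell-separated" genotypes),
Matrix Market coordinate integer (vartrix-style markers x cells allele
matrix) plus a barcode list, FASTA, AGP v2.1, and the genetic-map TSV.

The vartrix value convention is used throughout: 0/absent = no call,
1 = ref, 2 = alt, 3 = both alleles observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq
from scipy import sparse
from scipy.io import mmread, mmwrite

from .errors import FormatError

if TYPE_CHECKING:  # pragma: no cover
    from .scaffold import ScaffoldPlan

logger = logging.getLogger(__name__)

MISSING, REF, ALT, BOTH = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# the sparse cell x marker container


@dataclass
class CellAlleleMatrix:
    """Sparse per-cell haploid allele observations over a marker list.

    ``markers`` is a DataFrame with columns (contig, pos, ref, alt), sorted
    by (contig, pos) with 1-based positions; ``X`` is a markers x cells
    CSR matrix with values in {1, 2, 3} (stored zeros are not allowed).
    """

    markers: pd.DataFrame
    barcodes: list[str]
    X: sparse.csr_matrix

    def __post_init__(self) -> None:
        self.X = sparse.csr_matrix(self.X, dtype=np.int8)
        self.X.eliminate_zeros()
        if self.X.shape != (len(self.markers), len(self.barcodes)):
            raise FormatError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.markers)} markers x {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")
        if self.X.nnz and not np.isin(self.X.data, (REF, ALT, BOTH)).all():
            bad = sorted(set(self.X.data) - {REF, ALT, BOTH})
            raise FormatError(f"matrix values outside {{1,2,3}}: {bad}")
        mk = self.markers.reset_index(drop=True)
        order = mk.sort_values(["contig", "pos"], kind="stable")
        if not order.index.equals(mk.index):
            raise FormatError("markers must be sorted by (contig, pos)")
        self.markers = mk

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def subset_cells(self, keep: Sequence[str]) -> "CellAlleleMatrix":
        index = {b: i for i, b in enumerate(self.barcodes)}
        cols = [index[b] for b in keep]
        return CellAlleleMatrix(
            markers=self.markers, barcodes=list(keep), X=self.X[:, cols]
        )

    def per_cell_counts(self) -> pd.DataFrame:
        """Observation and both-allele counts per cell."""
        n_obs = np.asarray((self.X != 0).sum(axis=0)).ravel()
        xb = self.X.copy()
        xb.data = (xb.data == BOTH).astype(np.int8)
        n_both = np.asarray(xb.sum(axis=0)).ravel()
        return pd.DataFrame(
            {"barcode": self.barcodes, "n_observed": n_obs, "n_both": n_both}
        )


# ---------------------------------------------------------------------------
# VCF


def read_het_sites(vcf_path: str | Path) -> pd.DataFrame:
    """Read biallelic SNPs from a bulk VCF into a marker table.

    Multi-allelic and indel records are skipped (logged).  Returns a
    DataFrame with columns (contig, pos, ref, alt) sorted by (contig, pos).
    """
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"{vcf_path}: cannot parse VCF: {exc}") from exc
    rows = []
    skipped = 0
    with vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                skipped += 1
                continue
            rows.append((rec.chrom, rec.pos, rec.ref, alts[0]))
    if skipped:
        logger.info("read_het_sites: skipped %d non-biallelic-SNP records", skipped)
    df = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    return df.sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)


def write_het_vcf(
    markers: pd.DataFrame,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a bulk VCF of het sites with a diploid 0/1 parent genotype."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lengths = dict(contig_lengths or {})
    for contig in pd.unique(markers["contig"]):
        length = lengths.get(contig)
        if length is None:
            sub = markers.loc[markers["contig"] == contig, "pos"]
            length = int(sub.max()) if len(sub) else 1
        header.contigs.add(str(contig), length=int(length))
    header.add_sample("bulk")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in markers.itertuples(index=False):
            rec = out.new_record(
                contig=str(row.contig),
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(str(row.ref), str(row.alt)),
            )
            rec.samples["bulk"]["GT"] = (0, 1)
            out.write(rec)


_GT_CODES = {REF: (0,), ALT: (1,), BOTH: (0, 1)}


def write_cell_vcf(
    matrix: CellAlleleMatrix,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write the cell-separated multi-sample VCF dialect.

    One sample per barcode; haploid genotype codes 0 (ref) and 1 (alt),
    ``./.`` for missing, and ``0/1`` where both alleles were seen
    (doublet evidence).
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lengths = dict(contig_lengths or {})
    for contig in pd.unique(matrix.markers["contig"]):
        length = lengths.get(contig)
        if length is None:
            sub = matrix.markers.loc[matrix.markers["contig"] == contig, "pos"]
            length = int(sub.max()) if len(sub) else 1
        header.contigs.add(str(contig), length=int(length))
    for b in matrix.barcodes:
        header.add_sample(b)
    Xcsr = matrix.X.tocsr()
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, row in enumerate(matrix.markers.itertuples(index=False)):
            rec = out.new_record(
                contig=str(row.contig),
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(str(row.ref), str(row.alt)),
            )
            sl = slice(Xcsr.indptr[i], Xcsr.indptr[i + 1])
            for j, v in zip(Xcsr.indices[sl], Xcsr.data[sl]):
                rec.samples[int(j)]["GT"] = _GT_CODES[int(v)]
            out.write(rec)


def read_cell_vcf(path: str | Path) -> CellAlleleMatrix:
    """Read the cell-separated VCF dialect back into a CellAlleleMatrix."""
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse VCF: {exc}") from exc
    barcodes = list(vcf.header.samples)
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"{path}: duplicate sample barcodes")
    rows, cols, vals, marker_rows = [], [], [], []
    with vcf:
        for i, rec in enumerate(vcf):
            alts = rec.alts or ()
            if len(alts) != 1:
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} is not biallelic"
                )
            marker_rows.append((rec.chrom, rec.pos, rec.ref, alts[0]))
            for j, sample in enumerate(rec.samples.values()):
                gt = sample.get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                alleles = tuple(a for a in gt if a is not None)
                if alleles == (0,):
                    v = REF
                elif alleles == (1,):
                    v = ALT
                elif set(alleles) == {0, 1}:
                    v = BOTH
                else:
                    raise FormatError(
                        f"{path}: unsupported genotype {gt} at {rec.chrom}:{rec.pos}"
                    )
                rows.append(i)
                cols.append(j)
                vals.append(v)
    markers = pd.DataFrame(marker_rows, columns=["contig", "pos", "ref", "alt"])
    X = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(len(markers), len(barcodes)), dtype=np.int8
    ).tocsr()
    return CellAlleleMatrix(markers=markers, barcodes=barcodes, X=X)


# ---------------------------------------------------------------------------
# Matrix Market + barcodes (vartrix convention)


def write_allele_matrix(
    matrix: CellAlleleMatrix, mtx_path: str | Path, barcodes_path: str | Path
) -> None:
    mmwrite(str(mtx_path), matrix.X.tocoo(), field="integer")
    Path(barcodes_path).write_text("\n".join(matrix.barcodes) + "\n")


def read_allele_matrix(
    mtx_path: str | Path, barcodes_path: str | Path, markers: pd.DataFrame
) -> CellAlleleMatrix:
    """Read a vartrix-style Matrix Market file against a marker list."""
    try:
        M = mmread(str(mtx_path))
    except ValueError as exc:
        raise FormatError(f"{mtx_path}: cannot parse Matrix Market: {exc}") from exc
    M = sparse.coo_matrix(M)
    barcodes = [
        line.strip()
        for line in Path(barcodes_path).read_text().splitlines()
        if line.strip()
    ]
    if M.shape[0] != len(markers):
        raise FormatError(
            f"matrix has {M.shape[0]} rows but marker list has {len(markers)}"
        )
    if M.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix has {M.shape[1]} columns but barcode list has {len(barcodes)}"
        )
    keep = M.data != 0
    data = M.data[keep]
    if data.size and not np.isin(data, (REF, ALT, BOTH)).all():
        bad = sorted(set(data) - {REF, ALT, BOTH})
        raise FormatError(f"{mtx_path}: values outside {{0,1,2,3}}: {bad}")
    X = sparse.coo_matrix(
        (data.astype(np.int8), (M.row[keep], M.col[keep])), shape=M.shape
    ).tocsr()
    return CellAlleleMatrix(markers=markers, barcodes=barcodes, X=X)


# ---------------------------------------------------------------------------
# FASTA helpers


def read_contig_lengths(path: str | Path) -> dict[str, int]:
    """Contig lengths from a FASTA file or a two-column TSV (contig, length)."""
    path = Path(path)
    first = path.open().read(1)
    if first == ">":
        lengths: dict[str, int] = {}
        with pysam.FastxFile(str(path)) as fx:
            for rec in fx:
                lengths[rec.name] = len(rec.sequence)
        return lengths
    df = pd.read_csv(path, sep="\t")
    if not {"contig", "length"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns 'contig' and 'length'")
    return dict(zip(df["contig"].astype(str), df["length"].astype(int)))


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fx:
        for rec in fx:
            seqs[rec.name] = rec.sequence
    return seqs


def _write_fasta_record(fh, name: str, seq: str, width: int = 80) -> None:
    fh.write(f">{name}\n")
    for i in range(0, len(seq), width):
        fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# AGP v2.1 + scaffold FASTA


def write_agp(plan: "ScaffoldPlan", path: str | Path) -> None:
    """Write the scaffold plan as AGP v2.1.

    Oriented contigs are W component lines with +/-.  Unoriented contigs
    follow the convention of appearing in the chromosome sequence as an
    N-run of their own length (they are emitted separately in FASTA), so
    they are written as N gap lines with gap_type ``contig``.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for group in plan.groups:
            pos = 1
            part = 1
            for comp in group.components:
                beg, end = pos, pos + comp.length - 1
                if comp.kind == "gap":
                    fh.write(
                        f"{group.name}\t{beg}\t{end}\t{part}\tN\t{comp.length}"
                        f"\tscaffold\tyes\tmap\n"
                    )
                elif comp.unoriented:
                    fh.write(
                        f"{group.name}\t{beg}\t{end}\t{part}\tN\t{comp.length}"
                        f"\tcontig\tyes\tmap\n"
                    )
                else:
                    fh.write(
                        f"{group.name}\t{beg}\t{end}\t{part}\tW\t{comp.contig}"
                        f"\t1\t{comp.length}\t{comp.orientation}\n"
                    )
                pos = end + 1
                part += 1


def validate_agp(path: str | Path) -> int:
    """Validate AGP coordinates: 1-based, contiguous, sequential parts.

    Returns the number of component lines checked; raises FormatError on
    the first violation.
    """
    n = 0
    expected: dict[str, tuple[int, int]] = {}  # object -> (next_beg, next_part)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) < 8:
            raise FormatError(f"{path}:{lineno}: expected >= 8 fields")
        obj, beg, end, part, kind = (
            fields[0],
            int(fields[1]),
            int(fields[2]),
            int(fields[3]),
            fields[4],
        )
        if beg > end:
            raise FormatError(f"{path}:{lineno}: object_beg > object_end")
        nb, npart = expected.get(obj, (1, 1))
        if beg != nb:
            raise FormatError(
                f"{path}:{lineno}: object_beg {beg} not contiguous (expected {nb})"
            )
        if part != npart:
            raise FormatError(
                f"{path}:{lineno}: part_number {part} (expected {npart})"
            )
        if kind == "W":
            comp_beg, comp_end = int(fields[6]), int(fields[7])
            if comp_end - comp_beg != end - beg:
                raise FormatError(
                    f"{path}:{lineno}: component span does not match object span"
                )
            if fields[8] not in ("+", "-", "?"):
                raise FormatError(f"{path}:{lineno}: bad orientation {fields[8]!r}")
        elif kind in ("N", "U"):
            if int(fields[5]) != end - beg + 1:
                raise FormatError(
                    f"{path}:{lineno}: gap_length does not match object span"
                )
        else:
            raise FormatError(f"{path}:{lineno}: unknown component_type {kind!r}")
        expected[obj] = (end + 1, part + 1)
        n += 1
    return n


def write_scaffold_fasta(
    plan: "ScaffoldPlan",
    contig_seqs: Mapping[str, str],
    path: str | Path,
    include_unplaced: bool = True,
) -> dict[str, int]:
    """Emit scaffold sequences (plus separate records for unoriented and,
    optionally, unplaced contigs).  Returns emitted record lengths."""
    lengths: dict[str, int] = {}
    with open(path, "w") as fh:
        for group in plan.groups:
            parts: list[str] = []
            extras: list[tuple[str, str]] = []
            for comp in group.components:
                if comp.kind == "gap":
                    parts.append("N" * comp.length)
                    continue
                seq = contig_seqs.get(comp.contig)
                if seq is None:
                    raise FormatError(f"no sequence for contig {comp.contig!r}")
                if len(seq) != comp.length:
                    raise FormatError(
                        f"sequence length {len(seq)} != plan length "
                        f"{comp.length} for contig {comp.contig!r}"
                    )
                if comp.unoriented:
                    parts.append("N" * comp.length)
                    extras.append((f"{group.name}_unoriented_{comp.contig}", seq))
                elif comp.orientation == "-":
                    parts.append(str(Seq(seq).reverse_complement()))
                else:
                    parts.append(seq)
            scaffold = "".join(parts)
            _write_fasta_record(fh, group.name, scaffold)
            lengths[group.name] = len(scaffold)
            for name, seq in extras:
                _write_fasta_record(fh, name, seq)
                lengths[name] = len(seq)
        if include_unplaced:
            for contig, _length in plan.unplaced:
                seq = contig_seqs.get(contig)
                if seq is None:
                    raise FormatError(f"no sequence for contig {contig!r}")
                _write_fasta_record(fh, contig, seq)
                lengths[contig] = len(seq)
    return lengths


# ---------------------------------------------------------------------------
# genetic map TSV

_MAP_COLUMNS = [
    "group",
    "contig",
    "orientation",
    "phys_start",
    "phys_end",
    "cM_start",
    "cM_end",
]


def write_map_tsv(map_df: pd.DataFrame, path: str | Path) -> None:
    missing = set(_MAP_COLUMNS) - set(map_df.columns)
    if missing:
        raise FormatError(f"map table missing columns: {sorted(missing)}")
    map_df[_MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_map_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
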