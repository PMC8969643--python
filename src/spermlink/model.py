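"""Model/Results interface over the two-pass linkage pipeline.

``SpermLinkageModel`` is built from a sparse per-cell allele matrix and
the contig lengths; ``fit()`` runs the full pipeline — bin markers, filter
bins, phase contigs, impute, QC and remove non-haploid cells, then a full
second pass with identical parameters on the kept cells — and returns a
``LinkageMapResults`` carrying the linkage-group map, scaffold plan,
assembly statistics, per-cell QC, and a run manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import ioforms, qccells, scaffold
from .config import Config
from .errors import ParameterError
from .genotype import BinnedGenotypes, bin_markers, filter_markers
from .ioforms import CellAlleleMatrix
from .linkmap import LinkageGroupMap, PairStats, build_linkage_map
from .phasing import end_haplotypes, impute_missing, phase_all_contigs, phase_report


@dataclass
class PassResult:
    """Intermediate products of one pipeline pass."""

    binned: BinnedGenotypes
    marker_report: dict
    phases: dict
    phase_table: pd.DataFrame


class SpermLinkageModel:
    """Linkage-map model for single-sperm genotype data.

    Parameters
    ----------
    matrix : CellAlleleMatrix
        Sparse markers x cells allele observations (vartrix convention).
    contig_lengths : mapping
        Contig id -> length in bp for every contig under analysis.
    config : Config, optional
        Pipeline parameters; defaults follow the haploid single-cell
        preset (p=0.03, b=0.03, cs=2, nl=0.9, r=4000, ldseqnum=3, ...).
    """

    def __init__(
        self,
        matrix: CellAlleleMatrix,
        contig_lengths: Mapping[str, int],
        config: Config | None = None,
    ) -> None:
        self.matrix = matrix
        self.contig_lengths = dict(contig_lengths)
        self.config = config or Config()
        missing = set(matrix.markers["contig"]) - set(self.contig_lengths)
        if missing:
            raise ParameterError(
                f"markers reference contigs without lengths: {sorted(missing)[:5]}"
            )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        mtx_path,
        barcodes_path,
        het_vcf_path,
        contigs_path,
        config: Config | None = None,
    ) -> "SpermLinkageModel":
        """Build from a vartrix matrix + barcodes + bulk het VCF + contig
        FASTA (or a contig/length TSV)."""
        markers = ioforms.read_het_sites(het_vcf_path)
        matrix = ioforms.read_allele_matrix(mtx_path, barcodes_path, markers)
        lengths = ioforms.read_contig_lengths(contigs_path)
        return cls(matrix, lengths, config)

    @classmethod
    def from_cell_vcf(
        cls, cell_vcf_path, contigs_path, config: Config | None = None
    ) -> "SpermLinkageModel":
        matrix = ioforms.read_cell_vcf(cell_vcf_path)
        lengths = ioforms.read_contig_lengths(contigs_path)
        return cls(matrix, lengths, config)

    # -- fitting -----------------------------------------------------------

    def _run_pass(self, matrix: CellAlleleMatrix, impute: bool) -> PassResult:
        cfg = self.config
        binned = bin_markers(matrix, cfg.r)
        binned, marker_report = filter_markers(binned, cfg)
        phases = phase_all_contigs(binned, cfg)
        if impute:
            for phase in phases.values():
                impute_missing(phase, cfg.ldseqnum)
                end_haplotypes(phase, cfg.end_window_bins)
        return PassResult(
            binned=binned,
            marker_report=marker_report,
            phases=phases,
            phase_table=phase_report(phases),
        )

    def fit(self, two_pass: bool = True) -> "LinkageMapResults":
        """Run the pipeline and return the fitted results.

        With ``two_pass`` (the default) non-haploid cells flagged in the
        first pass are removed and every stage is rerun with identical
        parameters on the kept cells; removed cells are never
        reintroduced.
        """
        cfg = self.config
        timings: dict[str, float] = {}
        t0 = time.perf_counter()
        pass1 = self._run_pass(self.matrix, impute=False)
        timings["pass1"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        qc = qccells.build_cell_qc(self.matrix, pass1.phases, cfg)
        kept = qccells.filter_cells(qc)
        timings["cell_qc"] = time.perf_counter() - t0

        if two_pass and len(kept) < self.matrix.n_cells:
            matrix2 = self.matrix.subset_cells(kept)
        else:
            matrix2 = self.matrix
            kept = list(self.matrix.barcodes) if not two_pass else kept
        t0 = time.perf_counter()
        pass2 = self._run_pass(matrix2, impute=True)
        timings["pass2"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        lmap, pair_stats = build_linkage_map(
            pass2.phases, self.contig_lengths, cfg
        )
        plan = scaffold.build_plan(lmap, self.contig_lengths, cfg.gap_len)
        stats = scaffold.assembly_stats(plan, self.contig_lengths)
        timings["linkage"] = time.perf_counter() - t0

        manifest = {
            "config": cfg.as_dict(),
            "n_markers": self.matrix.n_markers,
            "n_cells_input": self.matrix.n_cells,
            "n_cells_kept": len(kept),
            "cell_attrition": {
                "input": self.matrix.n_cells,
                "after_conflict_filter": int(
                    (~qc["removed_conflict"]).sum()
                ),
                "after_breakpoint_filter": len(kept),
            },
            "marker_report_pass1": pass1.marker_report,
            "marker_report_pass2": pass2.marker_report,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "stats": stats,
        }
        return LinkageMapResults(
            model=self,
            config=cfg,
            qc=qc,
            kept_cells=kept,
            map=lmap,
            pair_stats=pair_stats,
            plan=plan,
            stats=stats,
            pass1=pass1,
            pass2=pass2,
            manifest=manifest,
        )


@dataclass
class LinkageMapResults:
    """Fitted linkage map with QC, scaffolds and summaries."""

    model: SpermLinkageModel
    config: Config
    qc: pd.DataFrame
    kept_cells: list[str]
    map: LinkageGroupMap
    pair_stats: PairStats | None
    plan: scaffold.ScaffoldPlan
    stats: dict
    pass1: PassResult
    pass2: PassResult
    manifest: dict

    def summary(self) -> str:
        """Human-readable fit summary."""
        s = self.stats
        att = self.manifest["cell_attrition"]
        lines = [
            "Single-sperm linkage map",
            "=" * 64,
            f"cells: {att['input']} input -> "
            f"{att['after_conflict_filter']} after conflict filter -> "
            f"{att['after_breakpoint_filter']} kept",
            f"markers: {self.model.matrix.n_markers}  "
            f"bins (pass 2): {self.pass2.binned.n_bins}",
            f"contigs: {len(self.model.contig_lengths)} "
            f"({s['total_contig_bp']} bp)",
            f"linkage groups: {s['n_scaffolds']}  "
            f"unplaced contigs: {len(self.map.unplaced)}",
            f"placed bases: {s['placed_pct']}%   "
            f"oriented bases: {s['oriented_pct']}%",
            f"scaffold N50: {s['n50']} bp  total output: {s['total_bp']} bp",
            "-" * 64,
        ]
        gsum = self.map.summary()
        if len(gsum):
            lines.append(gsum.to_string(index=False))
        return "\n".join(lines)

    def map_table(self) -> pd.DataFrame:
        """Genetic map with scaffold (physical) coordinates."""
        df = self.map.df.copy()
        phys_start = np.zeros(len(df), dtype=np.int64)
        phys_end = np.zeros(len(df), dtype=np.int64)
        for gname in self.map.groups:
            sub = df[df["group"] == gname].sort_values("order_index")
            pos = 1
            for idx, row in sub.iterrows():
                phys_start[df.index.get_loc(idx)] = pos
                phys_end[df.index.get_loc(idx)] = pos + row["length"] - 1
                pos += row["length"] + self.config.gap_len
        df["phys_start"] = phys_start
        df["phys_end"] = phys_end
        return df

    def save(self, outdir) -> dict:
        """Write map TSV, QC TSV, stats JSON, AGP and manifest; returns
        the output paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "map": outdir / "linkage_map.tsv",
            "qc": outdir / "cell_qc.tsv",
            "stats": outdir / "stats.json",
            "agp": outdir / "scaffolds.agp",
            "manifest": outdir / "manifest.json",
            "phase_report": outdir / "phase_report.tsv",
        }
        ioforms.write_map_tsv(self.map_table(), paths["map"])
        self.qc.to_csv(paths["qc"], sep="\t", index=False)
        paths["stats"].write_text(json.dumps(self.stats, indent=2, sort_keys=True))
        ioforms.write_agp(self.plan, paths["agp"])
        paths["manifest"].write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True, default=str)
        )
        self.pass2.phase_table.to_csv(paths["phase_report"], sep="\t", index=False)
        return {k: str(v) for k, v in paths.items()}

    def write_scaffolds(self, contig_fasta, out_fasta) -> dict:
        seqs = ioforms.read_fasta_sequences(contig_fasta)
        return ioforms.write_scaffold_fasta(self.plan, seqs, out_fasta)

    def plot_map(self, path=None):
        from .plotting import plot_map

        return plot_map(self, path)
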