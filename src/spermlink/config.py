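"""Analysis configuration.

Parameter names mirror the SELDLA command-line flags so that a config file
written for one can be read side by side with the other.  The semantics as
implemented here are documented per field; see ``docs/methods.md`` for the
rationale behind each default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParameterError

# SELDLA flag name -> dataclass field name
_FLAG_ALIASES: dict[str, str] = {
    "p": "p",
    "b": "b",
    "cs": "cs",
    "nl": "nl",
    "NonZeroSampleRate": "non_zero_sample_rate",
    "NonZeroPhaseRate": "non_zero_phase_rate",
    "r": "r",
    "RateOfNotNASNP": "rate_of_not_na_snp",
    "RateOfNotNALD": "rate_of_not_na_ld",
    "ldseqnum": "ldseqnum",
    "cell_breakpoint_max": "cell_breakpoint_max",
    "conflict_rate_max": "conflict_rate_max",
    "gap_len": "gap_len",
    "end_window_bins": "end_window_bins",
    "map_function": "map_function",
    "min_group_size": "min_group_size",
}


@dataclass
class Config:
    """Tunable parameters of the linkage pipeline.

    Attributes
    ----------
    p : float
        Phase mismatch tolerance when linking adjacent bins: two bins are
        phase-linked only if the minority (discordant) fraction of shared
        informative cells is <= ``p``.
    b : float
        Consensus error tolerance for per-cell contig haplotype calls: a
        cell's contig call is NA unless the minority fraction of its
        phased-bin calls is <= ``b``.
    cs : int
        Minimum shared-cell support for a phase link, and the minimum
        discordant-cell evidence difference required to orient a contig.
    nl : float
        Linkage threshold on LD = 1 - 2r for clustering contigs into groups.
    non_zero_sample_rate : float
        Minimum fraction of cells with a non-NA call for a bin to be kept.
    non_zero_phase_rate : float
        Minimum per-cell contig-call rate for a contig to enter linkage.
    r : int
        Bin (meta-marker) width in bp; markers are aggregated into fixed
        windows of this width to combat ~0.1x per-cell sparsity.
    rate_of_not_na_snp : float
        Minimum informative (A/B) cell fraction for a bin to be kept.
    rate_of_not_na_ld : float
        Minimum shared-cell fraction for a pairwise recombination fraction
        to be considered in clustering.
    ldseqnum : int
        Number of nearby valid markers consulted when imputing a missing
        call, and the number of previous phased bins a candidate bin is
        tested against before being declared unphased.
    cell_breakpoint_max : float
        Cells whose haplotype-switch rate across adjacent informative bin
        pairs exceeds this are removed as non-haploid (strict >).
    conflict_rate_max : float
        Cells whose fraction of both-allele observations exceeds this are
        removed as likely diploid (strict >).
    gap_len : int
        N-gap length between consecutive contigs in scaffold output.
    end_window_bins : int
        Number of phased bins averaged into each contig-end haplotype call.
    map_function : str
        ``"direct"`` (cM = 100 r) or ``"haldane"`` (cM = -50 ln(1-2r)).
    min_group_size : int
        Connected components with fewer contigs are reported as unplaced.
    """

    p: float = 0.03
    b: float = 0.03
    cs: int = 2
    nl: float = 0.9
    non_zero_sample_rate: float = 0.05
    non_zero_phase_rate: float = 0.1
    r: int = 4000
    rate_of_not_na_snp: float = 0.001
    rate_of_not_na_ld: float = 0.01
    ldseqnum: int = 3
    cell_breakpoint_max: float = 0.05
    conflict_rate_max: float = 0.1
    gap_len: int = 10000
    end_window_bins: int = 5
    map_function: str = "direct"
    min_group_size: int = 2

    def __post_init__(self) -> None:
        for name in (
            "p",
            "b",
            "nl",
            "non_zero_sample_rate",
            "non_zero_phase_rate",
            "rate_of_not_na_snp",
            "rate_of_not_na_ld",
            "cell_breakpoint_max",
            "conflict_rate_max",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v!r}")
        if self.r < 1:
            raise ParameterError(f"r must be >= 1, got {self.r!r}")
        if self.ldseqnum < 1:
            raise ParameterError(f"ldseqnum must be >= 1, got {self.ldseqnum!r}")
        if self.cs < 1:
            raise ParameterError(f"cs must be >= 1, got {self.cs!r}")
        if self.end_window_bins < 1:
            raise ParameterError(
                f"end_window_bins must be >= 1, got {self.end_window_bins!r}"
            )
        if self.gap_len < 0:
            raise ParameterError(f"gap_len must be >= 0, got {self.gap_len!r}")
        if self.map_function not in ("direct", "haldane"):
            raise ParameterError(
                f"map_function must be 'direct' or 'haldane', got {self.map_function!r}"
            )
        if self.min_group_size < 1:
            raise ParameterError(
                f"min_group_size must be >= 1, got {self.min_group_size!r}"
            )

    # -- serialisation -----------------------------------------------------

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Read a ``key = value`` config file using SELDLA flag names.

        Lines starting with ``#`` and blank lines are ignored.  Field names
        of this class are accepted as well as the flag aliases.
        """
        values: dict[str, object] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(
                    f"{path}:{lineno}: expected 'key = value', got {raw!r}"
                )
            key, _, val = (s.strip() for s in line.partition("="))
            name = _FLAG_ALIASES.get(key, key)
            if name not in fields:
                raise ParameterError(f"{path}:{lineno}: unknown parameter {key!r}")
            ftype = fields[name].type
            try:
                if ftype in ("int", int):
                    values[name] = int(val)
                elif ftype in ("float", float):
                    values[name] = float(val)
                else:
                    values[name] = val
            except ValueError as exc:
                raise ParameterError(f"{path}:{lineno}: bad value {val!r}") from exc
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        inverse = {v: k for k, v in _FLAG_ALIASES.items()}
        lines = [
            f"{inverse[f.name]} = {getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")
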