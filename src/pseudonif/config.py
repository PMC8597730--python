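"""Analysis configuration shared by every pipeline stage.

All thresholds that drive a decision anywhere in the package live in
:class:`AnalysisConfig` so that a run can be reproduced from its manifest
alone.  Defaults follow the published protocol this package reimplements:
a 10-CDS same-strand neighborhood for operon typing, a 95% genome
completeness floor, 90%/95% identity thresholds for partial-sequence
mapping, USEARCH-style read merging (max 5 differences, min 20-base
overlap), an expected-error budget of 0.5 per read, a 200-base minimum
merged length, a 2.5M read cap per sample, 95%-of-maximum hit retention
for read typing, and 99% Poisson confidence intervals for the
gene-length proportionality test.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import yaml

logger = logging.getLogger("pseudonif")


@dataclass
class AnalysisConfig:
    # --- genome census ---
    neighborhood_radius: int = 10          # CDSs up/downstream, same strand
    completeness_min: float = 0.95         # inclusive ("95% or higher")

    # --- confusability / mapping ---
    identity_thresholds: tuple[float, ...] = (0.90, 0.95)
    subseq_lengths: tuple[int, ...] = (40, 60, 80, 100)   # amino acids
    subseqs_per_length: int = 10
    msa_window: int = 40                   # MSA columns per window
    msa_window_starts: tuple[int, ...] = (31, 71, 111, 151, 191, 231, 271)
    min_window_residues: int = 20          # degapped floor for a window row
    cluster_identity: float = 0.95         # greedy clustering threshold

    # --- read QC ---
    merge_max_diffs: int = 5
    merge_min_overlap: int = 20
    max_expected_errors: float = 0.5       # strict: sum(p) < max_ee
    min_merged_length: int = 200           # bases, inclusive
    reads_cap: int = 2_500_000

    # --- metagenome screen ---
    stage1_min_identity: float = 0.5
    stage1_min_cols: int = 30
    stage2_min_identity: float = 0.6
    min_peptide_fragment: int = 20         # aa; translated fragments below are dropped
    hit_retention_factor: float = 0.95
    retention_mode: str = "multiplicative"  # or "subtractive" (s >= s_max - 0.05)

    # --- proportionality test ---
    gene_length_H: int = 1497              # bp, nifH
    gene_length_D: int = 894               # bp, nifD
    gene_length_K: int = 1560              # bp, nifK (typical; not fixed by protocol)
    ci_level: float = 0.99

    # --- alignment scoring ---
    gap_open: float = -11.0
    gap_extend: float = -1.0
    matrix_name: str = "BLOSUM62"
    identity_denominator: str = "exclude_terminal_gaps"  # or "all_columns"

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness_min <= 1.0:
            raise ValueError("completeness_min must be in [0, 1]")
        if self.neighborhood_radius < 0:
            raise ValueError("neighborhood_radius must be >= 0")
        for t in self.identity_thresholds:
            if not 0.0 <= t <= 1.0:
                raise ValueError("identity thresholds must be in [0, 1]")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.retention_mode not in ("multiplicative", "subtractive"):
            raise ValueError("retention_mode must be multiplicative|subtractive")
        if self.identity_denominator not in ("exclude_terminal_gaps", "all_columns"):
            raise ValueError(
                "identity_denominator must be exclude_terminal_gaps|all_columns"
            )

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def header_comment(self) -> str:
        """One-line ``# key=value ...`` comment for output TSV headers."""
        items = " ".join(f"{k}={v}" for k, v in self.to_dict().items())
        return f"# config: {items}"


DEFAULT_CONFIG = AnalysisConfig()
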