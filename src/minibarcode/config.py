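"""Declarative run configuration for the CLI.

One YAML document holds every tunable default; CLI flags override config
values, which override the built-in defaults.  Unknown keys are rejected so
typos fail loudly.  Every run logs the fully resolved configuration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ContractError

#: Parameters of the heuristic local-alignment search the original analysis
#: used, recorded for provenance only; this package computes exact
#: end-gap-free alignments and no E-value statistics.
BLASTN_PROVENANCE = {"evalue": 10, "word_size": 11, "gapopen": 5, "gapextend": 2}


@dataclass
class RunConfig:
    # alignment profiling
    conservation_statistic: str = "modal"
    block_min_len: int = 18
    block_min_col_score: float = 0.9
    block_max_gap_fraction: float = 0.1
    loop_min_len: int = 40
    loop_max_len: int = 120
    # primer design
    primer_len_min: int = 18
    primer_len_max: int = 27
    amplicon_len_min: int = 100
    amplicon_len_max: int = 140
    max_degeneracy: int = 8
    minor_allele_floor: float = 0.10
    dimer_flag_threshold: int = 5
    # blocking oligo
    blocker_min_target_mismatches: int = 4
    blocker_len_min: int = 25
    blocker_len_max: int = 40
    blocker_primer_site_max_mismatch: int = 2
    # in-silico PCR
    max_mismatch_total: int = 2
    clamp_3prime: int = 3
    max_product_length: int = 2000
    blocker_max_mismatch: int = 0
    # identification
    identity_threshold: float = 97.0
    tie_margin: float = 0.5
    min_replicate_identity: float = 80.0
    # I/O and reproducibility
    header_scheme: str = "id_species"
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config, rejecting unknown keys; None gives the defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ContractError("config file must contain a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ContractError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
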