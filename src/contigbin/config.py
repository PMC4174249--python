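"""Pipeline configuration: the thresholds and conventions of every stage.

Defaults mirror the selection rules the pipeline is built around:
strict E-value cutoffs of 1e-10 for global nucleotide/protein databases
and 1e-5 for rRNA databases, a 100 nt contig floor, family-level
reporting with class-level grouping, and a 90% cumulative-abundance
cutoff for the "major families" listing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import IO, Any

import yaml

from .taxonomy import DEFAULT_EXCLUSION_TERMS

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration value or file (message names the field)."""


@dataclass
class PipelineConfig:
    #: strict E-value cutoff for nt/nr-style (global) database hits
    evalue_max_global: float = 1e-10
    #: strict E-value cutoff for rRNA-database hits
    evalue_max_rrna: float = 1e-5
    #: minimum contig length retained (assembler floor; inclusive)
    min_contig_len: int = 100
    #: cumulative-proportion cutoff selecting the "major" taxa
    cumulative_frac: float = 0.90
    #: LCA bitscore window: hits within this % of the best are candidates
    lca_top_percent: float = 10.0
    #: rank at which abundance profiles are reported
    report_rank: str = "family"
    #: rank used to group rows in comparisons and gene-taxon tables
    group_rank: str = "class"
    #: name substrings excluding a subject from best-hit taxonomy
    exclusion_terms: tuple[str, ...] = DEFAULT_EXCLUSION_TERMS
    #: seed driving every stochastic draw (simulation)
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if self.evalue_max_global <= 0:
            raise ConfigError("evalue_max_global must be > 0")
        if self.evalue_max_rrna <= 0:
            raise ConfigError("evalue_max_rrna must be > 0")
        if self.min_contig_len <= 0:
            raise ConfigError("min_contig_len must be > 0")
        if not 0.0 < self.cumulative_frac <= 1.0:
            raise ConfigError("cumulative_frac must be in (0, 1]")
        if self.lca_top_percent < 0:
            raise ConfigError("lca_top_percent must be >= 0")
        self.exclusion_terms = tuple(self.exclusion_terms)

    @classmethod
    def from_yaml(cls, source: str | Path | IO[str]) -> "PipelineConfig":
        """Load a config from a flat-key YAML file; unknown keys error."""
        if isinstance(source, (str, Path)):
            with open(source, "rt", encoding="utf-8") as fh:
                data = yaml.safe_load(fh) or {}
        else:
            data = yaml.safe_load(source) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["exclusion_terms"] = list(self.exclusion_terms)
        return d

    def to_yaml(self, destination: str | Path | IO[str]) -> None:
        if isinstance(destination, (str, Path)):
            with open(destination, "wt", encoding="utf-8") as fh:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        else:
            yaml.safe_dump(self.to_dict(), destination, sort_keys=True)
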