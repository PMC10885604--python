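"""Run configuration: one object carrying every stage parameter.

Defaults follow the published analysis settings where they exist: 50-nt
windows with a 25-nt step, a >20 mean-mismatch window filter, top-5 %-median
normalization, 10 % deciles, a 0.4 average-Gini threshold for the stability
comparisons, and 100-nt stop-codon flanks for the meta-gene profile.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional


@dataclass
class RunConfig:
    mode: str = "genomewide"           # 'amplicon' | 'genomewide'
    # stage parameters
    window_size: int = 50
    step: int = 25
    mismatch_threshold: float = 20.0
    top_fraction: float = 0.05
    q: float = 0.10
    gini_threshold: float = 0.4
    flank: int = 100
    min_coverage: Optional[int] = None  # default depends on mode
    ac_only: bool = True
    background_method: str = "subtract"
    seed: int = 0
    # paths
    input_dir: Optional[str] = None
    output_dir: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("amplicon", "genomewide"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_coverage is None:
            # amplicon libraries are deep over one target; transcriptome-wide
            # coverage is thinner, so the per-base floor is relaxed
            self.min_coverage = 100 if self.mode == "amplicon" else 20

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
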