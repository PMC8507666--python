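"""Declarative pipeline configuration.

Every tunable threshold of the pipeline lives here with its default:

``min_reads``
    Uniquely-mapped read floor for QC; strictly greater-than comparison.
``reported_reads_tier``
    Secondary, higher read tier reported alongside (not used for exclusion).
``positivity_tpm``
    TPM at or above which a marker gene counts as expressed (contaminant
    calling and CTC-type positivity alike).
``k_epithelial`` / ``k_emt_stem``
    Number of clusters cut from the two marker dendrograms.
``score_method``
    ``"sum"`` (default) or ``"mean"`` of log10(TPM+1) over a panel.
``line_filter``
    Minimum treatment line for the stratified survival analysis.
``emt_burden_threshold``
    CTC count at/above which a patient is called high-burden in the
    headline EMT stratification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    min_reads: int = 100_000
    reported_reads_tier: int = 400_000
    positivity_tpm: float = 1.0
    k_epithelial: int = 3
    k_emt_stem: int = 4
    score_method: str = "sum"
    alpha_levels: Tuple[float, float] = (0.05, 0.01)
    line_filter: int = 2
    emt_burden_threshold: int = 2
    exclusive_emt_rule: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ConfigurationError("min_reads must be >= 0")
        if self.positivity_tpm < 0:
            raise ConfigurationError("positivity_tpm must be >= 0")
        if self.score_method not in {"sum", "mean"}:
            raise ConfigurationError("score_method must be 'sum' or 'mean'")
        if self.k_epithelial < 1 or self.k_emt_stem < 1:
            raise ConfigurationError("cluster counts must be >= 1")
        if self.line_filter < 1:
            raise ConfigurationError("line_filter must be >= 1")
        self.alpha_levels = tuple(sorted(self.alpha_levels, reverse=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known - {"simulation"}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = dataclasses.asdict(self)
        data["alpha_levels"] = list(self.alpha_levels)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def load_config(path: Optional[Union[str, Path]] = None,
                seed: Optional[int] = None) -> PipelineConfig:
    cfg = PipelineConfig.from_yaml(path) if path else PipelineConfig()
    if seed is not None:
        cfg.seed = int(seed)
    return cfg
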