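"""Run configuration: paths, plex, channel pairs and algorithm choice.

A run is described by a YAML file (keys mirror the dataclass fields);
command-line flags override file values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields
from typing import Optional

import yaml

from .model import AlgorithmCombination, ChannelPair
from .pipeline import QuantOptions


@dataclass
class RunConfig:
    """Everything one quantitation run needs."""

    spectra: str = ""
    identifications: str = ""  # pepXML or PSM TSV
    proteins: str = ""  # protXML or protein TSV (optional)
    matrix: str = ""  # plex preset name or CSV path
    plex: str = "TMT-6"
    pairs: list[str] = field(default_factory=list)
    ground_truth: str = ""
    out_dir: str = "plexquant_out"

    peptide_kernel: str = "MedianPsmRatio"
    protein_kernel: str = "MedianPepRatio"
    normalization: str = "none"
    rcc_enabled: bool = False

    fdr_threshold: float = 0.01
    reporter_tolerance_th: float = 0.002
    s2i_kmax: int = 3
    s2i_match_ppm: float = 10.0
    unique_peptides_only: bool = True
    require_complete_channels: bool = False
    psm_weight_mode: str = "pair"

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def combination(self) -> AlgorithmCombination:
        return AlgorithmCombination(
            self.peptide_kernel, self.protein_kernel, self.normalization, self.rcc_enabled
        )

    def channel_pairs(self) -> list[ChannelPair]:
        return [ChannelPair.parse(p) for p in self.pairs]

    def quant_options(self) -> QuantOptions:
        return QuantOptions(
            fdr_threshold=self.fdr_threshold,
            reporter_tolerance_th=self.reporter_tolerance_th,
            s2i_kmax=self.s2i_kmax,
            s2i_match_ppm=self.s2i_match_ppm,
            unique_peptides_only=self.unique_peptides_only,
            require_complete_channels=self.require_complete_channels,
            psm_weight_mode=self.psm_weight_mode,
        )

    def validate_paths(self) -> None:
        for name in ("spectra", "identifications"):
            path = getattr(self, name)
            if not path or not os.path.exists(path):
                raise FileNotFoundError(f"{name} file not found: {path!r}")
        for name in ("proteins", "ground_truth"):
            path = getattr(self, name)
            if path and not os.path.exists(path):
                raise FileNotFoundError(f"{name} file not found: {path!r}")
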