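"""Run configuration: every threshold used by a pipeline rule, in one place."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import yaml

log = logging.getLogger("m6akit.config")

DEFAULT_STAGES = ["GV", "MII", "1C", "2C", "8C", "BLT"]


@dataclass
class RunConfig:
    bin_size: int = 10
    similarity_window: int = 1000
    stages: List[str] = field(default_factory=lambda: list(DEFAULT_STAGES))
    replicates: int = 2
    seed: int = 0

    # rule thresholds, as printed
    tpm_expressed_min: float = 1.0        # floor for m6A gene calls
    mdecay_gv_tpm_min: float = 10.0       # TPM > 10 in GV
    zga_oocyte_tpm_max: float = 1.0       # TPM < 1 in GV and MII
    zga_8c_tpm_min: float = 10.0          # TPM > 10 at 8C
    constant_tpm_min: float = 10.0        # TPM >= 10 in all samples
    entropy_max: float = 0.5              # entropy specificity < 0.5
    coexpressed_tpm_min: float = 50.0     # TPM >= 50 in both species
    species_specific_tpm_max: float = 10.0
    mirna_rpm_min: float = 10.0           # RPM >= 10
    te_fpkm_min: float = 10.0             # mRNA FPKM >= 10
    completeness_min: float = 0.9         # repeat completeness >= 0.9

    # naive caller + structural knobs
    peak_threshold: float = 1.0
    peak_min_bins: int = 3
    peak_merge_gap: int = 1
    stop_codon_flank: int = 200
    fl_erv_gap: int = 500
    element_profile_bins: int = 100
    exon_level_intersection: bool = True
    strand_aware: bool = False

    def validate(self) -> None:
        positive = [
            "bin_size", "similarity_window", "tpm_expressed_min", "mdecay_gv_tpm_min",
            "zga_oocyte_tpm_max", "zga_8c_tpm_min", "constant_tpm_min", "entropy_max",
            "coexpressed_tpm_min", "species_specific_tpm_max", "mirna_rpm_min",
            "te_fpkm_min", "completeness_min", "peak_threshold",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be positive")
        if self.similarity_window % self.bin_size:
            raise ValueError("config: bin_size must divide similarity_window")
        if self.replicates < 1:
            raise ValueError("config: need at least one replicate")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        unknown = set(raw) - known
        if unknown - {"simulate", "paths", "outdir"}:
            log.info("config: ignoring unknown keys %s", sorted(unknown))
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def echo(self) -> str:
        return "; ".join(f"{k}={v}" for k, v in dataclasses.asdict(self).items())
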