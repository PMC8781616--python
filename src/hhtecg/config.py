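"""Runtime configuration for the featuring pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Featuring-chain parameters, logged with every scan for auditability.

    Defaults: 5th-order 16 Hz zero-phase low-pass; EMD Cauchy stop 0.2 with at
    most 10 modes and 100 sifts per mode; marginal spectra on a 0–20 Hz grid at
    0.05 Hz resolution using amplitude-based energy.
    """

    filter_order: int = 5
    filter_cutoff_hz: float = 16.0
    emd_stop_sd: float = 0.2
    emd_max_imfs: int = 10
    emd_max_sifts: int = 100
    mhs_bin_hz: float = 0.05
    mhs_fmax_hz: float = 20.0
    mhs_energy: str = "amplitude"  # or "squared" for a^2-based energy

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
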