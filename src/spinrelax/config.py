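"""Pipeline configuration: one YAML file holding every tunable threshold.

CLI flags override config values; the effective config (and its hash) is
logged by every subcommand so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    # spin-pair defaults (15N backbone amide)
    r_nh: float = 1.02          # Angstrom
    delta_sigma: float = -164.0  # ppm
    beta: float = 18.0           # degrees

    # noise / error model
    noise_rate_frac: float = 0.02
    noise_noe: float = 0.02
    cpmg_sigma: float = 0.4      # 1/s
    r1rho_noise_frac: float = 0.03
    mc_draws: int = 100

    # filters
    noe_cutoff: float = 0.65
    alignment_ratio_max: float = 0.4   # |w_off|/w_SL for on-resonance R1rho
    chi2_ratio_cutoff: float = 2.0     # chi2_g/chi2_i exclusion
    trim_sd: float = 1.5               # R2/R1 trimming for tau_c

    # fit options
    aicc: bool = False
    seed: int = 0
    fields_mhz: list = field(default_factory=lambda: [750.0, 900.0])
    rate_field_mhz: float = 700.0

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
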