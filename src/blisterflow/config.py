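"""Pipeline configuration.

All physical and numerical defaults are the study conditions this package
reproduces: blood viscosity 0.0035 Pa s and density 1056 kg/m^3, inlet
flow 4e-6 m^3/s, outlet mean arterial pressure 90 mmHg, 25 cells per lumen
diameter, under-relaxation 0.3 (pressure) / 0.7 (velocity), residual
tolerance 1e-5, 100 validation slices and 300 bootstrap iterations.
Configuration layers: built-in defaults < config file (JSON or YAML) <
explicit keyword overrides.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    # fluid
    dynamic_viscosity: float = 0.0035  # Pa s
    density: float = 1056.0  # kg/m^3
    gravity: float = 9.81  # m/s^2

    # boundary conditions
    flow_rate: float = 4.0e-6  # m^3/s
    outlet_pressure_mmhg: float = 90.0  # MAP

    # discretization / solver
    cells_per_diameter: int = 25
    relax_pressure: float = 0.3
    relax_velocity: float = 0.7
    residual_tol: float = 1.0e-5
    max_iter: int = 8000
    stokes: bool = False

    # validation
    n_slices: int = 100
    n_bootstrap: int = 300
    band_k_sd: float = 1.0

    # synthetic geometry
    vessel_diameter_mm: float = 4.0
    vessel_length_mm: float = 30.0
    n_centerline_samples: int = 200
    n_circumferential: int = 32
    pixel_spacing_mm: float = 0.05
    oblique_angle_deg: float = 40.0
    blister_height_mm: float = 0.6
    blister_t0: float = 0.5
    blister_longitudinal_mm: float = 3.5
    blister_circumferential_deg: float = 110.0

    # analysis thresholds
    wss_high_pa: float = 10.0
    wss_low_pa: float = 0.4
    wss_normal_ref_pa: float = 2.0
    recirculation_threshold: float = 0.25
    inlet_exclusion_diameters: float = 1.0

    # reproducibility
    seed: int = 0
    stage_seeds: dict = field(default_factory=dict)

    def seed_for(self, stage: str) -> int:
        """Stable per-stage seed derived from the master seed."""
        if stage in self.stage_seeds:
            return int(self.stage_seeds[stage])
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31 - 1)

    # -- IO ----------------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        data.update(overrides)
        return cls(**data)
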