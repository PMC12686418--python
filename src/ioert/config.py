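"""Run configuration: schema-validated TOML with physics-backed defaults.

A minimal file needs only the nominal beam energy; every other field is
filled from the commissioning defaults below (tuned source parameters per
nominal energy, reference z_max table, 3%/3 mm gamma criteria, 21 Gy
prescription).  Unknown keys are rejected by name.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from typing import Literal

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

#: tuned source spectrum per nominal energy [MeV]: (mean energy, sigma)
NOMINAL_BEAMS: dict[int, tuple[float, float]] = {
    6: (7.2, 0.7),
    9: (9.8, 0.9),
    12: (12.35, 1.2),
}

#: reference depth of maximum per nominal energy [mm]
ZMAX_TABLE_MM: dict[int, float] = {6: 13.0, 9: 18.0, 12: 22.0}

DEFAULT_SPOT_FWHM_MM = 1.6
DEFAULT_DIVERGENCE_DEG = 0.0


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class BeamConfig(_Section):
    energy: int = 9  # nominal label (6 | 9 | 12)
    mean_energy: float | None = None  # MeV; default from NOMINAL_BEAMS
    sigma_e: float | None = None
    spot_fwhm: float = DEFAULT_SPOT_FWHM_MM
    divergence: float = DEFAULT_DIVERGENCE_DEG

    @model_validator(mode="after")
    def _fill_defaults(self):
        if self.mean_energy is None or self.sigma_e is None:
            if self.energy not in NOMINAL_BEAMS:
                raise ValueError(
                    f"beam.energy must be one of {sorted(NOMINAL_BEAMS)} "
                    "unless mean_energy and sigma_e are given")
            mean, sig = NOMINAL_BEAMS[self.energy]
            if self.mean_energy is None:
                self.mean_energy = mean
            if self.sigma_e is None:
                self.sigma_e = sig
        return self


class MachineConfig(_Section):
    ssd_mm: float = 500.0
    ssf_density: float = 2.70  # g/cm^3


class ApplicatorConfig(_Section):
    diameter_cm: float = 10.0
    bevel_deg: float = 0.0
    length_cm: float = 20.0
    wall_material: str = "aluminum"
    air_gap_cm: float = 0.0


class PhantomConfig(_Section):
    kind: Literal["water", "thorax"] = "water"
    side_mm: float = 140.0
    depth_mm: float = 80.0
    spacing_mm: float = 1.0
    voxel_mm: float = 2.0  # thorax phantom pitch


class TransportSection(_Section):
    n_histories: int = 1_000_000
    seed: int = 0
    max_step_mm: float = 1.0
    energy_cutoff_mev: float = 0.2
    energy_straggling: float = 0.11
    ms_scale: float = 1.7


class AnalysisConfig(_Section):
    gamma_dose_pct: float = 3.0
    gamma_dta_mm: float = 3.0
    gamma_low_dose_threshold: float | None = None
    prescription_gy: float = 21.0
    zmax_mm: dict[int, float] = dict(ZMAX_TABLE_MM)
    pdd_scoring_mm: tuple[float, float, float] = (6.0, 6.0, 1.0)
    profile_scoring_mm: tuple[float, float, float] = (1.0, 3.0, 6.0)


class RunConfig(_Section):
    beam: BeamConfig = BeamConfig()
    machine: MachineConfig = MachineConfig()
    applicator: ApplicatorConfig = ApplicatorConfig()
    phantom: PhantomConfig = PhantomConfig()
    transport: TransportSection = TransportSection()
    analysis: AnalysisConfig = AnalysisConfig()

    # -- builders ----------------------------------------------------------

    def beam_source(self):
        from .beam import BeamSource

        return BeamSource(self.beam.mean_energy, self.beam.sigma_e,
                          self.beam.spot_fwhm, self.beam.divergence)

    def applicator_obj(self):
        from .beam import Applicator

        return Applicator(self.applicator.diameter_cm, self.applicator.bevel_deg,
                          self.applicator.wall_material, self.applicator.length_cm)

    def machine_geometry(self):
        from .beam import build_machine, default_stack

        stack = default_stack().with_ssf_density(self.machine.ssf_density)
        return build_machine(stack, self.applicator_obj(),
                             ssd_mm=self.machine.ssd_mm,
                             air_gap_mm=self.applicator.air_gap_cm * 10.0)

    def transport_config(self):
        from .transport import TransportConfig

        t = self.transport
        return TransportConfig(max_step=t.max_step_mm,
                               energy_cutoff=t.energy_cutoff_mev,
                               seed=t.seed, n_histories=t.n_histories,
                               energy_straggling=t.energy_straggling,
                               ms_scale=t.ms_scale)

    def phantom_spec(self):
        from .transport import water_phantom

        p = self.phantom
        if p.kind != "water":
            raise ValueError("phantom_spec() builds water phantoms; "
                             "use ioert.phantom.build_thorax_phantom for 'thorax'")
        return water_phantom(p.side_mm, p.depth_mm, p.spacing_mm)

    def gamma_criteria(self):
        from .gamma import GammaCriteria

        a = self.analysis
        return GammaCriteria(a.gamma_dose_pct, a.gamma_dta_mm,
                             a.gamma_low_dose_threshold)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class ConfigError(ValueError):
    pass


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration, filling defaults."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        # name the offending key explicitly
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"invalid configuration at {loc!r}: {first['msg']}") from exc


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def dump_config(config: RunConfig) -> str:
    """Serialize back to TOML (load -> dump -> load is the identity)."""
    lines = []
    for section, values in config.model_dump().items():
        lines.append(f"[{section}]")
        for key, val in values.items():
            if val is None:
                continue
            if isinstance(val, dict):
                inner = ", ".join(f'"{k}" = {_toml_value(v)}' for k, v in val.items())
                lines.append(f"{key} = {{ {inner} }}")
            else:
                lines.append(f"{key} = {_toml_value(val)}")
        lines.append("")
    return "\n".join(lines)
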