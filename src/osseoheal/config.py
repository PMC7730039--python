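"""Run configuration: defaults, YAML loading, and model building.

All defaults reproduce the study constants: 0.05 mm mesh, a = 0.0375,
b = 3 um/s, smoothing window 10, 35 healing days, 8 um settlement,
friction coefficient 0.3, and the standard tissue property table.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

from .fem import InterfaceSpec, LoadCase
from .geometry import ChamberParams, ImplantSpec, catalog_implants, generate_mesh
from .materials import TISSUE_PROPERTIES, MaterialProperties

__all__ = ["RunConfig", "load_config", "save_config", "build_model", "config_hash"]


@dataclass
class RunConfig:
    implant: str = "single_chamber"  # catalog label, "single_chamber", or custom
    chamber: dict | None = None  # explicit ChamberParams fields (overrides label)
    element_size: float = 0.05  # mm
    implant_element_factor: float = 2.0  # coarsening inside the rigid implant
    far_field_growth: float = 1.0  # >1 grades the host bone away from the callus
    days: int = 35
    stimulus_a: float = 0.0375
    stimulus_b: float = 3.0  # um/s
    smoothing_window: int = 10
    diffusivity: float | str = "calibrate"  # mm^2/day or "calibrate"
    saturation_threshold: float = 0.99
    load_displacement_um: float = 8.0
    ramp_duration: float = 1.0  # s
    n_time_steps: int = 10
    interface_mode: str = "coulomb_penalty"  # or "tied"
    friction_coefficient: float = 0.3
    penalty_stiffness: float = 1.0e5  # MPa/mm
    material_overrides: dict = field(default_factory=dict)
    cortical_thickness: float | None = None  # None -> geometry default
    callus_margin: float | None = None
    domain_extent: tuple[float, float] | None = None
    core_radius: float | None = None
    collar_length: float | None = None
    tip_length: float | None = None
    output_dir: str = "runs"
    seed: int = 0  # reserved; the pipeline is deterministic

    def load_case(self) -> LoadCase:
        return LoadCase(self.load_displacement_um, self.ramp_duration,
                        self.n_time_steps)

    def interface(self) -> InterfaceSpec:
        return InterfaceSpec(self.interface_mode, self.friction_coefficient,
                             self.penalty_stiffness)

    def material_table(self) -> dict[str, MaterialProperties]:
        table = dict(TISSUE_PROPERTIES)
        for name, over in self.material_overrides.items():
            if name not in table:
                raise KeyError(f"material_overrides: unknown tissue '{name}'")
            table[name] = table[name].with_values(**over)
        return table


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Read a YAML config; unknown keys raise naming the offender."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    cfg = RunConfig(**data)
    if isinstance(cfg.domain_extent, list):
        cfg.domain_extent = tuple(cfg.domain_extent)
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    if cfg.element_size <= 0:
        raise ValueError("config key element_size must be > 0")
    if cfg.days < 1:
        raise ValueError("config key days must be >= 1")
    if cfg.smoothing_window < 1:
        raise ValueError("config key smoothing_window must be >= 1")
    if cfg.interface_mode not in ("tied", "coulomb_penalty"):
        raise ValueError("config key interface_mode must be tied|coulomb_penalty")
    if isinstance(cfg.diffusivity, str) and cfg.diffusivity != "calibrate":
        raise ValueError("config key diffusivity must be a number or 'calibrate'")


def save_config(cfg: RunConfig, path) -> None:
    data = dataclasses.asdict(cfg)
    if isinstance(data.get("domain_extent"), tuple):
        data["domain_extent"] = list(data["domain_extent"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    data = dataclasses.asdict(cfg)
    if isinstance(data.get("domain_extent"), tuple):
        data["domain_extent"] = list(data["domain_extent"])
    canon = yaml.safe_dump(data, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


#: compact single-chamber reference geometry used for tests and calibration:
#: a smooth neck passing through the cortical plate, one healing chamber in
#: cancellous bone, and the tip seated on host bone
TOY_SPEC = ImplantSpec(
    ChamberParams(depth_d=0.3, upper_flank_angle_phi=60.0,
                  lower_flank_angle=60.0, root_length_r=0.1,
                  crest_length_c=0.1, pitch=0.8, n_threads=1),
    core_radius=1.0, collar_length=1.0, tip_length=0.2,
    cortical_thickness=0.8, callus_margin=0.35, domain_extent=(2.0, 3.0),
)


def implant_spec(cfg: RunConfig) -> ImplantSpec:
    if cfg.chamber is not None:
        base = TOY_SPEC if cfg.implant == "single_chamber" \
            else catalog_implants()[cfg.implant]
        params = ChamberParams(**cfg.chamber)
        base = dataclasses.replace(base, params=params)
    elif cfg.implant == "single_chamber":
        base = TOY_SPEC
    elif cfg.implant.startswith("analog-"):
        from .geometry import analog_implants

        base = analog_implants()[cfg.implant.split("-", 1)[1]]
    else:
        try:
            base = catalog_implants()[cfg.implant]
        except KeyError:
            raise KeyError(f"unknown implant label '{cfg.implant}'") from None
    over = {}
    for name in ("core_radius", "collar_length", "tip_length",
                 "cortical_thickness", "callus_margin", "domain_extent"):
        val = getattr(cfg, name)
        if val is not None:
            over[name] = tuple(val) if name == "domain_extent" else val
    return dataclasses.replace(base, **over) if over else base


def build_model(cfg: RunConfig):
    """(mesh, layout, load, interface, table) for a run configuration."""
    spec = implant_spec(cfg)
    layout = spec.layout()
    mesh = generate_mesh(layout, cfg.element_size, cfg.implant_element_factor,
                         cfg.far_field_growth)
    return mesh, layout, cfg.load_case(), cfg.interface(), cfg.material_table()
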