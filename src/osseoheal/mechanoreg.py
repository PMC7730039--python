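"""Mechano-regulatory tissue differentiation around the implant.

The healing loop couples the poroelastic day-load solve with stem-cell
diffusion: local octahedral shear strain gamma and interstitial fluid speed
nu are collapsed into the scalar stimulus

    S = gamma / a + nu / b,      a = 0.0375,  b = 3 um/s,

which classifies each callus element into a tissue phenotype:

    fibrous tissue   S > 3
    cartilage        3 >= S > 1
    immature bone    1 >= S > 0.266
    mature bone      0.266 >= S > 0.010
    resorption       0.010 >= S

Element properties then blend linearly between granulation tissue and the
differentiated phenotype with the local stem-cell concentration, and are
smoothed over a ten-iteration moving window (the current mixed value plus
the nine previous smoothed values) to avoid abrupt material jumps.  One
iteration represents one healing day; a standard run is 35 days.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import diffusion as _diff
from . import fem as _fem
from . import morphometry as _morph
from .materials import TISSUE_PROPERTIES, REGION_MATERIALS, MaterialProperties

__all__ = [
    "StimulusConstants",
    "Phenotype",
    "MaterialField",
    "DayRecord",
    "HealingHistory",
    "stimulus",
    "classify",
    "classify_array",
    "mixed_properties",
    "smooth_properties",
    "run_healing",
]


@dataclass(frozen=True)
class StimulusConstants:
    """Solid and fluid stimulus normalisation constants."""

    a: float = 0.0375  # dimensionless strain constant
    b: float = 3.0  # um/s

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("stimulus constants a, b must be positive")


class Phenotype(str, enum.Enum):
    FIBROUS_TISSUE = "fibrous_tissue"
    CARTILAGE = "cartilage"
    IMMATURE_BONE = "immature_bone"
    MATURE_BONE = "mature_bone"
    RESORPTION = "resorption"
    GRANULATION = "granulation"


#: classification boundaries, upper end closed for the lower class
S_FIBROUS = 3.0
S_CARTILAGE = 1.0
S_IMMATURE = 0.266
S_MATURE = 0.010

#: property-table entry backing each phenotype; resorbed tissue reverts to
#: the softest (granulation) state and is counted as non-bone downstream.
PHENOTYPE_TABLE_KEY = {
    Phenotype.FIBROUS_TISSUE: "fibrous_tissue",
    Phenotype.CARTILAGE: "cartilage",
    Phenotype.IMMATURE_BONE: "immature_bone",
    Phenotype.MATURE_BONE: "mature_bone",
    Phenotype.RESORPTION: "granulation",
    Phenotype.GRANULATION: "granulation",
}


def stimulus(gamma_oct, nu, constants: StimulusConstants = StimulusConstants()):
    """S = gamma/a + nu/b (scalar or array)."""
    g = np.asarray(gamma_oct, dtype=float)
    v = np.asarray(nu, dtype=float)
    if np.any(g < 0) or np.any(v < 0):
        raise ValueError("stimulus inputs gamma_oct and nu must be >= 0")
    s = g / constants.a + v / constants.b
    return float(s) if s.ndim == 0 else s


def classify(S: float) -> Phenotype:
    """Phenotype for one stimulus value with exact boundary semantics."""
    if S < 0:
        raise ValueError("stimulus must be >= 0")
    if S > S_FIBROUS:
        return Phenotype.FIBROUS_TISSUE
    if S > S_CARTILAGE:
        return Phenotype.CARTILAGE
    if S > S_IMMATURE:
        return Phenotype.IMMATURE_BONE
    if S > S_MATURE:
        return Phenotype.MATURE_BONE
    return Phenotype.RESORPTION


def classify_array(S: np.ndarray) -> np.ndarray:
    """Vectorised classification; returns phenotype value strings."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("stimulus must be >= 0")
    codes = ((S > S_MATURE).view(np.int8) + (S > S_IMMATURE).view(np.int8)
             + (S > S_CARTILAGE).view(np.int8) + (S > S_FIBROUS).view(np.int8))
    labels = np.array([Phenotype.RESORPTION.value, Phenotype.MATURE_BONE.value,
                       Phenotype.IMMATURE_BONE.value, Phenotype.CARTILAGE.value,
                       Phenotype.FIBROUS_TISSUE.value], dtype="<U16")
    return labels[codes]


def mixed_properties(phenotype: Phenotype, n_i: float, n_max: float = 1.0,
                     table: dict[str, MaterialProperties] | None = None,
                     ) -> MaterialProperties:
    """Concentration-weighted blend of granulation and phenotype properties.

    X_mix = (n_max - n_i)/n_max * X_g + n_i/n_max * X_d for Young's modulus,
    Poisson ratio and permeability alike.
    """
    if not (0.0 <= n_i <= n_max):
        raise ValueError(f"concentration n_i={n_i} outside [0, n_max={n_max}]")
    table = table or TISSUE_PROPERTIES
    key = PHENOTYPE_TABLE_KEY.get(Phenotype(phenotype))
    if key is None or key not in table:
        raise KeyError(f"no property-table entry for phenotype {phenotype}")
    g = table["granulation"]
    d = table[key]
    w = n_i / n_max
    return MaterialProperties(
        young_modulus=(1 - w) * g.young_modulus + w * d.young_modulus,
        poisson_ratio=(1 - w) * g.poisson_ratio + w * d.poisson_ratio,
        permeability=(1 - w) * g.permeability + w * d.permeability,
    )


def smooth_properties(x_mix: MaterialProperties,
                      history: list[MaterialProperties],
                      window: int = 10) -> MaterialProperties:
    """Moving-window average of the mixed value and prior smoothed values.

    The window shortens while fewer than ``window - 1`` prior iterations
    exist; the divisor is the actual number of summed terms.
    """
    if len(history) > window - 1:
        raise ValueError(
            f"history holds {len(history)} sets, more than window-1 = {window - 1}")
    terms = [x_mix, *history]
    m = len(terms)
    return MaterialProperties(
        young_modulus=sum(t.young_modulus for t in terms) / m,
        poisson_ratio=sum(t.poisson_ratio for t in terms) / m,
        permeability=sum(t.permeability for t in terms) / m,
    )


@dataclass
class MaterialField:
    """Per-callus-element phenotype, smoothed properties, and history."""

    element_ids: np.ndarray  # callus element ids into the full mesh
    phenotype: np.ndarray  # (C,) value strings
    young: np.ndarray  # (C,) MPa, current smoothed
    poisson: np.ndarray
    permeability: np.ndarray  # m^4/(N s)
    history: deque = field(default_factory=lambda: deque(maxlen=9))

    @classmethod
    def granulation(cls, element_ids: np.ndarray, window: int = 10,
                    table=None) -> "MaterialField":
        table = table or TISSUE_PROPERTIES
        g = table["granulation"]
        C = len(element_ids)
        return cls(element_ids,
                   np.full(C, Phenotype.GRANULATION.value, dtype="<U16"),
                   np.full(C, g.young_modulus), np.full(C, g.poisson_ratio),
                   np.full(C, g.permeability),
                   deque(maxlen=window - 1))


@dataclass
class DayRecord:
    """State of one healing day (iteration)."""

    day: int
    phenotype: np.ndarray  # (C,) phenotype used in this day's solve
    concentration: np.ndarray  # (N,) nodal stem-cell fraction after diffusion
    young: np.ndarray  # (C,) smoothed modulus entering this day's solve, MPa
    gamma_oct: np.ndarray  # (C,)
    fluid_speed: np.ndarray  # (C,) um/s
    S: np.ndarray  # (C,)
    morphometry: "_morph.MorphometryResult"
    mean_S: float
    mean_modulus: float  # area-weighted callus mean, MPa


@dataclass
class HealingHistory:
    """Full 35-day (by default) healing simulation output."""

    mesh: object
    profile: object
    callus_elements: np.ndarray
    days: list[DayRecord]
    diffusivity: float  # mm^2/day
    config: object = None

    def mean_modulus_series(self) -> np.ndarray:
        return np.array([d.mean_modulus for d in self.days])

    def mean_S_series(self) -> np.ndarray:
        return np.array([d.mean_S for d in self.days])


def run_healing(config) -> HealingHistory:
    """Iterate the daily solve -> classify -> diffuse -> mix -> smooth loop.

    ``config`` is a :class:`osseoheal.config.RunConfig`.  The callus starts
    as granulation tissue at zero cell concentration; regions outside the
    callus keep their fixed table properties throughout.
    """
    from .config import build_model

    mesh, layout, load, interface, table = build_model(config)
    profile = layout.profile
    cal_ids = mesh.elements_in_region("callus")
    if len(cal_ids) == 0:
        raise ValueError("domain has no callus elements")
    areas = mesh.element_areas()[cal_ids]
    consts = StimulusConstants(config.stimulus_a, config.stimulus_b)

    if config.diffusivity == "calibrate":
        D = _diff.calibrate_diffusivity(mesh, config.days,
                                        config.saturation_threshold)
    else:
        D = float(config.diffusivity)

    mat_field = MaterialField.granulation(cal_ids, config.smoothing_window,
                                          table)
    base = {tag: table[REGION_MATERIALS[tag]] for tag in
            ("implant", "cortical", "cancellous", "callus")}
    roi = _morph.extract_roi(mesh, profile)
    conc = _diff.ConcentrationField(np.zeros(mesh.n_nodes), 0, D)
    g_props = table["granulation"]

    days: list[DayRecord] = []
    full_phen = np.array(mesh.element_region, dtype="<U16")
    for day in range(1, config.days + 1):
        # per-element materials: fixed regions + smoothed callus state
        mats = _fem.MaterialArrays(
            young=np.array([base[t].young_modulus for t in mesh.element_region]),
            poisson=np.array([base[t].poisson_ratio for t in mesh.element_region]),
            mobility_mm=np.array(
                [0.0 if base[t].is_solid_only else base[t].permeability * 1e12
                 for t in mesh.element_region]),
            solid_only=np.array([base[t].is_solid_only
                                 for t in mesh.element_region]),
        )
        mats.young[cal_ids] = mat_field.young
        mats.poisson[cal_ids] = mat_field.poisson
        mats.mobility_mm[cal_ids] = mat_field.permeability * 1e12

        try:
            sol = _fem.solve_loadstep(mesh, mats, load, interface)
            stim = _fem.compute_stimuli(sol, mats)
        except Exception as exc:
            raise RuntimeError(f"healing day {day}: solver failed: {exc}") from exc

        gamma = stim.gamma_oct[cal_ids]
        nu = stim.fluid_speed_nu[cal_ids]
        S = stimulus(gamma, nu, consts)
        next_phen = classify_array(S)

        conc = _diff.advance_concentration(conc, mesh, dt=1.0)

        # record the state that produced this day's mechanics
        full_phen[cal_ids] = mat_field.phenotype
        mm = _morph.morphometry_result(full_phen, roi, mesh,
                                       young=mats.young)
        days.append(DayRecord(
            day=day, phenotype=mat_field.phenotype.copy(),
            concentration=conc.n.copy(), young=mat_field.young.copy(),
            gamma_oct=gamma, fluid_speed=nu, S=S, morphometry=mm,
            mean_S=float(S.mean()),
            mean_modulus=float(np.average(mat_field.young, weights=areas)),
        ))

        # Eq. (3): blend granulation with the freshly classified phenotype
        n_elem = conc.n[mesh.elements[cal_ids]].mean(axis=1)
        w = np.clip(n_elem, 0.0, 1.0)
        d_young = np.empty(len(cal_ids))
        d_pois = np.empty(len(cal_ids))
        d_perm = np.empty(len(cal_ids))
        for ph in np.unique(next_phen):
            m = table[PHENOTYPE_TABLE_KEY[Phenotype(ph)]]
            sel = next_phen == ph
            d_young[sel] = m.young_modulus
            d_pois[sel] = m.poisson_ratio
            d_perm[sel] = m.permeability
        mix_young = (1 - w) * g_props.young_modulus + w * d_young
        mix_pois = (1 - w) * g_props.poisson_ratio + w * d_pois
        mix_perm = (1 - w) * g_props.permeability + w * d_perm

        # Eq. (4): truncated-window smoothing
        hist = list(mat_field.history)
        m_terms = 1 + len(hist)
        sm_young = (mix_young + sum(h[0] for h in hist)) / m_terms
        sm_pois = (mix_pois + sum(h[1] for h in hist)) / m_terms
        sm_perm = (mix_perm + sum(h[2] for h in hist)) / m_terms
        mat_field.history.appendleft((sm_young, sm_pois, sm_perm))
        mat_field.young, mat_field.poisson = sm_young, sm_pois
        mat_field.permeability = sm_perm
        mat_field.phenotype = next_phen

    return HealingHistory(mesh, profile, cal_ids, days, D, config)
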