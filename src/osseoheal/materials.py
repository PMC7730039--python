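"""Tissue and implant material properties.

Properties are stored in the units they are conventionally tabulated in:
Young's modulus in MPa, Poisson's ratio dimensionless, and permeability as
hydraulic mobility k in m^4/(N s) (intrinsic permeability already divided by
the interstitial-fluid viscosity).  The finite-element kernels work in a
mm / N / s / MPa unit system; ``MM4_PER_M4`` converts mobilities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

#: mobility conversion m^4/(N s) -> mm^4/(N s)
MM4_PER_M4 = 1.0e12


@dataclass(frozen=True)
class MaterialProperties:
    """Isotropic poroelastic (or solid-only) material point data."""

    young_modulus: float  # MPa
    poisson_ratio: float  # dimensionless
    permeability: float | None  # m^4/(N s); None only if is_solid_only
    is_solid_only: bool = False

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError(f"young_modulus must be positive, got {self.young_modulus}")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError(f"poisson_ratio must lie in [0, 0.5), got {self.poisson_ratio}")
        if not self.is_solid_only and (self.permeability is None or self.permeability <= 0):
            raise ValueError("poroelastic material requires positive permeability")

    @property
    def permeability_mm(self) -> float:
        """Hydraulic mobility in mm^4/(N s)."""
        if self.is_solid_only:
            raise ValueError("solid-only material has no permeability")
        return self.permeability * MM4_PER_M4

    def with_values(self, **kw) -> "MaterialProperties":
        return replace(self, **kw)


#: Baseline property table for every tissue phenotype and structural region.
TISSUE_PROPERTIES: dict[str, MaterialProperties] = {
    "granulation": MaterialProperties(1.0, 0.17, 1.0e-14),
    "fibrous_tissue": MaterialProperties(2.0, 0.17, 1.0e-14),
    "cartilage": MaterialProperties(10.0, 0.17, 5.0e-15),
    "immature_bone": MaterialProperties(1000.0, 0.30, 1.0e-13),
    "mature_bone": MaterialProperties(6000.0, 0.30, 3.7e-13),
    "cortical_bone": MaterialProperties(20000.0, 0.30, 1.0e-17),
    "cancellous_bone": MaterialProperties(6000.0, 0.30, 3.7e-13),
    "titanium": MaterialProperties(113000.0, 0.30, None, is_solid_only=True),
}

#: Region tag -> fixed material for everything outside the healing callus.
REGION_MATERIALS: dict[str, str] = {
    "implant": "titanium",
    "cortical": "cortical_bone",
    "cancellous": "cancellous_bone",
    "callus": "granulation",
}
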