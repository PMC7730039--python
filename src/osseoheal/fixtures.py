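"""Deterministic synthetic fixtures with attached analytic oracles.

Every fixture is small (<= 2,000 elements), generated in memory, and carries
the metadata needed to verify the numerical kernels against closed forms:
the 1D half-space erf profile for diffusion, the Terzaghi consolidation
series for the coupled solver, and the Lame thick-walled cylinder for the
elastic kernel.  ``single_chamber`` is the reference healing geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fem import LoadCase
from .geometry import Mesh, rect_mesh
from .materials import MaterialProperties, TISSUE_PROPERTIES

__all__ = ["Fixture", "make_fixture"]

FIXTURE_KINDS = ("strip_1d", "single_chamber", "lame_cylinder", "terzaghi_column")


@dataclass
class Fixture:
    kind: str
    mesh: Mesh
    materials: object  # dict tag->MaterialProperties or per-element list
    load: LoadCase | None
    meta: dict = field(default_factory=dict)


def make_fixture(kind: str) -> Fixture:
    if kind == "strip_1d":
        return _strip_1d()
    if kind == "terzaghi_column":
        return _terzaghi_column()
    if kind == "lame_cylinder":
        return _lame_cylinder()
    if kind == "single_chamber":
        return _single_chamber()
    raise ValueError(f"unknown fixture kind '{kind}', expected {FIXTURE_KINDS}")


def _strip_1d() -> Fixture:
    """Axial diffusion strip: hot (cells-origin) boundary at y = 0.

    Before the far boundary is felt, the nodal concentration follows the
    half-space solution n(y, t) = erfc(y / (2 sqrt(D t))).
    """
    L, w, h = 1.0, 0.1, 0.025
    mesh = rect_mesh(w, L, h, region="callus")
    mesh.boundary_sets["cells_origin"] = mesh.boundary_sets["bottom"]

    def erf_profile(y, t, D):
        y = np.asarray(y, dtype=float)
        return np.array([math.erfc(yi / (2.0 * math.sqrt(D * t))) for yi in y])

    n_nodes_formula = (round(w / h) + 1) * (round(L / h) + 1)
    return Fixture("strip_1d", mesh, {"callus": TISSUE_PROPERTIES["granulation"]},
                   None, {"length": L, "erf_profile": erf_profile,
                          "n_nodes_formula": n_nodes_formula})


def _terzaghi_column() -> Fixture:
    """Laterally confined consolidation column, drained at the top.

    Material normalised to oedometric modulus M = 1 MPa and mobility
    k = 1e-2 mm^4/(N s), giving cv = 1e-2 mm^2/s; a step load q acts on the
    top surface from t = 0+.
    """
    H, w = 1.0, 0.05
    mesh = rect_mesh(w, H, 0.025, region="callus", nx=2, ny=40)
    mat = MaterialProperties(1.0, 0.0, 1.0e-14)  # M = E for nu = 0
    cv = mat.permeability_mm * 1.0
    q = 0.1  # MPa

    def pressure_series(y, Tv, n_terms=200):
        """Excess pore pressure at height y for time factor Tv."""
        z = H - np.asarray(y, dtype=float)  # depth below the drained surface
        p = np.zeros_like(z)
        for m in range(1, 2 * n_terms, 2):
            p += (4.0 * q / (m * np.pi) * np.sin(m * np.pi * z / (2 * H))
                  * np.exp(-((m * np.pi / 2) ** 2) * Tv))
        return p

    def velocity_series(y, Tv, n_terms=200):
        """Darcy speed (um/s) = k |dp/dz| at height y, time factor Tv."""
        z = H - np.asarray(y, dtype=float)
        g = np.zeros_like(z)
        for m in range(1, 2 * n_terms, 2):
            g += (4.0 * q / (2 * H) * np.cos(m * np.pi * z / (2 * H))
                  * np.exp(-((m * np.pi / 2) ** 2) * Tv))
        return mat.permeability_mm * np.abs(g) * 1e3

    return Fixture(
        "terzaghi_column", mesh, {"callus": mat}, None,
        {"height": H, "q": q, "cv": cv,
         "pressure_series": pressure_series,
         "velocity_series": velocity_series})


def _lame_cylinder() -> Fixture:
    """Drained thick-walled cylinder, internal pressure P at r = a.

    Plane strain (u_z = 0); the radial displacement closed form is
    u_r = P a^2 / (E (b^2 - a^2)) * ((1+nu)(1-2nu) r + (1+nu) b^2 / r).
    """
    a, b, height, h = 1.0, 2.0, 0.2, 0.05
    mesh = rect_mesh(b - a, height, h, region="callus", origin=(a, 0.0))
    E, nu, P = 100.0, 0.3, 1.0
    mat = MaterialProperties(E, nu, 1.0e-14)

    def u_r(r):
        r = np.asarray(r, dtype=float)
        c = P * a ** 2 / (E * (b ** 2 - a ** 2))
        return c * ((1 + nu) * (1 - 2 * nu) * r + (1 + nu) * b ** 2 / r)

    left = np.sort(mesh.boundary_sets["left"])
    order = np.argsort(mesh.node_coords[left, 1])
    inner_edges = np.column_stack([left[order][:-1], left[order][1:]])
    return Fixture("lame_cylinder", mesh, {"callus": mat}, None,
                   {"a": a, "b": b, "E": E, "nu": nu, "P": P, "u_r": u_r,
                    "inner_edges": inner_edges})


def _single_chamber() -> Fixture:
    """Reference single-chamber healing geometry (toy implant)."""
    from .config import TOY_SPEC, RunConfig
    from .geometry import generate_mesh

    cfg = RunConfig()
    layout = TOY_SPEC.layout()
    mesh = generate_mesh(layout, cfg.element_size, cfg.implant_element_factor)
    return Fixture("single_chamber", mesh, dict(TISSUE_PROPERTIES),
                   cfg.load_case(),
                   {"layout": layout, "profile": layout.profile,
                    "spec": TOY_SPEC})
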