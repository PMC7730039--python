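"""Quasi-static axisymmetric Biot poroelasticity on bilinear quads.

Monolithic displacement / pore-pressure (u-p) formulation with backward-Euler
time stepping, Biot coefficient 1 and incompressible constituents (zero
storativity).  Unit system: mm, N, s, MPa; hydraulic mobilities enter in
m^4/(N s) and are converted internally; Darcy speeds are reported in um/s.

Strain components are ordered (err, ezz, ehoop, grz) with engineering shear.
All volume integrals carry the axisymmetric 2*pi*r weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .materials import MaterialProperties, MM4_PER_M4

__all__ = [
    "LoadCase",
    "InterfaceSpec",
    "SolutionFields",
    "ElementStimuli",
    "MaterialArrays",
    "assemble_poroelastic_system",
    "solve_transient",
    "solve_loadstep",
    "element_strains",
    "octahedral_shear_strain",
    "darcy_velocity",
    "compute_stimuli",
    "edge_traction_forces",
]

_G = 1.0 / np.sqrt(3.0)
GAUSS_POINTS = [(-_G, -_G), (_G, -_G), (_G, _G), (-_G, _G)]


def shape_functions(xi: float, eta: float) -> np.ndarray:
    return 0.25 * np.array([
        (1 - xi) * (1 - eta),
        (1 + xi) * (1 - eta),
        (1 + xi) * (1 + eta),
        (1 - xi) * (1 + eta),
    ])


def shape_gradients(xi: float, eta: float) -> np.ndarray:
    return 0.25 * np.array([
        [-(1 - eta), -(1 - xi)],
        [(1 - eta), -(1 + xi)],
        [(1 + eta), (1 + xi)],
        [-(1 + eta), (1 - xi)],
    ])


@dataclass(frozen=True)
class LoadCase:
    """Prescribed axial settlement of the implant top surface."""

    top_displacement: float = 8.0  # um, applied along -y
    ramp_duration: float = 1.0  # s
    n_time_steps: int = 10

    def __post_init__(self) -> None:
        if self.ramp_duration <= 0 or self.n_time_steps < 1:
            raise ValueError("ramp_duration must be > 0 and n_time_steps >= 1")


@dataclass(frozen=True)
class InterfaceSpec:
    """Implant-callus interface mechanics."""

    mode: str = "tied"  # or "coulomb_penalty"
    friction_coefficient: float = 0.3
    penalty_stiffness: float = 1.0e5  # MPa/mm (per unit interface area)
    max_iterations: int = 40

    def __post_init__(self) -> None:
        if self.mode not in ("tied", "coulomb_penalty"):
            raise ValueError("mode must be 'tied' or 'coulomb_penalty'")
        if self.friction_coefficient < 0:
            raise ValueError("friction_coefficient must be >= 0")


@dataclass
class MaterialArrays:
    """Per-element material data in solver units."""

    young: np.ndarray  # MPa
    poisson: np.ndarray
    mobility_mm: np.ndarray  # mm^4/(N s); 0 on solid-only elements
    solid_only: np.ndarray  # bool mask


def material_arrays(mesh, materials) -> MaterialArrays:
    if isinstance(materials, MaterialArrays):
        return materials
    n = mesh.n_elements
    if isinstance(materials, dict):
        seq = [materials[tag] for tag in mesh.element_region]
    else:
        seq = list(materials)
        if len(seq) != n:
            raise ValueError(f"need {n} per-element materials, got {len(seq)}")
    young = np.array([m.young_modulus for m in seq])
    poisson = np.array([m.poisson_ratio for m in seq])
    solid = np.array([m.is_solid_only for m in seq], dtype=bool)
    mob = np.array([0.0 if m.is_solid_only else m.permeability * MM4_PER_M4
                    for m in seq])
    if np.any(~solid & (mob <= 0)):
        raise ValueError("poroelastic element with non-positive permeability")
    return MaterialArrays(young, poisson, mob, solid)


@dataclass
class PoroSystem:
    """Assembled coupled operator blocks for one backward-Euler step."""

    K: sp.csr_matrix  # (2N, 2N) elastic stiffness
    Q: sp.csr_matrix  # (2N, P) volumetric coupling (Biot alpha = 1)
    H: sp.csr_matrix  # (P, P) mobility (Darcy) matrix
    p_nodes: np.ndarray  # node ids carrying a pressure dof
    p_index: np.ndarray  # node id -> pressure dof (-1 if none)
    n_nodes: int

    @property
    def n_u(self) -> int:
        return 2 * self.n_nodes

    @property
    def n_p(self) -> int:
        return len(self.p_nodes)

    def matrix(self, dt: float) -> sp.csc_matrix:
        """Symmetric monolithic operator [[K, -Q], [-Q^T, -dt*H]]."""
        return sp.bmat([[self.K, -self.Q], [-self.Q.T, -dt * self.H]],
                       format="csc")


def assemble_poroelastic_system(mesh, materials, interface: InterfaceSpec | None = None,
                                dt: float = 0.1) -> PoroSystem:
    """Assemble K, Q, H for the axisymmetric u-p problem.

    Solid-only (implant) elements contribute elasticity only and carry no
    pressure unknowns on their interior nodes.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    mats = material_arrays(mesh, materials)
    coords = mesh.element_corner_coords()  # (E, 4, 2)
    nE = mesh.n_elements
    nN = mesh.n_nodes

    # pressure dofs: nodes touched by at least one poroelastic element
    p_index = np.full(nN, -1, dtype=int)
    poro_nodes = np.unique(mesh.elements[~mats.solid_only])
    p_index[poro_nodes] = np.arange(len(poro_nodes))

    E, nu = mats.young, mats.poisson
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((nE, 4, 4))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
    D[:, 3, 3] = mu

    Ke = np.zeros((nE, 8, 8))
    Qe = np.zeros((nE, 8, 4))
    He = np.zeros((nE, 4, 4))
    poro = ~mats.solid_only
    for xi, eta in GAUSS_POINTS:
        N = shape_functions(xi, eta)
        dNr = shape_gradients(xi, eta)
        J = np.einsum("eai,aj->eij", coords, dNr)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        invJ = np.empty_like(J)
        invJ[:, 0, 0] = J[:, 1, 1] / detJ
        invJ[:, 1, 1] = J[:, 0, 0] / detJ
        invJ[:, 0, 1] = -J[:, 0, 1] / detJ
        invJ[:, 1, 0] = -J[:, 1, 0] / detJ
        dNx = np.einsum("aj,eji->eai", dNr, invJ)
        r = coords[:, :, 0] @ N
        w = 2.0 * np.pi * r * detJ  # unit gauss weights

        B = np.zeros((nE, 4, 8))
        for a in range(4):
            B[:, 0, 2 * a] = dNx[:, a, 0]
            B[:, 1, 2 * a + 1] = dNx[:, a, 1]
            B[:, 2, 2 * a] = N[a] / r
            B[:, 3, 2 * a] = dNx[:, a, 1]
            B[:, 3, 2 * a + 1] = dNx[:, a, 0]
        Ke += np.einsum("esi,est,etj->eij", B, D, B) * w[:, None, None]

        Bv = B[:, 0, :] + B[:, 1, :] + B[:, 2, :]  # volumetric strain row
        Qe[poro] += (np.einsum("ei,j->eij", Bv, N) * w[:, None, None])[poro]
        He[poro] += (np.einsum("eai,ebi->eab", dNx, dNx)
                     * (mats.mobility_mm * w)[:, None, None])[poro]

    conn = mesh.elements
    udof = np.empty((nE, 8), dtype=int)
    udof[:, 0::2] = 2 * conn
    udof[:, 1::2] = 2 * conn + 1
    pdof = p_index[conn]

    K = sp.coo_matrix(
        (Ke.ravel(),
         (np.repeat(udof, 8, axis=1).ravel(), np.tile(udof, 8).ravel())),
        shape=(2 * nN, 2 * nN)).tocsr()
    rows = np.repeat(udof, 4, axis=1)[poro].ravel()
    cols = np.tile(pdof, (1, 8)).reshape(nE, 8, 4)[poro].ravel()
    Q = sp.coo_matrix((Qe[poro].ravel(), (rows, cols)),
                      shape=(2 * nN, len(poro_nodes))).tocsr()
    hr = np.repeat(pdof, 4, axis=1)[poro].ravel()
    hc = np.tile(pdof, (1, 4)).reshape(nE, 4, 4)[poro].ravel()
    H = sp.coo_matrix((He[poro].ravel(), (hr, hc)),
                      shape=(len(poro_nodes),) * 2).tocsr()
    return PoroSystem(K, Q, H, poro_nodes, p_index, nN)


@dataclass
class SolutionFields:
    """Displacement and pore-pressure solution, last step at peak load."""

    displacement: np.ndarray  # (N, 2) mm
    pore_pressure: np.ndarray  # (N,) MPa, NaN on solid-only nodes
    mesh: object
    p_mask: np.ndarray  # bool, nodes with a pressure dof
    times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    step_displacements: list = field(default_factory=list)
    step_pressures: list = field(default_factory=list)


@dataclass
class ElementStimuli:
    """Per-element biophysical stimuli at peak load."""

    gamma_oct: np.ndarray  # octahedral shear strain, dimensionless
    fluid_velocity: np.ndarray  # (E, 2) um/s, NaN on solid elements
    fluid_speed_nu: np.ndarray  # (E,) um/s


def solve_transient(mesh, materials, *, dt: float, n_steps: int,
                    u_fix: dict[int, float] | None = None,
                    p_fix_nodes=None, forces=None, ramp: bool = True,
                    store_steps: bool = False) -> SolutionFields:
    """March the coupled system with backward Euler.

    ``u_fix`` maps displacement dof index (2*node [+1]) to its final value;
    prescribed values and ``forces`` are scaled linearly over the ramp when
    ``ramp`` is true, otherwise applied in full from the first step.
    """
    sys_ = assemble_poroelastic_system(mesh, materials, dt=dt)
    A = sys_.matrix(dt)
    ndof = sys_.n_u + sys_.n_p

    u_fix = u_fix or {}
    fixed = np.array(sorted(u_fix), dtype=int)
    fixed_vals = np.array([u_fix[d] for d in fixed])
    if p_fix_nodes is not None and len(p_fix_nodes):
        pd = sys_.p_index[np.asarray(p_fix_nodes, dtype=int)]
        pd = pd[pd >= 0] + sys_.n_u
        fixed = np.concatenate([fixed, pd])
        fixed_vals = np.concatenate([fixed_vals, np.zeros(len(pd))])
    free = np.setdiff1d(np.arange(ndof), fixed)

    A_ff = A[free][:, free].tocsc()
    A_fc = A[free][:, fixed].tocsr()
    try:
        lu = splu(A_ff)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"singular poroelastic system (missing constraints?): {exc}") from exc

    x = np.zeros(ndof)
    sol = SolutionFields(np.zeros((mesh.n_nodes, 2)), np.zeros(mesh.n_nodes),
                         mesh, sys_.p_index >= 0)
    times = []
    for k in range(1, n_steps + 1):
        s = k / n_steps if ramp else 1.0
        b = np.zeros(ndof)
        if forces is not None:
            b[:sys_.n_u] += s * forces
        b[sys_.n_u:] = -(sys_.Q.T @ x[:sys_.n_u])
        xc = s * fixed_vals
        xf = lu.solve(b[free] - A_fc @ xc)
        x = np.zeros(ndof)
        x[free] = xf
        x[fixed] = xc
        times.append(k * dt)
        if store_steps:
            sol.step_displacements.append(x[:sys_.n_u].reshape(-1, 2).copy())
            p_full = np.full(mesh.n_nodes, np.nan)
            p_full[sys_.p_nodes] = x[sys_.n_u:]
            sol.step_pressures.append(p_full)

    sol.displacement = x[:sys_.n_u].reshape(-1, 2)
    p_full = np.full(mesh.n_nodes, np.nan)
    p_full[sys_.p_nodes] = x[sys_.n_u:]
    sol.pore_pressure = p_full
    sol.times = np.array(times)
    return sol


def solve_loadstep(mesh, materials, load: LoadCase,
                   interface: InterfaceSpec | None = None) -> SolutionFields:
    """One healing day's load: ramp the implant settlement and return the
    peak-load solution.

    Boundary conditions: radial fixity on the symmetry axis, axial fixity on
    the base, prescribed axial displacement on the implant top surface,
    drained (p = 0) outer boundary, no-flux on the axis and the implant
    interface.
    """
    interface = interface or InterfaceSpec()
    if interface.mode == "coulomb_penalty":
        return _solve_contact(mesh, materials, load, interface)

    u_fix = _displacement_bcs(mesh, load)
    dt = load.ramp_duration / load.n_time_steps
    return solve_transient(mesh, materials, dt=dt, n_steps=load.n_time_steps,
                           u_fix=u_fix,
                           p_fix_nodes=mesh.boundary_sets.get("drained"))


def _displacement_bcs(mesh, load: LoadCase) -> dict[int, float]:
    u_fix: dict[int, float] = {}
    for n in mesh.boundary_sets["axis"]:
        u_fix[2 * int(n)] = 0.0
    for n in mesh.boundary_sets["fixed_base"]:
        u_fix[2 * int(n) + 1] = 0.0
    # bottom-left corner radial fixity is implied by the axis constraint
    for n in mesh.boundary_sets["load_surface"]:
        u_fix[2 * int(n) + 1] = -load.top_displacement * 1e-3  # um -> mm
    return u_fix


def element_strains(solution: SolutionFields, mesh=None) -> np.ndarray:
    """Axisymmetric strains (err, ezz, ehoop, grz) at element centroids."""
    mesh = mesh or solution.mesh
    coords = mesh.element_corner_coords()
    u = solution.displacement[mesh.elements]  # (E, 4, 2)
    N = shape_functions(0.0, 0.0)
    dNr = shape_gradients(0.0, 0.0)
    J = np.einsum("eai,aj->eij", coords, dNr)
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    invJ = np.empty_like(J)
    invJ[:, 0, 0] = J[:, 1, 1] / detJ
    invJ[:, 1, 1] = J[:, 0, 0] / detJ
    invJ[:, 0, 1] = -J[:, 0, 1] / detJ
    invJ[:, 1, 0] = -J[:, 1, 0] / detJ
    dNx = np.einsum("aj,eji->eai", dNr, invJ)
    r = coords[:, :, 0] @ N
    strains = np.empty((mesh.n_elements, 4))
    strains[:, 0] = np.einsum("ea,ea->e", dNx[:, :, 0], u[:, :, 0])
    strains[:, 1] = np.einsum("ea,ea->e", dNx[:, :, 1], u[:, :, 1])
    strains[:, 2] = (u[:, :, 0] @ N) / r
    strains[:, 3] = (np.einsum("ea,ea->e", dNx[:, :, 1], u[:, :, 0])
                     + np.einsum("ea,ea->e", dNx[:, :, 0], u[:, :, 1]))
    return strains


def octahedral_shear_strain(strains: np.ndarray) -> np.ndarray:
    """gamma_oct = (2/3) sqrt(sum of squared principal-strain differences).

    The hoop strain is a principal strain; the in-plane pair comes from the
    (err, ezz, grz) Mohr circle.
    """
    s = np.atleast_2d(np.asarray(strains, dtype=float))
    err, ezz, ehoop, grz = s[:, 0], s[:, 1], s[:, 2], s[:, 3]
    mean = 0.5 * (err + ezz)
    rad = np.sqrt((0.5 * (err - ezz)) ** 2 + (0.5 * grz) ** 2)
    e1, e2, e3 = mean + rad, mean - rad, ehoop
    g = (2.0 / 3.0) * np.sqrt((e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2)
    return g[0] if np.asarray(strains).ndim == 1 else g


def darcy_velocity(solution: SolutionFields, materials, mesh=None,
                   elements=None) -> np.ndarray:
    """Centroid Darcy velocity v = -k grad(p), in um/s, shape (E, 2).

    Solid-only (implant) elements carry NaN; requesting them explicitly via
    ``elements`` raises.
    """
    mesh = mesh or solution.mesh
    mats = material_arrays(mesh, materials)
    if elements is not None and np.any(mats.solid_only[np.asarray(elements)]):
        raise ValueError("implant elements carry no pore-pressure field")
    coords = mesh.element_corner_coords()
    dNr = shape_gradients(0.0, 0.0)
    J = np.einsum("eai,aj->eij", coords, dNr)
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    invJ = np.empty_like(J)
    invJ[:, 0, 0] = J[:, 1, 1] / detJ
    invJ[:, 1, 1] = J[:, 0, 0] / detJ
    invJ[:, 0, 1] = -J[:, 0, 1] / detJ
    invJ[:, 1, 0] = -J[:, 1, 0] / detJ
    dNx = np.einsum("aj,eji->eai", dNr, invJ)
    p = solution.pore_pressure[mesh.elements]  # (E, 4)
    grad = np.einsum("eai,ea->ei", dNx, np.nan_to_num(p))
    v = -mats.mobility_mm[:, None] * grad * 1e3  # mm/s -> um/s
    v[mats.solid_only] = np.nan
    if elements is not None:
        return v[np.asarray(elements)]
    return v


def compute_stimuli(solution: SolutionFields, materials) -> ElementStimuli:
    """gamma_oct and Darcy speed per element at the peak-load step."""
    strains = element_strains(solution)
    gamma = octahedral_shear_strain(strains)
    v = darcy_velocity(solution, materials)
    speed = np.sqrt(v[:, 0] ** 2 + v[:, 1] ** 2)
    return ElementStimuli(gamma, v, speed)


def edge_traction_forces(mesh, edges: np.ndarray, traction) -> np.ndarray:
    """Consistent nodal forces for a constant traction on straight edges.

    Axisymmetric: f_a = t * 2*pi * L * (2 r_a + r_b) / 6 on a linear edge.
    """
    t = np.asarray(traction, dtype=float)
    f = np.zeros(2 * mesh.n_nodes)
    for a, b in np.asarray(edges, dtype=int):
        xa, xb = mesh.node_coords[a], mesh.node_coords[b]
        L = np.linalg.norm(xb - xa)
        ra, rb = xa[0], xb[0]
        fa = 2 * np.pi * L * (2 * ra + rb) / 6.0
        fb = 2 * np.pi * L * (ra + 2 * rb) / 6.0
        f[2 * a:2 * a + 2] += fa * t
        f[2 * b:2 * b + 2] += fb * t
    return f


# --------------------------------------------------------------------------
# Coulomb penalty contact at the implant-callus interface
# --------------------------------------------------------------------------

@dataclass
class _ContactData:
    mesh: object  # augmented mesh (duplicate callus-side interface nodes)
    orig: np.ndarray  # (P,) implant-side node ids
    dup: np.ndarray  # (P,) callus-side duplicates
    normals: np.ndarray  # (P, 2) unit, implant -> callus
    weights: np.ndarray  # (P,) tributary interface area (2*pi*r*L/2 sums)


def build_contact(mesh) -> _ContactData:
    from copy import copy

    edges = mesh.edge_sets["implant_callus_interface"]
    if len(edges) == 0:
        raise ValueError("mesh has no implant_callus_interface edges")
    inodes = np.unique(edges)
    nN = mesh.n_nodes
    dup = {int(n): nN + i for i, n in enumerate(inodes)}
    coords = np.vstack([mesh.node_coords, mesh.node_coords[inodes]])
    elements = mesh.elements.copy()
    is_implant = mesh.element_region == "implant"
    for e in np.nonzero(~is_implant)[0]:
        for i in range(4):
            n = int(elements[e, i])
            if n in dup:
                elements[e, i] = dup[n]

    # edge normals pointing away from the implant side
    nrm = np.zeros((len(inodes), 2))
    wgt = np.zeros(len(inodes))
    idx = {int(n): i for i, n in enumerate(inodes)}
    impl_cent = mesh.element_centroids()
    edge_elems: dict[tuple[int, int], list[int]] = {}
    for e, conn in enumerate(mesh.elements):
        if not is_implant[e]:
            continue
        for i in range(4):
            a, b = int(conn[i]), int(conn[(i + 1) % 4])
            edge_elems[(min(a, b), max(a, b))] = [e]
    for a, b in edges:
        key = (min(int(a), int(b)), max(int(a), int(b)))
        e_imp = edge_elems[key][0]
        xa, xb = mesh.node_coords[a], mesh.node_coords[b]
        tv = xb - xa
        L = np.linalg.norm(tv)
        n_vec = np.array([tv[1], -tv[0]]) / L
        mid = 0.5 * (xa + xb)
        if np.dot(n_vec, mid - impl_cent[e_imp]) < 0:
            n_vec = -n_vec
        area = 2 * np.pi * max(mid[0], 1e-6) * L
        for n in (int(a), int(b)):
            nrm[idx[n]] += n_vec * L
            wgt[idx[n]] += 0.5 * area
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)

    mesh2 = copy(mesh)
    mesh2.node_coords = coords
    mesh2.elements = elements
    dup_arr = np.array([dup[int(n)] for n in inodes], dtype=int)
    return _ContactData(mesh2, inodes.astype(int), dup_arr, nrm, wgt)


def _spring_matrix(cdata: _ContactData, kn: np.ndarray,
                   kt: np.ndarray) -> sp.csr_matrix:
    """Penalty springs (normal + tangential) on every interface node pair."""
    n2 = 2 * cdata.mesh.n_nodes
    rows, cols, vals = [], [], []
    for i, (o, d) in enumerate(zip(cdata.orig, cdata.dup)):
        n = cdata.normals[i]
        t = np.array([-n[1], n[0]])
        Kp = kn[i] * np.outer(n, n) + kt[i] * np.outer(t, t)
        dofs = [2 * o, 2 * o + 1, 2 * d, 2 * d + 1]
        block = np.block([[Kp, -Kp], [-Kp, Kp]])
        for r_ in range(4):
            for c_ in range(4):
                rows.append(dofs[r_])
                cols.append(dofs[c_])
                vals.append(block[r_, c_])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n2, n2)).tocsr()


def _solve_contact(mesh, materials, load: LoadCase,
                   interface: InterfaceSpec) -> SolutionFields:
    cdata = build_contact(mesh)
    m2 = cdata.mesh
    mats = material_arrays(mesh, materials)
    sys_ = assemble_poroelastic_system(m2, mats, dt=1.0)
    dt = load.ramp_duration / load.n_time_steps
    A0 = sys_.matrix(dt)
    ndof = sys_.n_u + sys_.n_p

    u_fix = _displacement_bcs(mesh, load)
    # mirror axis / base constraints onto duplicate nodes
    axis = set(int(n) for n in mesh.boundary_sets["axis"])
    base_set = set(int(n) for n in mesh.boundary_sets["fixed_base"])
    for o, d in zip(cdata.orig, cdata.dup):
        if int(o) in axis:
            u_fix[2 * int(d)] = 0.0
        if int(o) in base_set:
            u_fix[2 * int(d) + 1] = 0.0
    fixed = np.array(sorted(u_fix), dtype=int)
    fixed_vals = np.array([u_fix[dof] for dof in fixed])
    drained = mesh.boundary_sets.get("drained")
    if drained is not None and len(drained):
        dn = list(drained)
        # drained duplicates as well (same physical surface)
        dmap = {int(o): int(d) for o, d in zip(cdata.orig, cdata.dup)}
        dn += [dmap[int(n)] for n in drained if int(n) in dmap]
        pd = sys_.p_index[np.asarray(dn, dtype=int)]
        pd = pd[pd >= 0] + sys_.n_u
        fixed = np.concatenate([fixed, pd])
        fixed_vals = np.concatenate([fixed_vals, np.zeros(len(pd))])
    free = np.setdiff1d(np.arange(ndof), fixed)

    kn = interface.penalty_stiffness * cdata.weights
    # elasto-slip tangential stiffness: scaled to the adjacent callus
    # stiffness so stick compliance matches one element layer of tissue and
    # the force-correction iteration contracts well
    h_ref = getattr(mesh, "element_size_target", 0.05)
    adj_young = np.full(len(cdata.orig), mats.young.mean())
    for i, d in enumerate(cdata.dup):
        elems = np.nonzero((m2.elements == d).any(axis=1))[0]
        if len(elems):
            adj_young[i] = mats.young[elems].mean()
    kt = adj_young * cdata.weights / h_ref
    mu_f = interface.friction_coefficient
    tvec = np.column_stack([-cdata.normals[:, 1], cdata.normals[:, 0]])

    # constant-stiffness return mapping: the stick stiffness stays in the
    # (factorized-once) matrix; the Coulomb cap is enforced by a damped
    # corrective force  corr = clip(kt*gt + corr, +-mu*Fn) - kt*gt  on the rhs.
    S = _spring_matrix(cdata, kn, kt)
    A = (A0 + sp.bmat([[S, None],
                       [None, sp.csr_matrix((sys_.n_p,) * 2)]],
                      format="csc")).tocsc()
    lu = splu(A[free][:, free])
    A_fc = A[free][:, fixed].tocsr()

    def gaps(xv):
        du = np.column_stack([xv[2 * cdata.dup] - xv[2 * cdata.orig],
                              xv[2 * cdata.dup + 1] - xv[2 * cdata.orig + 1]])
        gn = np.einsum("ij,ij->i", du, cdata.normals)
        gt = np.einsum("ij,ij->i", du, tvec)
        return gn, gt

    x = np.zeros(ndof)
    corr = np.zeros(len(cdata.orig))
    times = []
    omega = 0.7  # fixed-point damping
    for k in range(1, load.n_time_steps + 1):
        s = k / load.n_time_steps
        b0 = np.zeros(ndof)
        b0[sys_.n_u:] = -(sys_.Q.T @ x[:sys_.n_u])
        xc = s * fixed_vals
        for it in range(interface.max_iterations):
            b = b0.copy()
            fvec = corr[:, None] * tvec
            np.add.at(b, 2 * cdata.dup, fvec[:, 0])
            np.add.at(b, 2 * cdata.dup + 1, fvec[:, 1])
            np.add.at(b, 2 * cdata.orig, -fvec[:, 0])
            np.add.at(b, 2 * cdata.orig + 1, -fvec[:, 1])
            xf = lu.solve(b[free] - A_fc @ xc)
            x = np.zeros(ndof)
            x[free] = xf
            x[fixed] = xc
            gn, gt = gaps(x)
            fn = np.maximum(-kn * gn, 0.0)
            ft_trial = kt * gt + corr
            ft_target = np.clip(ft_trial, -mu_f * fn, mu_f * fn)
            corr_new = ft_target - kt * gt
            ref = max(float(np.abs(ft_target).max()),
                      float(np.abs(corr).max()), 1e-9)
            delta = float(np.abs(corr_new - corr).max())
            corr = (1 - omega) * corr + omega * corr_new
            if delta < 1e-3 * ref and it >= 1:
                break
        else:
            raise RuntimeError(
                f"contact iteration failed to converge within "
                f"{interface.max_iterations} iterations at load step {k}")
        times.append(k * dt)

    sol = SolutionFields(x[:sys_.n_u].reshape(-1, 2),
                         np.full(m2.n_nodes, np.nan), m2, sys_.p_index >= 0)
    sol.pore_pressure[sys_.p_nodes] = x[sys_.n_u:]
    sol.times = np.array(times)
    return sol
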