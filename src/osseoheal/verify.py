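"""Built-in analytic-oracle verification of the numerical kernels."""

from __future__ import annotations

import numpy as np

from . import diffusion, fem
from .fixtures import make_fixture
from .geometry import rect_mesh
from .materials import MaterialProperties

__all__ = ["run_verification"]


def terzaghi_error(Tv: float = 0.5, n_steps: int = 100) -> float:
    """Relative L2 error of the pore-pressure profile at time factor Tv."""
    fx = make_fixture("terzaghi_column")
    mesh, meta = fx.mesh, fx.meta
    H, cv, q = meta["height"], meta["cv"], meta["q"]
    t_end = Tv * H ** 2 / cv
    dt = t_end / n_steps
    u_fix = {2 * int(n): 0.0 for n in range(mesh.n_nodes)}
    for n in mesh.boundary_sets["bottom"]:
        u_fix[2 * int(n) + 1] = 0.0
    top = np.sort(mesh.boundary_sets["top"])
    order = np.argsort(mesh.node_coords[top, 0])
    top_edges = np.column_stack([top[order][:-1], top[order][1:]])
    forces = fem.edge_traction_forces(mesh, top_edges, (0.0, -q))
    sol = fem.solve_transient(mesh, fx.materials, dt=dt, n_steps=n_steps,
                              u_fix=u_fix, p_fix_nodes=mesh.boundary_sets["top"],
                              forces=forces, ramp=False)
    y = mesh.node_coords[:, 1]
    p_ref = meta["pressure_series"](y, Tv)
    p_num = sol.pore_pressure
    return float(np.linalg.norm(p_num - p_ref) / np.linalg.norm(p_ref))


def lame_error(element_size: float = 0.05) -> float:
    """Relative L2 error of the radial displacement field."""
    fx = make_fixture("lame_cylinder")
    mesh = fx.mesh if element_size == 0.05 else rect_mesh(
        fx.meta["b"] - fx.meta["a"], 0.2, element_size, region="callus",
        origin=(fx.meta["a"], 0.0))
    meta = fx.meta
    if element_size != 0.05:
        left = np.sort(mesh.boundary_sets["left"])
        order = np.argsort(mesh.node_coords[left, 1])
        inner_edges = np.column_stack([left[order][:-1], left[order][1:]])
    else:
        inner_edges = meta["inner_edges"]
    u_fix = {2 * int(n) + 1: 0.0 for n in range(mesh.n_nodes)}  # plane strain
    forces = fem.edge_traction_forces(mesh, inner_edges, (meta["P"], 0.0))
    sol = fem.solve_transient(mesh, fx.materials, dt=1.0, n_steps=1,
                              u_fix=u_fix,
                              p_fix_nodes=np.arange(mesh.n_nodes),
                              forces=forces, ramp=False)
    r = mesh.node_coords[:, 0]
    u_ref = meta["u_r"](r)
    return float(np.linalg.norm(sol.displacement[:, 0] - u_ref)
                 / np.linalg.norm(u_ref))


def patch_test_error() -> float:
    """Confined uniaxial patch: interior solution vs the exact linear field."""
    mesh = rect_mesh(1.0, 1.0, 0.25, region="callus")
    mat = MaterialProperties(10.0, 0.25, 1.0e-14)
    alpha = -1e-3
    u_fix = {2 * int(n): 0.0 for n in range(mesh.n_nodes)}
    for n in mesh.boundary_sets["bottom"]:
        u_fix[2 * int(n) + 1] = 0.0
    for n in mesh.boundary_sets["top"]:
        u_fix[2 * int(n) + 1] = alpha
    sol = fem.solve_transient(mesh, {"callus": mat}, dt=1.0, n_steps=1,
                              u_fix=u_fix,
                              p_fix_nodes=np.arange(mesh.n_nodes), ramp=False)
    u_exact = alpha * mesh.node_coords[:, 1]
    return float(np.abs(sol.displacement[:, 1] - u_exact).max())


def diffusion_erf_error(t: float = 0.02, D: float = 1.0) -> float:
    """Relative L2 error of the strip concentration against erfc."""
    fx = make_fixture("strip_1d")
    mesh = fx.mesh
    steps = 80
    hist = diffusion.evolve_concentration(mesh, D, steps, dt=t / steps)
    y = mesh.node_coords[:, 1]
    ref = fx.meta["erf_profile"](y, t, D)
    return float(np.linalg.norm(hist[-1] - ref) / np.linalg.norm(ref))


def run_verification(echo=print) -> bool:
    checks = [
        ("patch test (max abs error)", patch_test_error(), 1e-10),
        ("Terzaghi Tv=0.5 (rel L2)", terzaghi_error(0.5), 0.02),
        ("Lame cylinder (rel L2)", lame_error(), 0.01),
        ("diffusion erf (rel L2)", diffusion_erf_error(), 0.02),
    ]
    ok = True
    for name, err, tol in checks:
        passed = err < tol
        ok &= passed
        echo(f"{'PASS' if passed else 'FAIL'}  {name}: {err:.3e} (< {tol:g})")
    return ok
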