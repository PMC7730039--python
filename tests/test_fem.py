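import numpy as np
import pytest

from osseoheal import fem
from osseoheal.fem import (InterfaceSpec, LoadCase, SolutionFields,
                           assemble_poroelastic_system, darcy_velocity,
                           element_strains, octahedral_shear_strain,
                           solve_loadstep, solve_transient)
from osseoheal.fixtures import make_fixture
from osseoheal.geometry import rect_mesh
from osseoheal.materials import MaterialProperties, REGION_MATERIALS
from osseoheal.verify import lame_error, patch_test_error, terzaghi_error

GRANULATION = MaterialProperties(1.0, 0.17, 1.0e-14)


def toy_materials(fx):
    return {t: fx.materials[REGION_MATERIALS[t]]
            for t in ("implant", "cortical", "cancellous", "callus")}


class TestAssembly:
    def test_uniaxial_patch_test_exact(self):
        assert patch_test_error() < 1e-12

    def test_implant_interior_nodes_have_no_pressure_dof(self, toy):
        mesh = toy.mesh
        sys_ = assemble_poroelastic_system(mesh, toy_materials(toy), dt=0.1)
        implant_elems = mesh.elements[mesh.element_region == "implant"]
        other = mesh.elements[mesh.element_region != "implant"]
        interior = np.setdiff1d(np.unique(implant_elems), np.unique(other))
        assert len(interior) > 0
        assert np.all(sys_.p_index[interior] == -1)
        assert np.all(sys_.p_index[np.unique(other)] >= 0)

    def test_monolithic_operator_is_symmetric(self, toy):
        sys_ = assemble_poroelastic_system(toy.mesh, toy_materials(toy), dt=0.1)
        A = sys_.matrix(0.1)
        asym = abs(A - A.T).max()
        assert asym <= 1e-10 * abs(A).max()

    def test_nonpositive_permeability_raises(self):
        mesh = rect_mesh(1.0, 1.0, 0.5)
        bad = MaterialProperties(1.0, 0.2, 1.0e-14).with_values(permeability=1e-14)
        object.__setattr__(bad, "permeability", -1.0)
        with pytest.raises(ValueError, match="permeability"):
            fem.material_arrays(mesh, {"callus": bad})

    def test_bad_dt_raises(self):
        mesh = rect_mesh(1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            assemble_poroelastic_system(mesh, {"callus": GRANULATION}, dt=0.0)


class TestOracles:
    @pytest.mark.parametrize("Tv", [0.1, 0.5])
    def test_terzaghi_pressure_profile(self, Tv):
        """Consolidation column vs the classical series solution."""
        assert terzaghi_error(Tv) < 0.02

    def test_terzaghi_pressure_decays_monotonically(self):
        fx = make_fixture("terzaghi_column")
        mesh, meta = fx.mesh, fx.meta
        u_fix = {2 * int(n): 0.0 for n in range(mesh.n_nodes)}
        for n in mesh.boundary_sets["bottom"]:
            u_fix[2 * int(n) + 1] = 0.0
        top = np.sort(mesh.boundary_sets["top"])
        order = np.argsort(mesh.node_coords[top, 0])
        edges = np.column_stack([top[order][:-1], top[order][1:]])
        forces = fem.edge_traction_forces(mesh, edges, (0.0, -meta["q"]))
        t_end = 1.0 * meta["height"] ** 2 / meta["cv"]
        sol = solve_transient(mesh, fx.materials, dt=t_end / 50, n_steps=50,
                              u_fix=u_fix, p_fix_nodes=mesh.boundary_sets["top"],
                              forces=forces, ramp=False, store_steps=True)
        base = mesh.boundary_sets["bottom"][0]
        p_base = np.array([p[base] for p in sol.step_pressures])
        assert np.all(np.diff(p_base) < 1e-12)
        assert p_base[-1] < 0.15 * meta["q"]  # mostly consolidated at Tv = 1

    def test_terzaghi_darcy_velocity(self):
        fx = make_fixture("terzaghi_column")
        mesh, meta = fx.mesh, fx.meta
        Tv, n_steps = 0.5, 100
        u_fix = {2 * int(n): 0.0 for n in range(mesh.n_nodes)}
        for n in mesh.boundary_sets["bottom"]:
            u_fix[2 * int(n) + 1] = 0.0
        top = np.sort(mesh.boundary_sets["top"])
        order = np.argsort(mesh.node_coords[top, 0])
        edges = np.column_stack([top[order][:-1], top[order][1:]])
        forces = fem.edge_traction_forces(mesh, edges, (0.0, -meta["q"]))
        dt = Tv * meta["height"] ** 2 / meta["cv"] / n_steps
        sol = solve_transient(mesh, fx.materials, dt=dt, n_steps=n_steps,
                              u_fix=u_fix, p_fix_nodes=mesh.boundary_sets["top"],
                              forces=forces, ramp=False)
        v = darcy_velocity(sol, fx.materials)
        speed = np.hypot(v[:, 0], v[:, 1])
        ref = meta["velocity_series"](mesh.element_centroids()[:, 1], Tv)
        assert np.linalg.norm(speed - ref) / np.linalg.norm(ref) < 0.03

    def test_lame_cylinder_displacement(self):
        assert lame_error() < 0.01

    def test_mesh_refinement_rate(self):
        rate = np.log2(lame_error(0.1) / lame_error(0.05))
        assert rate >= 1.8

    def test_zero_load_gives_zero_solution(self, toy):
        sol = solve_loadstep(toy.mesh, toy_materials(toy),
                             LoadCase(0.0, 1.0, 2), InterfaceSpec("tied"))
        assert np.abs(sol.displacement).max() < 1e-15
        assert np.nanmax(np.abs(sol.pore_pressure)) < 1e-15


class TestStrains:
    def test_rigid_translation_has_zero_strain(self):
        mesh = rect_mesh(1.0, 1.0, 0.25, origin=(0.5, 0.0))
        u = np.tile([0.0, -3e-3], (mesh.n_nodes, 1))
        sol = SolutionFields(u, np.zeros(mesh.n_nodes), mesh,
                             np.ones(mesh.n_nodes, bool))
        assert np.abs(element_strains(sol)).max() < 1e-12

    def test_linear_axial_field_gives_exact_ezz(self):
        mesh = rect_mesh(1.0, 1.0, 0.25, origin=(0.5, 0.0))
        alpha = 2.5e-3
        u = np.column_stack([np.zeros(mesh.n_nodes),
                             alpha * mesh.node_coords[:, 1]])
        sol = SolutionFields(u, np.zeros(mesh.n_nodes), mesh,
                             np.ones(mesh.n_nodes, bool))
        s = element_strains(sol)
        assert np.allclose(s[:, 1], alpha, atol=1e-14)
        assert np.abs(s[:, [0, 3]]).max() < 1e-14

    def test_centroid_strains_match_finite_differences(self):
        rng = np.random.default_rng(7)
        mesh = rect_mesh(1.0, 1.0, 0.25, origin=(1.0, 0.0))
        coords = mesh.node_coords.copy()
        interior = (coords[:, 0] > 1.01) & (coords[:, 0] < 1.99) \
            & (coords[:, 1] > 0.01) & (coords[:, 1] < 0.99)
        coords[interior] += rng.uniform(-0.03, 0.03, (interior.sum(), 2))
        mesh.node_coords = coords
        u = rng.uniform(-1e-3, 1e-3, (mesh.n_nodes, 2))
        sol = SolutionFields(u, np.zeros(mesh.n_nodes), mesh,
                             np.ones(mesh.n_nodes, bool))
        s = element_strains(sol)

        d = 1e-6
        for e in rng.choice(mesh.n_elements, 5, replace=False):
            xe = coords[mesh.elements[e]]
            ue = u[mesh.elements[e]]

            def interp(xi, eta, arr):
                N = fem.shape_functions(xi, eta)
                return N @ arr

            du_dxi = (interp(d, 0, ue) - interp(-d, 0, ue)) / (2 * d)
            du_deta = (interp(0, d, ue) - interp(0, -d, ue)) / (2 * d)
            dx_dxi = (interp(d, 0, xe) - interp(-d, 0, xe)) / (2 * d)
            dx_deta = (interp(0, d, xe) - interp(0, -d, xe)) / (2 * d)
            J = np.column_stack([dx_dxi, dx_deta])
            grad = np.column_stack([du_dxi, du_deta]) @ np.linalg.inv(J)
            r_c = interp(0, 0, xe)[0]
            u_c = interp(0, 0, ue)[0]
            expect = [grad[0, 0], grad[1, 1], u_c / r_c, grad[0, 1] + grad[1, 0]]
            assert np.allclose(s[e], expect, atol=1e-6)


class TestOctahedralShear:
    def test_hydrostatic_state_vanishes(self):
        c = 1e-3
        assert octahedral_shear_strain(np.array([c, c, c, 0.0])) == pytest.approx(0.0)

    def test_uniaxial_closed_form(self):
        e = 4e-3
        expect = 2.0 * np.sqrt(2.0) / 3.0 * e
        assert octahedral_shear_strain(np.array([e, 0, 0, 0])) == pytest.approx(expect)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_dense_eigendecomposition(self, seed):
        rng = np.random.default_rng(seed)
        err, ezz, ehoop, grz = rng.uniform(-1e-2, 1e-2, 4)
        T = np.array([[err, grz / 2, 0], [grz / 2, ezz, 0], [0, 0, ehoop]])
        ev = np.linalg.eigvalsh(T)
        expect = (2.0 / 3.0) * np.sqrt((ev[0] - ev[1]) ** 2 + (ev[1] - ev[2]) ** 2
                                       + (ev[2] - ev[0]) ** 2)
        got = octahedral_shear_strain(np.array([err, ezz, ehoop, grz]))
        assert got == pytest.approx(expect, rel=1e-12)


class TestDarcy:
    def _elastic_solution(self, p_field):
        mesh = rect_mesh(1.0, 1.0, 0.25, origin=(1.0, 0.0))
        return mesh, SolutionFields(np.zeros((mesh.n_nodes, 2)), p_field(mesh),
                                    mesh, np.ones(mesh.n_nodes, bool))

    def test_uniform_pressure_gives_zero_velocity(self):
        mesh, sol = self._elastic_solution(lambda m: np.full(m.n_nodes, 2.5))
        v = darcy_velocity(sol, {"callus": GRANULATION})
        assert np.abs(v).max() < 1e-12

    def test_linear_pressure_closed_form(self):
        beta = 0.3  # MPa/mm
        mesh, sol = self._elastic_solution(lambda m: beta * m.node_coords[:, 1])
        v = darcy_velocity(sol, {"callus": GRANULATION})
        expect = -GRANULATION.permeability_mm * beta * 1e3  # um/s
        assert np.allclose(v[:, 1], expect, rtol=1e-12)
        assert np.abs(v[:, 0]).max() < 1e-12

    def test_requesting_implant_elements_raises(self, toy):
        mats = toy_materials(toy)
        sol = solve_loadstep(toy.mesh, mats, LoadCase(8.0, 1.0, 2),
                             InterfaceSpec("tied"))
        implant = toy.mesh.elements_in_region("implant")
        with pytest.raises(ValueError, match="implant"):
            darcy_velocity(sol, mats, elements=implant[:3])


class TestStimulusInvariance:
    def test_stimuli_invariant_under_rigid_axial_motion(self, toy):
        mats = toy_materials(toy)
        sol = solve_loadstep(toy.mesh, mats, LoadCase(8.0, 1.0, 3),
                             InterfaceSpec("tied"))
        s0 = fem.compute_stimuli(sol, mats)
        sol.displacement = sol.displacement + np.array([0.0, 5e-3])
        s1 = fem.compute_stimuli(sol, mats)
        assert np.allclose(s1.gamma_oct, s0.gamma_oct, atol=1e-12)
        assert np.allclose(np.nan_to_num(s1.fluid_speed_nu),
                           np.nan_to_num(s0.fluid_speed_nu), atol=1e-12)


class TestContactInterface:
    def test_tied_and_coulomb_modes_agree_on_day_one(self, toy):
        """Both interface treatments must produce the same stimulus regime."""
        mats = toy_materials(toy)
        load = LoadCase(8.0, 1.0, 5)
        cal = toy.mesh.elements_in_region("callus")
        means = {}
        for mode in ("tied", "coulomb_penalty"):
            sol = solve_loadstep(toy.mesh, mats, load, InterfaceSpec(mode))
            stim = fem.compute_stimuli(sol, fem.material_arrays(sol.mesh, mats))
            S = stim.gamma_oct[cal] / 0.0375 + stim.fluid_speed_nu[cal] / 3.0
            assert np.all(np.isfinite(S))
            means[mode] = S.mean()
        rel = abs(means["tied"] - means["coulomb_penalty"]) / means["tied"]
        assert rel < 0.2

    def test_frictionless_contact_converges(self, toy):
        mats = toy_materials(toy)
        sol = solve_loadstep(toy.mesh, mats, LoadCase(8.0, 1.0, 3),
                             InterfaceSpec("coulomb_penalty", 0.0,
                                           max_iterations=80))
        assert np.all(np.isfinite(sol.displacement))
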