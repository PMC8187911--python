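"""FE solver verification: patch test, bar, strains, energy, contact, Lamé."""

import numpy as np
import pytest
import scipy.sparse as sp

from calvaria.benchmarks import box_mesh, sphere_in_shell
from calvaria.fe_core import (
    ContactKinematics,
    ContactPair,
    ContactSpec,
    Material,
    MaterialCard,
    assemble,
    compute_strains,
    contact_forces,
    element_matrices,
    solve_dirichlet,
    solve_free,
    solve_increment,
)
from calvaria.mesh import LabeledMesh, to_quadratic


def _card(label="block", E=3000.0, nu=0.3, growth=()):
    card = MaterialCard.baseline()
    card.by_label[label] = Material(E, nu)
    card.growth_labels = frozenset(growth)
    return card


def _distorted_box():
    m = box_mesh((2.0, 1.5, 1.0), (3, 3, 3))
    rng = np.random.default_rng(7)
    interior = np.ones(len(m.points), dtype=bool)
    interior[np.unique(m.boundary_faces())] = False
    m.points[interior] += 0.06 * rng.standard_normal((interior.sum(), 3))
    return m


# Independent closed-form for the thick-wall sphere benchmark: solve the
# 3-unknown radial BVP (core u = A r; shell u = C r + D/r^2) numerically.
def lame_pressure_oracle(a, b, E1, nu1, E2, nu2, alpha):
    K1 = E1 / (3 * (1 - 2 * nu1))
    K2 = E2 / (3 * (1 - 2 * nu2))
    G2 = E2 / (2 * (1 + nu2))
    M = np.array([
        [a, -a, -1 / a**2],
        [3 * K1, -3 * K2, 4 * G2 / a**3],
        [0, 3 * K2, -4 * G2 / b**3],
    ])
    A, C, D = np.linalg.solve(M, np.array([0.0, 3 * K1 * alpha, 0.0]))
    return -(3 * K2 * C - 4 * G2 * D / a**3)


@pytest.mark.parametrize("order", [1, 2])
def test_patch_test_affine_field(order):
    """Affine boundary displacements reproduce the affine field everywhere."""
    m = _distorted_box()
    if order == 2:
        m = to_quadratic(m)
    card = _card()
    K, _ = assemble(m, card)
    A = np.array([[0.01, 0.002, 0.0], [0.003, -0.004, 0.001], [0.0, 0.005, 0.02]])
    uex = m.points @ A.T + np.array([0.1, -0.2, 0.05])
    if order == 1:
        bnodes = np.unique(m.boundary_faces())
    else:
        # boundary = all nodes on the original box surface planes
        tol = 1e-9
        p = m.points
        onb = (np.isclose(p[:, 0], 0) | np.isclose(p[:, 0], 2.0)
               | np.isclose(p[:, 1], 0) | np.isclose(p[:, 1], 1.5)
               | np.isclose(p[:, 2], 0) | np.isclose(p[:, 2], 1.0))
        bnodes = np.flatnonzero(onb)
    fixed = (3 * bnodes[:, None] + np.arange(3)).ravel()
    u = solve_dirichlet(K, np.zeros(K.shape[0]), fixed, uex[bnodes].ravel())
    err = np.abs(u.reshape(-1, 3) - uex).max() / np.abs(uex).max()
    assert err < 1e-8


def test_stiffness_row_sums_vanish_single_tet():
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    Ke, _ = element_matrices(pts, np.array([[0, 1, 2, 3]]),
                             [3000.0], [0.3], [0.0])
    # translation invariance: sum over nodes of each dof direction is zero
    r = Ke[0].reshape(4, 3, 4, 3).sum(axis=2)
    assert np.abs(r).max() < 1e-9 * np.abs(Ke).max()


def test_assembly_matches_per_element_oracle(rng):
    """Global matrix equals the dense sum of independently computed element
    stiffnesses (direct B-matrix integration per element)."""
    m = box_mesh((1.0, 1.0, 1.0), (1, 1, 1))  # 6 tets
    E, nu = 123.0, 0.27
    card = _card(E=E, nu=nu)
    K, _ = assemble(m, card)
    n = len(m.points)
    dense = np.zeros((3 * n, 3 * n))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    for tet in m.corner_tets:
        X = m.points[tet]
        Mmat = np.column_stack([np.ones(4), X])
        C = np.linalg.inv(Mmat)
        grads = C[1:4, :].T
        vol = abs(np.linalg.det(Mmat)) / 6.0
        B = np.zeros((6, 12))
        for a in range(4):
            gx, gy, gz = grads[a]
            B[0, 3 * a] = gx
            B[1, 3 * a + 1] = gy
            B[2, 3 * a + 2] = gz
            B[3, 3 * a], B[3, 3 * a + 1] = gy, gx
            B[4, 3 * a + 1], B[4, 3 * a + 2] = gz, gy
            B[5, 3 * a], B[5, 3 * a + 2] = gz, gx
        Ke = vol * B.T @ D @ B
        dofs = (3 * tet[:, None] + np.arange(3)).ravel()
        dense[np.ix_(dofs, dofs)] += Ke
    assert np.allclose(K.toarray(), dense, atol=1e-9 * np.abs(dense).max())


def test_zero_eigenstrain_zero_displacement():
    m = box_mesh((1, 1, 1), (2, 2, 2))
    K, f = assemble(m, _card(growth={"block"}), alpha=0.0)
    assert np.linalg.norm(f) == 0.0
    fixed = (3 * np.unique(m.boundary_faces())[:, None] + np.arange(3)).ravel()
    u = solve_dirichlet(K, f, fixed)
    assert np.abs(u).max() == 0.0


def test_uniaxial_bar_strain_and_energy():
    """End traction t: axial strain = t/E exactly; strain energy = work/2."""
    E, t_load = 200.0, 5.0
    m = box_mesh((10.0, 2.0, 2.0), (5, 2, 2))
    card = _card(E=E, nu=0.3)
    K, _ = assemble(m, card)
    p = m.points
    left = np.flatnonzero(np.isclose(p[:, 0], 0.0))
    right = np.flatnonzero(np.isclose(p[:, 0], 10.0))
    fixed = list(3 * left)  # ux = 0 on the left face
    pin = left[np.argmin(p[left, 1] + p[left, 2])]
    fixed += [3 * pin + 1, 3 * pin + 2]
    pin2 = left[np.argmax(p[left, 1] - p[left, 2])]
    fixed += [3 * pin2 + 2]
    f = np.zeros(K.shape[0])
    # consistent lumped traction on the right face (tributary areas)
    faces = m.boundary_faces()
    fc = p[faces].mean(axis=1)
    rf = faces[np.isclose(fc[:, 0], 10.0)]
    tri = p[rf]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    for k in range(3):
        np.add.at(f, 3 * rf[:, k], t_load * areas / 3.0)
    u = solve_dirichlet(K, f, np.array(fixed))
    strain, eps_h = compute_strains(m, u.reshape(-1, 3))
    assert strain[:, 0] == pytest.approx(t_load / E, rel=1e-9)
    # energy consistency: 1/2 u'Ku equals 1/2 f'u
    assert 0.5 * u @ (K @ u) == pytest.approx(0.5 * f @ u, rel=1e-6)


class TestStrains:
    def test_zero_displacement(self):
        m = box_mesh((1, 1, 1), (1, 1, 1))
        _, eps_h = compute_strains(m, np.zeros((len(m.points), 3)))
        assert np.abs(eps_h).max() == 0.0

    def test_affine_dilation_exact(self):
        m = box_mesh((1, 1, 1), (2, 2, 2))
        u = 0.05 * m.points
        _, eps_h = compute_strains(m, u)
        np.testing.assert_allclose(eps_h, 0.05, rtol=1e-12)

    def test_matches_finite_difference_oracle(self, rng):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        mesh = LabeledMesh(pts, np.array([[0, 1, 2, 3]]), np.zeros(1, np.int32),
                           ["block"])
        u = 0.01 * rng.standard_normal((4, 3))
        _, eps_h = compute_strains(mesh, u)
        # finite-difference gradient of the interpolated field
        h = 1e-6
        x0 = pts.mean(axis=0)
        Mmat = np.column_stack([np.ones(4), pts])

        def interp(x):
            w = np.linalg.solve(Mmat.T, np.concatenate([[1.0], x]))
            return w @ u

        tr = sum(
            (interp(x0 + h * e)[i] - interp(x0 - h * e)[i]) / (2 * h)
            for i, e in enumerate(np.eye(3))
        )
        assert eps_h[0] == pytest.approx(tr / 3.0, abs=1e-6)


def test_free_expansion_is_pure_dilation():
    m = box_mesh((2, 1, 1), (3, 2, 2))
    K, f = assemble(m, _card(E=100.0, nu=0.48, growth={"block"}), alpha=0.02)
    u = solve_free(K, f, m.points)
    _, eps_h = compute_strains(m, u.reshape(-1, 3))
    np.testing.assert_allclose(eps_h, 0.02, atol=1e-8)


class TestLame:
    E1, nu1, E2, nu2, alpha = 100.0, 0.48, 3000.0, 0.3, 0.01

    def _bonded_pressure(self, n_theta):
        s = sphere_in_shell(20.0, 26.0, n_theta=n_theta)
        card = MaterialCard.baseline()
        card.by_label = {"core": Material(self.E1, self.nu1),
                         "shell": Material(self.E2, self.nu2)}
        card.growth_labels = frozenset({"core"})
        K, f = assemble(s, card, self.alpha)
        u = solve_free(K, f, s.points)
        shell_idx = np.flatnonzero(s.element_labels() == "shell")
        sub = LabeledMesh(s.points, s.corner_tets[shell_idx],
                          s.region_id[shell_idx], list(s.region_names))
        Ks, _ = assemble(sub, card, 0.0)
        fr = (Ks @ u).reshape(-1, 3)
        r = np.linalg.norm(s.points, axis=1)
        iface = np.flatnonzero(np.abs(r - 20.0) < 1e-6)
        rhat = s.points[iface] / 20.0
        Fn = np.einsum("ij,ij->i", fr[iface], rhat).sum()
        return Fn / (4 * np.pi * 20.0**2), u, s

    def test_bonded_interface_pressure_within_5pct(self):
        p_fe, _, _ = self._bonded_pressure(14)
        p_an = lame_pressure_oracle(20, 26, self.E1, self.nu1,
                                    self.E2, self.nu2, self.alpha)
        assert p_fe == pytest.approx(p_an, rel=0.05)

    def test_mesh_convergence_under_refinement(self):
        _, u1, s1 = self._bonded_pressure(12)
        _, u2, s2 = self._bonded_pressure(24)

        def iface_ur(u, s):
            r = np.linalg.norm(s.points, axis=1)
            sel = np.abs(r - 20.0) < 1e-6
            return np.einsum("ij,ij->i", u.reshape(-1, 3)[sel],
                             s.points[sel] / 20.0).mean()

        assert iface_ur(u1, s1) == pytest.approx(iface_ur(u2, s2), rel=0.02)

    def test_contact_mean_pressure_within_10pct(self):
        sc = sphere_in_shell(20.0, 26.0, n_theta=14, bonded=False)
        card = MaterialCard.baseline()
        card.by_label = {"core": Material(self.E1, self.nu1),
                         "shell": Material(self.E2, self.nu2)}
        card.growth_labels = frozenset({"core"})
        outer = sc.node_sets["outer"]
        p = sc.points[outer]
        picks = np.array([outer[np.argmax(p[:, 2])], outer[np.argmin(p[:, 2])],
                          outer[np.argmax(p[:, 0])]])
        fixed = (3 * picks[:, None] + np.arange(3)).ravel()
        st = solve_increment(sc, card, self.alpha,
                             contact=ContactSpec(pair="core_shell"),
                             constraints=fixed)
        p_an = lame_pressure_oracle(20, 26, self.E1, self.nu1,
                                    self.E2, self.nu2, self.alpha)
        assert st.contact_node_pressure.mean() == pytest.approx(p_an, rel=0.10)
        # complementarity on the converged increment
        pen = np.maximum(-st.contact_node_gap, 0.0)
        assert pen.max() <= 0.5
        assert st.contact_node_pressure.min() >= 0.0


class TestContactUnit:
    def _pair(self):
        sc = sphere_in_shell(10.0, 13.0, n_theta=8, bonded=False)
        return sc, ContactPair(sc, ContactSpec(pair="core_shell"))

    def test_pressure_equals_penalty_times_penetration(self):
        sc, pair = self._pair()
        ndof = 3 * len(sc.points)
        gap0, n, fidx, bary = pair.find(sc.points, np.zeros(ndof))
        frz = ContactKinematics(gap0, n, fidx, bary)
        delta = 0.004
        u = np.zeros((len(sc.points), 3))
        core_nodes = np.unique(sc.corner_tets[sc.element_labels() == "core"])
        r = np.linalg.norm(sc.points[core_nodes], axis=1)
        u[core_nodes] = delta / 10.0 * sc.points[core_nodes]
        _, _, pressure, gap, active = contact_forces(pair, frz, u.ravel(), ndof)
        sel = np.isclose(np.linalg.norm(sc.points[pair.slave_nodes], axis=1), 10.0)
        # smoothed nodal normals deviate from radial by < 1 % at this mesh
        np.testing.assert_allclose(pressure[sel], 600.0 * delta, rtol=0.01)

    def test_open_gap_no_pressure(self):
        sc, pair = self._pair()
        ndof = 3 * len(sc.points)
        gap0, n, fidx, bary = pair.find(sc.points, np.zeros(ndof))
        frz = ContactKinematics(gap0, n, fidx, bary)
        u = np.zeros((len(sc.points), 3))
        core_nodes = np.unique(sc.corner_tets[sc.element_labels() == "core"])
        u[core_nodes] = -0.01 / 10.0 * sc.points[core_nodes]  # shrink: open
        f, Kc, pressure, gap, active = contact_forces(pair, frz, u.ravel(), ndof)
        sel = np.isclose(np.linalg.norm(sc.points[pair.slave_nodes], axis=1), 10.0)
        assert pressure[sel].max() == 0.0
        assert np.abs(f).max() == 0.0

    def test_frictionless_tangential_force_zero(self):
        sc = sphere_in_shell(10.0, 13.0, n_theta=8, bonded=False)
        spec = ContactSpec(pair="core_shell", friction_coefficient=0.0)
        pair = ContactPair(sc, spec)
        ndof = 3 * len(sc.points)
        gap0, n, fidx, bary = pair.find(sc.points, np.zeros(ndof))
        frz = ContactKinematics(gap0, n, fidx, bary)
        rng = np.random.default_rng(3)
        u = np.zeros((len(sc.points), 3))
        core_nodes = np.unique(sc.corner_tets[sc.element_labels() == "core"])
        u[core_nodes] = 0.002 * sc.points[core_nodes] / 10.0
        u[core_nodes, 0] += 0.001  # tangential shift
        f, _, pressure, gap, active = contact_forces(pair, frz, u.ravel(), ndof)
        # force on each active slave node must be purely normal
        fs = f.reshape(-1, 3)[pair.slave_nodes[active]]
        nn = frz.n[active]
        tangential = fs - np.einsum("ij,ij->i", fs, nn)[:, None] * nn
        assert np.abs(tangential).max() <= 1e-9 * max(np.abs(fs).max(), 1.0)

    def test_coulomb_cap_respected(self):
        sc = sphere_in_shell(10.0, 13.0, n_theta=8, bonded=False)
        spec = ContactSpec(pair="core_shell", friction_coefficient=0.1)
        pair = ContactPair(sc, spec)
        ndof = 3 * len(sc.points)
        gap0, n, fidx, bary = pair.find(sc.points, np.zeros(ndof))
        frz = ContactKinematics(gap0, n, fidx, bary)
        u = np.zeros((len(sc.points), 3))
        core_nodes = np.unique(sc.corner_tets[sc.element_labels() == "core"])
        u[core_nodes] = 0.002 * sc.points[core_nodes] / 10.0
        u[core_nodes, 0] += 0.05  # large slip: sliding regime
        f, _, pressure, gap, active = contact_forces(pair, frz, u.ravel(), ndof)
        fs = f.reshape(-1, 3)[pair.slave_nodes[active]]
        nn = frz.n[active]
        fn = -np.einsum("ij,ij->i", fs, nn)
        ft = np.linalg.norm(fs + fn[:, None] * nn, axis=1)
        assert np.all(ft <= 0.1 * np.abs(fn) * (1 + 1e-9) + 1e-12)


def test_missing_material_reported_by_label():
    m = box_mesh((1, 1, 1), (1, 1, 1), label="mystery")
    card = MaterialCard()  # no defaults, no entries
    with pytest.raises(KeyError, match="mystery"):
        assemble(m, card)


def test_unsolved_state_pressure_extraction_errors(skull_coarse):
    from calvaria.fe_core import SimulationState, extract_contact_pressure

    state = SimulationState(u=np.zeros((len(skull_coarse.points), 3)))
    with pytest.raises(ValueError):
        extract_contact_pressure(state, skull_coarse)
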