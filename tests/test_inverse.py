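import numpy as np
import pytest

from dotrecon.forward import AcquisitionConfig, BoundaryData, sample_boundary, solve_all_sources
from dotrecon.inverse import (
    TikhonovNewton,
    _solve_state,
    compute_jacobian,
    default_lambda,
    tr_update,
)
from dotrecon.mesh import build_mesh
from dotrecon.optics import OpticalProperties
from dotrecon.phantoms import Inclusion, PhantomSpec


@pytest.fixture(scope="module")
def coarse_setup():
    """Small homogeneous problem: 60 mm disk, 8 sources, ~70 nodes."""
    bg = OpticalProperties(0.01, 1.0)
    spec = PhantomSpec(60.0, 50.0, bg)
    acq = AcquisitionConfig(n_sources=8, noise_level=0.0)
    mesh = build_mesh(spec, 8.0, layout_m=8)
    oc = 2 * np.pi * spec.frequency_mhz * 1e-3 / acq.light_speed
    mu_a = np.full(mesh.n_nodes, bg.mu_a)
    mu_s = np.full(mesh.n_nodes, bg.mu_s_prime)
    state = _solve_state(mesh, acq, mu_a, mu_s, oc, bg.mu_s_prime)
    return spec, acq, mesh, oc, state


class TestJacobian:
    def test_shape(self, coarse_setup):
        spec, acq, mesh, oc, state = coarse_setup
        J = compute_jacobian(state, mesh, acq)
        assert J.shape == (2 * 8 * 7, 2 * mesh.n_nodes)

    def test_matches_finite_differences(self, coarse_setup):
        spec, acq, mesh, oc, state = coarse_setup
        J = compute_jacobian(state, mesh, acq)
        rng = np.random.default_rng(0)
        bg = spec.background
        for node in rng.choice(mesh.n_nodes, 5, replace=False):
            for chan, base in ((0, bg.mu_a), (1, bg.mu_s_prime)):
                eps = 0.01 * base  # 1% nodal perturbation
                cols = []
                for sign in (+1, -1):
                    mu_a = np.full(mesh.n_nodes, bg.mu_a)
                    mu_s = np.full(mesh.n_nodes, bg.mu_s_prime)
                    (mu_a if chan == 0 else mu_s)[node] += sign * eps
                    cols.append(
                        _solve_state(mesh, acq, mu_a, mu_s, oc, bg.mu_s_prime).modeled
                    )
                fd = (cols[0] - cols[1]) / (2 * eps)
                ana = J[:, node + chan * mesh.n_nodes]
                scale = np.abs(fd).max()
                assert np.abs(ana - fd).max() < 0.05 * scale

    def test_absorption_columns_reduce_log_amplitude(self, coarse_setup):
        spec, acq, mesh, oc, state = coarse_setup
        J = compute_jacobian(state, mesh, acq)
        mn = 8 * 7
        col_sums = J[:mn, : mesh.n_nodes].sum(axis=0)
        assert (col_sums < 0).all()  # more absorption -> less light

    def test_zero_perturbation_maps_to_zero(self, coarse_setup):
        _, acq, mesh, _, state = coarse_setup
        J = compute_jacobian(state, mesh, acq)
        assert np.abs(J @ np.zeros(2 * mesh.n_nodes)).max() == 0.0


class TestTRUpdate:
    def test_huge_lambda_kills_update(self, rng):
        J = rng.normal(size=(30, 12))
        r = rng.normal(size=30)
        dx = tr_update(J, r, lam=1e12)
        assert np.linalg.norm(dx) < 1e-10

    def test_zero_lambda_square_system_is_direct_solve(self, rng):
        J = rng.normal(size=(8, 8)) + 4 * np.eye(8)
        r = rng.normal(size=8)
        dx = tr_update(J, r, lam=0.0)
        assert np.allclose(dx, np.linalg.solve(J, r), atol=1e-8)

    def test_stacked_equals_normal_equations(self, rng):
        J = rng.normal(size=(40, 15))
        r = rng.normal(size=40)
        lam = 0.3
        dx = tr_update(J, r, lam)
        ref = np.linalg.solve(J.T @ J + lam**2 * np.eye(15), J.T @ r)
        assert np.abs(dx - ref).max() < 1e-6

    def test_update_norm_monotone_in_lambda(self, coarse_setup, rng):
        _, acq, mesh, _, state = coarse_setup
        J = compute_jacobian(state, mesh, acq)
        r = rng.normal(0, 0.01, size=J.shape[0])
        norms = [np.linalg.norm(tr_update(J, r, lam)) for lam in (1e-3, 1e-2, 1e-1, 1.0)]
        assert all(np.diff(norms) < 0)

    def test_nonfinite_residual_rejected(self, rng):
        J = rng.normal(size=(6, 4))
        with pytest.raises(FloatingPointError):
            tr_update(J, np.array([np.nan] * 6), 0.1)


class TestReconstruct:
    def test_truth_initialization_is_fixed_point(self, coarse_setup):
        # data simulated on the same mesh as the inversion, no noise:
        # starting at the truth leaves the objective at ~0
        spec, acq, mesh, oc, state = coarse_setup
        m = acq.n_sources
        amp = np.exp(state.modeled[: m * (m - 1)]).reshape(m, m - 1)
        pha = state.modeled[m * (m - 1) :].reshape(m, m - 1)
        data = BoundaryData(amp, pha)
        tn = TikhonovNewton(max_iter=3)
        tn.reconstruct(data, mesh, acq, spec.background, spec.frequency_mhz)
        assert tn.objective_history_[0] < 1e-16
        assert np.allclose(tn.mu_a_, spec.background.mu_a, rtol=1e-6)

    def test_objective_non_increasing_and_localization(self):
        bg = OpticalProperties(0.01, 1.0)
        inc = Inclusion((8.0, 5.0), 7.0, OpticalProperties(0.02, 2.0))
        spec = PhantomSpec(60.0, 50.0, bg, (inc,))
        acq = AcquisitionConfig(n_sources=16, noise_level=0.0)
        from dotrecon.forward import simulate_boundary_data

        data, _ = simulate_boundary_data(spec, acq, 3.0)
        inv_mesh = build_mesh(PhantomSpec(60.0, 50.0, bg), 5.0, layout_m=16)
        tn = TikhonovNewton(max_iter=6)
        img = tn.reconstruct(data, inv_mesh, acq, bg, spec.frequency_mhz)
        assert (np.diff(tn.objective_history_) < 0).all()
        # centroid of the top-decile mu_a pixels lands within 10 mm of truth
        mu = img.mu_a
        thr = np.quantile(mu[img.mask], 0.9)
        ys, xs = np.nonzero((mu >= thr) & img.mask)
        px = img.pixel_size
        cx = (-30.0 + (xs + 0.5) * px).mean()
        cy = (-30.0 + (ys + 0.5) * px).mean()
        assert np.hypot(cx - 8.0, cy - 5.0) < 10.0
        # contrast recovered (blurred): peak above background
        assert mu.max() > 1.2 * bg.mu_a

    def test_default_lambda_scales_with_jacobian(self, coarse_setup):
        _, acq, mesh, _, state = coarse_setup
        J = compute_jacobian(state, mesh, acq)
        assert default_lambda(J) == pytest.approx(
            0.1 * np.sqrt((J**2).sum(axis=0).max())
        )

    def test_normalized_data_rejected(self, coarse_setup):
        spec, acq, mesh, _, _ = coarse_setup
        data = BoundaryData(np.ones((8, 7)), np.zeros((8, 7)), normalized=True)
        with pytest.raises(ValueError):
            TikhonovNewton().reconstruct(data, mesh, acq, spec.background, 50.0)
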