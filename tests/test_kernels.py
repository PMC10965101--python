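import numpy as np
import pytest

from kcsdkit import (BasisConfig, ElectrodeSetup, EstimationSpace,
                     KernelModel, SliceGeometry, build_kernels, fit,
                     moi_potential_basis, okcsd_model, potential_basis_2d)
from kcsdkit.basis import csd_design_matrix, get_radial_potential
from kcsdkit.kernels import _reach


def brute_force_kernels(setup, basis, space):
    """Triple-loop oracle for K, K̃ and the potential cross-kernel."""
    d_max = _reach(setup, basis, space)
    table = get_radial_potential(basis.dim, basis.family, basis.R, basis.h,
                                 setup.sigma, d_max)
    M = basis.n_bases
    N = setup.n_electrodes
    P = space.n_points
    b_el = np.zeros((M, N))
    b_est = np.zeros((M, P))
    bt_est = csd_design_matrix(basis, space.points)
    for m in range(M):
        for j in range(N):
            b_el[m, j] = table(np.linalg.norm(setup.positions[j]
                                              - basis.centers[m]))
        for p in range(P):
            b_est[m, p] = table(np.linalg.norm(space.points[p]
                                               - basis.centers[m]))
    K = np.zeros((N, N))
    Kt = np.zeros((P, N))
    Ktp = np.zeros((P, N))
    for i in range(N):
        for j in range(N):
            for m in range(M):
                K[i, j] += b_el[m, i] * b_el[m, j]
    for p in range(P):
        for j in range(N):
            for m in range(M):
                Kt[p, j] += bt_est[m, p] * b_el[m, j]
                Ktp[p, j] += b_est[m, p] * b_el[m, j]
    return K, Kt, Ktp


class TestBuildKernels:
    def test_single_basis_rank_one(self):
        setup = ElectrodeSetup(np.array([[0.0], [0.5], [1.0]]))
        space = EstimationSpace(np.array([[0.25]]))
        basis = BasisConfig("gaussian", R=0.2, h=0.1,
                            centers=np.array([[0.5]]))
        model = build_kernels(setup, basis, space)
        d_max = _reach(setup, basis, space)
        table = get_radial_potential(1, "gaussian", 0.2, 0.1, 1.0, d_max)
        v = table(np.abs(setup.positions[:, 0] - 0.5))
        np.testing.assert_allclose(model.K, np.outer(v, v), rtol=1e-12)
        assert np.linalg.matrix_rank(model.K, tol=1e-12) == 1

    def test_matches_brute_force(self, probe_1d):
        K, Kt, Ktp = brute_force_kernels(probe_1d["setup"], probe_1d["basis"],
                                         probe_1d["space"])
        model = probe_1d["model"]
        scale = np.abs(model.K).max()
        assert np.abs(model.K - K).max() < 1e-10 * scale
        assert np.abs(model.Ktilde - Kt).max() < 1e-10 * np.abs(Kt).max()
        assert np.abs(model.Ktilde_pot - Ktp).max() < 1e-10 * np.abs(Ktp).max()

    def test_estimation_at_electrodes_reuses_kernel(self):
        setup = ElectrodeSetup(np.linspace(0, 1, 5)[:, None])
        space = EstimationSpace(setup.positions.copy())
        basis = BasisConfig("gaussian", R=0.2, h=0.1,
                            centers=np.linspace(0, 1, 7)[:, None])
        model = build_kernels(setup, basis, space)
        np.testing.assert_array_equal(model.Ktilde_pot, model.K)

    def test_dimensionality_mismatch(self):
        setup = ElectrodeSetup(np.array([[0.0], [1.0]]))
        space = EstimationSpace(np.array([[0.0, 0.0]]))
        basis = BasisConfig("gaussian", R=0.2, h=0.1,
                            centers=np.array([[0.5]]))
        with pytest.raises(ValueError, match="dimensionality"):
            build_kernels(setup, basis, space)

    def test_psd_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            setup = ElectrodeSetup(
                np.sort(rng.uniform(0, 1, size=n))[:, None])
            space = EstimationSpace(rng.uniform(0, 1, size=(4, 1)))
            basis = BasisConfig("gaussian", R=float(rng.uniform(0.05, 0.3)),
                                h=0.1,
                                centers=np.linspace(0, 1, 6)[:, None])
            model = build_kernels(setup, basis, space)
            assert np.abs(model.K - model.K.T).max() < 1e-12
            assert model.eigvals[-1] > -1e-8 * model.eigvals[0]


class TestFit:
    def test_identity_kernel(self):
        model = KernelModel(K=np.eye(2), Ktilde=np.eye(2),
                            Ktilde_pot=np.eye(2), lam=0.0)
        est = fit(model, np.array([4.0, -2.0]))
        np.testing.assert_allclose(est.beta, [4.0, -2.0], atol=1e-12)

    def test_large_lambda_underfits_to_flat(self, probe_1d):
        model = probe_1d["model"]
        rng = np.random.default_rng(0)
        V = rng.normal(size=model.n_electrodes)
        est0 = fit(model, V, lam=0.0)
        big = fit(model, V, lam=1e12 * model.eigvals[0])
        assert np.abs(big.csd).max() < 1e-6 * np.abs(est0.csd).max()
        assert np.linalg.norm(big.beta) < 1e-6 * np.linalg.norm(est0.beta)

    def test_in_span_exact_recovery(self, probe_1d):
        # truth in the basis span, noise-free, lambda = 0
        setup, basis, space = (probe_1d["setup"], probe_1d["basis"],
                               probe_1d["space"])
        model = probe_1d["model"]
        rng = np.random.default_rng(5)
        alpha = rng.normal(size=basis.n_bases)
        d_max = _reach(setup, basis, space)
        table = get_radial_potential(1, "gaussian", basis.R, basis.h,
                                     setup.sigma, d_max)
        pot_el = table(np.abs(setup.positions[:, 0][None, :]
                              - basis.centers[:, 0][:, None]))
        V = pot_el.T @ alpha
        est = fit(model, V, lam=0.0)
        truth = csd_design_matrix(basis, space.points).T @ alpha
        err = (np.linalg.norm(est.csd - truth) / np.linalg.norm(truth))
        assert err < 1e-6
        # interpolation passes through the data (Eq 10 consistency)
        np.testing.assert_allclose(model.K @ est.beta, V, atol=1e-8)

    def test_linearity_in_potentials(self, probe_1d):
        model = probe_1d["model"]
        rng = np.random.default_rng(2)
        V1 = rng.normal(size=model.n_electrodes)
        V2 = rng.normal(size=model.n_electrodes)
        a, b = 1.7, -0.3
        lam = 1e-6 * model.eigvals[0]
        combined = fit(model, a * V1 + b * V2, lam=lam)
        separate = (a * fit(model, V1, lam=lam).csd
                    + b * fit(model, V2, lam=lam).csd)
        scale = np.abs(separate).max()
        np.testing.assert_allclose(combined.csd, separate, atol=1e-10 * scale)

    def test_multi_sample_batch(self, probe_1d):
        model = probe_1d["model"]
        rng = np.random.default_rng(3)
        V = rng.normal(size=(model.n_electrodes, 4))
        est = fit(model, V, lam=1e-8)
        scale = np.abs(est.csd).max()
        for t in range(4):
            single = fit(model, V[:, t], lam=1e-8)
            np.testing.assert_allclose(est.csd[:, t], single.csd,
                                       atol=1e-7 * scale)

    def test_wrong_row_count(self, probe_1d):
        with pytest.raises(ValueError, match="rows"):
            fit(probe_1d["model"], np.zeros(3))


class TestOkcsd:
    def test_equals_regular_placement(self, probe_1d):
        setup, basis, space = (probe_1d["setup"], probe_1d["basis"],
                               probe_1d["space"])
        model = okcsd_model(setup, basis.centers, space.points, R=basis.R,
                            h=basis.h)
        np.testing.assert_array_equal(model.K, probe_1d["model"].K)
        np.testing.assert_array_equal(model.Ktilde, probe_1d["model"].Ktilde)

    def test_single_estimation_point(self):
        setup = ElectrodeSetup(np.array([[0.0], [1.0]]))
        model = okcsd_model(setup, np.array([[0.3], [0.6]]),
                            np.array([[0.5]]), R=0.2, h=0.1)
        assert model.Ktilde.shape == (1, 2)

    def test_irregular_centers_brute_force(self):
        rng = np.random.default_rng(9)
        setup = ElectrodeSetup(rng.uniform(0, 1, size=(5, 2)))
        centers = rng.uniform(0, 1, size=(7, 2))
        pts = rng.uniform(0, 1, size=(6, 2))
        model = okcsd_model(setup, centers, pts, R=0.3, h=0.2)
        basis = BasisConfig("gaussian", R=0.3, h=0.2, centers=centers)
        space = EstimationSpace(pts)
        K, Kt, _ = brute_force_kernels(setup, basis, space)
        assert np.abs(model.K - K).max() < 1e-10 * np.abs(K).max()
        assert np.abs(model.Ktilde - Kt).max() < 1e-10 * np.abs(Kt).max()


class TestMoI:
    def test_no_contrast_reduces_to_layer_basis(self):
        geom = SliceGeometry(thickness=0.3, sigma_tissue=0.5,
                             sigma_saline=0.5, n_images=10)
        pts = np.array([[0.1, 0.0], [0.4, 0.3], [1.0, 0.5]])
        v_moi = moi_potential_basis([0.0, 0.0], 0.2, 0.1, geom, pts)
        v_std = potential_basis_2d([0.0, 0.0], 0.2, 0.1, 0.5, pts)
        np.testing.assert_allclose(v_moi, v_std, atol=1e-10)

    def test_zero_images_reduces_to_layer_basis(self):
        geom = SliceGeometry(thickness=0.3, sigma_tissue=0.5,
                             sigma_saline=2.0, n_images=0)
        pts = np.array([[0.2, 0.0]])
        v_moi = moi_potential_basis([0.0, 0.0], 0.2, 0.1, geom, pts)
        v_std = potential_basis_2d([0.0, 0.0], 0.2, 0.1, 0.5, pts)
        np.testing.assert_allclose(v_moi, v_std, atol=1e-12)

    def test_thin_layer_matches_image_charge_ladder(self):
        # electrostatics oracle: in the thin-layer limit the kernel is a
        # point charge at the origin plus doubled image charges at heights
        # 2nd with weights W^n (two boundaries: mirror below, saline above)
        from kcsdkit.kernels import _moi_kernel2d
        h, d = 1e-5, 0.3
        rho = np.array([0.2, 0.5, 1.0])
        geom = SliceGeometry(thickness=d, sigma_tissue=1.0,
                             sigma_saline=3.0, n_images=30)
        k = _moi_kernel2d(h, geom)(rho)
        H = 2 * h
        oracle = H / rho
        for n in range(1, 31):
            oracle = oracle + 2 * geom.W**n * H / np.hypot(rho, 2 * n * d)
        np.testing.assert_allclose(k, oracle, rtol=1e-7)

    def test_insulator_limit_image_pair_triples_contribution(self):
        # W -> 1 with a vanishing slice: the first image pair coincides
        # with the source, so n_images=1 gives 3x the free-layer kernel
        from kcsdkit.kernels import _moi_kernel2d
        h, d = 0.05, 1e-9
        rho = np.array([0.3, 0.7])
        base = np.arcsinh(2 * h / rho)
        geom = SliceGeometry(thickness=d, sigma_tissue=1.0,
                             sigma_saline=1e-12, n_images=1)
        assert abs(geom.W - 1.0) < 1e-9
        k = _moi_kernel2d(h, geom)(rho)
        np.testing.assert_allclose(k, 3 * base, rtol=1e-6)

    def test_image_series_geometric_tail_bound(self):
        # truncation error is bounded by the geometric tail of the ladder
        geom_a = SliceGeometry(thickness=0.3, sigma_tissue=0.3,
                               sigma_saline=1.5, n_images=20)
        geom_b = SliceGeometry(thickness=0.3, sigma_tissue=0.3,
                               sigma_saline=1.5, n_images=40)
        pts = np.array([[0.2, 0.0], [0.6, 0.0]])
        va = moi_potential_basis([0.0, 0.0], 0.2, 0.1, geom_a, pts)
        vb = moi_potential_basis([0.0, 0.0], 0.2, 0.1, geom_b, pts)
        W = abs(geom_a.W)
        # first neglected image pair, integrated against a unit source, is
        # at most arsinh((2*21*d + 2h)/rho) - arsinh(...) < 2h/(21*d)
        bound = W**21 / (1 - W) * (2 * 0.1 / (21 * 0.3)) / (2 * np.pi * 0.3)
        assert np.abs(va - vb).max() < bound

    def test_low_contrast_truncation_converges_fast(self):
        geom_a = SliceGeometry(thickness=0.3, sigma_tissue=1.0,
                               sigma_saline=2.5, n_images=20)
        geom_b = SliceGeometry(thickness=0.3, sigma_tissue=1.0,
                               sigma_saline=2.5, n_images=40)
        pts = np.array([[0.2, 0.0]])
        va = moi_potential_basis([0.0, 0.0], 0.2, 0.1, geom_a, pts)
        vb = moi_potential_basis([0.0, 0.0], 0.2, 0.1, geom_b, pts)
        assert abs(geom_a.W) < 0.45
        assert np.abs(va - vb).max() < 1e-8

    def test_moi_kernel_model_builds(self):
        pos = np.array([[i, j] for i in range(3) for j in range(3)], float)
        setup = ElectrodeSetup(pos, sigma=0.3)
        from kcsdkit import default_basis, default_estimation_space
        space = default_estimation_space(setup, 5)
        basis = default_basis(setup, R=1.0, h=0.25)
        geom = SliceGeometry(thickness=0.5, sigma_tissue=0.3,
                             sigma_saline=1.5, n_images=10)
        model = build_kernels(setup, basis, space, geometry=geom)
        assert model.eigvals[0] > 0
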