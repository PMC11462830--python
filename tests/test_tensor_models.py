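import numpy as np
import pytest

from gliomicro._sphere import fibonacci_sphere, rotation_to
from gliomicro.protocol_io import build_scheme
from gliomicro.tensor_models import (
    DKIEstimator,
    DTIEstimator,
    KurtosisFit,
    TensorFit,
    awf_from_kurtosis,
    dki_metrics,
    dti_metrics,
    fit_dki,
    fit_dti,
    quadratic_form,
    quartic_form,
)


def _dti_signal(D, scheme, s0=1.0):
    dapp = np.einsum("ni,ij,nj->n", scheme.bvecs, D, scheme.bvecs)
    return s0 * np.exp(-scheme.bvals * dapp)


def _dki_signal(d6, w15, scheme, s0=1.0):
    md = d6[:3].mean()
    dapp = quadratic_form(d6, scheme.bvecs)
    vapp = quartic_form(w15, scheme.bvecs) * md**2
    return s0 * np.exp(-scheme.bvals * dapp + scheme.bvals**2 / 6.0 * vapp)


class TestDTI:
    def test_noise_free_recovery(self, scheme):
        D = np.diag([1.7, 0.3, 0.3])
        fit = fit_dti(_dti_signal(D, scheme), scheme)
        assert np.abs(fit.eigenvalues - [1.7, 0.3, 0.3]).max() < 1e-6

    def test_isotropic(self, scheme):
        sig = np.exp(-scheme.bvals * 1.0)
        fit = fit_dti(sig, scheme)
        assert np.allclose(fit.eigenvalues, 1.0, atol=1e-9)

    def test_b0_only_rejected(self):
        sch = build_scheme(np.zeros(10), np.zeros((10, 3)))
        with pytest.raises(ValueError):
            fit_dti(np.ones(10), sch)

    def test_too_few_measurements_rejected(self):
        sch = build_scheme([0, 1000, 1000], np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]))
        with pytest.raises(ValueError):
            fit_dti(np.ones(3), sch)

    def test_only_low_b_used(self, scheme):
        """Corrupting the high-b shell must not move the tensor fit."""
        D = np.diag([1.5, 0.5, 0.4])
        sig = _dti_signal(D, scheme)
        sig2 = sig.copy()
        sig2[scheme.shell_mask(2.5)] *= 0.1
        a = fit_dti(sig, scheme)
        b = fit_dti(sig2, scheme)
        assert np.allclose(a.eigenvalues, b.eigenvalues)


class TestDTIMetrics:
    @pytest.mark.parametrize("evals,expect", [
        ((1.3, 1.3, 1.3), dict(FA=0.0, MD=1.3, AD=1.3, RD=1.3)),
        ((2.0, 0.0, 0.0), dict(FA=1.0, MD=2 / 3, AD=2.0, RD=0.0)),
        ((1.7, 0.3, 0.3), dict(FA=0.7990, MD=0.76667, AD=1.7, RD=0.3)),
    ])
    def test_closed_form_values(self, evals, expect):
        fit = TensorFit(D=np.array(list(evals) + [0, 0, 0.0]),
                        eigenvalues=np.array(evals), eigenvectors=np.eye(3),
                        lnS0=np.zeros(()))
        m = dti_metrics(fit)
        for k, v in expect.items():
            assert abs(float(m[k]) - v) < 1e-4, k

    def test_null_tensor_fa_zero(self):
        fit = TensorFit(D=np.zeros(6), eigenvalues=np.zeros(3),
                        eigenvectors=np.eye(3), lnS0=np.zeros(()))
        assert float(dti_metrics(fit)["FA"]) == 0.0

    def test_fa_rotation_invariant(self, scheme, rng):
        base = np.diag([1.9, 0.6, 0.2])
        ref = dti_metrics(fit_dti(_dti_signal(base, scheme), scheme))["FA"]
        for _ in range(5):
            ax = rng.normal(size=3)
            R = rotation_to(ax / np.linalg.norm(ax))
            fa = dti_metrics(fit_dti(_dti_signal(R @ base @ R.T, scheme), scheme))["FA"]
            assert abs(float(fa) - float(ref)) < 1e-9

    def test_md_trace_and_ordering(self, scheme, rng):
        for _ in range(5):
            A = rng.normal(size=(3, 3))
            D = A @ A.T / 3.0
            fit = fit_dti(_dti_signal(D, scheme), scheme)
            m = dti_metrics(fit)
            assert abs(float(m["MD"]) - np.trace(D) / 3) < 1e-8
            assert m["AD"] >= m["MD"] >= m["RD"]


class TestDKI:
    def test_single_direction_closed_form(self):
        """Three b-values along one direction determine (lnS0, D_app,
        K_app) exactly through the log-quadratic model."""
        b = np.array([0.0, 1.25, 2.5])
        d_app, k_app = 1.0, 1.0
        logs = -b * d_app + b**2 / 6 * d_app**2 * k_app
        A = np.column_stack([np.ones(3), -b, b**2 / 6])
        sol = np.linalg.solve(A, logs)
        assert np.allclose(sol, [0.0, d_app, d_app**2 * k_app])
        # signal ratio at b = 2.5 from the same closed form
        assert abs(np.exp(-2.5 + 6.25 / 6) - 0.23263) < 5e-5

    def test_full_tensor_recovery(self, scheme, rng):
        d6 = np.array([1.2, 0.9, 0.7, 0.1, -0.05, 0.08])
        w15 = rng.normal(0, 0.1, 15)
        fit = fit_dki(_dki_signal(d6, w15, scheme), scheme)
        assert np.abs(fit.D - d6).max() < 1e-6
        assert np.abs(fit.W - w15).max() < 1e-6

    def test_gaussian_signal_zero_kurtosis(self, scheme):
        d6 = np.array([1.0, 0.8, 0.6, 0.0, 0.0, 0.0])
        fit = fit_dki(_dki_signal(d6, np.zeros(15), scheme), scheme)
        assert np.abs(fit.W).max() < 1e-8

    def test_single_shell_rejected(self):
        dirs = fibonacci_sphere(30)
        sch = build_scheme([0.0] + [1000.0] * 30, np.vstack([np.zeros(3), dirs]))
        with pytest.raises(ValueError):
            fit_dki(np.ones(31), sch)


class TestDKIMetrics:
    def _iso_fit(self, k_app):
        d6 = np.array([1.0, 1.0, 1.0, 0, 0, 0.0])
        w15 = np.zeros(15)
        # isotropic W: K_app = k everywhere -> W_iiii = k, W_iijj = k/3
        w15[:3] = k_app
        w15[9:12] = k_app / 3.0
        return KurtosisFit(D=d6, W=w15, lnS0=np.zeros(()), eigenvalues=np.ones(3),
                           eigenvectors=np.eye(3))

    def test_isotropic_kurtosis(self):
        m = dki_metrics(self._iso_fit(0.8))
        for k in ("AK", "MK", "RK"):
            assert abs(float(m[k]) - 0.8) < 1e-10

    def test_zero_w(self):
        m = dki_metrics(self._iso_fit(0.0))
        assert all(abs(float(m[k])) < 1e-12 for k in ("AK", "MK", "RK"))

    def test_mk_matches_dense_brute_force(self, scheme):
        t_d6 = np.array([1.4, 0.8, 0.5, 0.05, 0.02, -0.03])
        rng = np.random.default_rng(4)
        w15 = rng.normal(0.3, 0.1, 15)
        fit = fit_dki(_dki_signal(t_d6, w15, scheme), scheme)
        mk = dki_metrics(fit, n_dirs=250)["MK"]
        brute = fit.k_app(fibonacci_sphere(10_000)).mean()
        assert abs(float(mk) - float(brute)) / abs(float(brute)) < 0.02

    def test_mk_monotone_in_w_elements(self):
        """MK is non-decreasing when an even-parity W element grows; for
        odd-parity elements the directional average is ~0 (small
        finite-direction-set asymmetry allowed)."""
        base = self._iso_fit(0.5)
        mk0 = float(dki_metrics(base)["MK"])
        even = (0, 1, 2, 9, 10, 11)  # x^4/y^4/z^4 and the x^2y^2 family
        for idx in range(15):
            bumped = KurtosisFit(D=base.D, W=base.W.copy(), lnS0=base.lnS0,
                                 eigenvalues=base.eigenvalues,
                                 eigenvectors=base.eigenvectors)
            bumped.W[idx] += 0.05
            mk = float(dki_metrics(bumped)["MK"])
            if idx in even:
                assert mk >= mk0 - 1e-12
            else:
                assert abs(mk - mk0) < 1e-4


class TestAWF:
    @pytest.mark.parametrize("k_max,expect", [(3.0, 0.5), (0.0, 0.0), (1.2, 0.2857)])
    def test_fixed_points(self, k_max, expect):
        d6 = np.array([1.0, 1.0, 1.0, 0, 0, 0.0])
        w15 = np.zeros(15)
        w15[:3] = k_max
        w15[9:12] = k_max / 3.0
        fit = KurtosisFit(D=d6, W=w15, lnS0=np.zeros(()), eigenvalues=np.ones(3),
                          eigenvectors=np.eye(3))
        assert abs(float(awf_from_kurtosis(fit)) - expect) < 1e-4

    def test_negative_kurtosis_clamps_to_zero(self):
        d6 = np.array([1.0, 1.0, 1.0, 0, 0, 0.0])
        w15 = np.zeros(15)
        w15[:3] = -0.2
        w15[9:12] = -0.2 / 3
        fit = KurtosisFit(D=d6, W=w15, lnS0=np.zeros(()), eigenvalues=np.ones(3),
                          eigenvectors=np.eye(3))
        assert float(awf_from_kurtosis(fit)) == 0.0


class TestEstimators:
    def test_batch_interface(self, scheme, rng):
        X = np.vstack([_dki_signal(np.array([1.2, 0.9, 0.7, 0.1, -0.05, 0.08]),
                                   rng.normal(0, 0.1, 15), scheme) for _ in range(3)])
        dti = DTIEstimator(scheme).fit(X)
        assert dti.transform().shape == (3, 4)
        dki = DKIEstimator(scheme).fit(X)
        assert dki.transform().shape == (3, 4)
        assert set(dki.get_params()) == {"scheme", "n_dirs"}
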