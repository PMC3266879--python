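"""Mean-field drift equations, fixed points, and stability spectra."""

import numpy as np
import pytest
from scipy import integrate as sciint

from eibstdp.meanfield import (
    GammaKernel,
    MeanFieldModel,
    PopulationModel,
    RateFloorError,
    drift_population,
    drift_single,
    fixed_point_inh_mu1_closed_form,
    fixed_point_single,
    homogeneous_fixed_point,
    integrate_population,
    kernel_overlap,
    stability_spectrum,
)
from eibstdp.plasticity import STDPRule
from eibstdp.spikegen import CorrelationSpec, build_correlation_matrix

GAMMA = GammaKernel(amplitude=18.0, decay_tau=8.0, latency=1.0)


def _inh_model(n=20, alpha=0.8, mu=0.0, within=0.2, between=0.05, drive=100.0,
               lam=1e-3, delay=1.0):
    if n % 2:
        raise ValueError
    spec = CorrelationSpec([n // 2, n // 2], 10.0, within_corr=within,
                           between_corr=between)
    pop = PopulationModel(n, STDPRule(lam, alpha, mu, 20.0, "I"),
                          build_correlation_matrix(spec))
    return MeanFieldModel(rate=10.0, drive=drive, inh=pop, delay_ms=delay)


class TestKernelOverlap:
    def test_zero_amplitude(self):
        assert kernel_overlap(STDPRule(1e-3, 0.9, 0.0, 20.0),
                              GammaKernel(0.0, 5.0)) == 0.0

    def test_exponential_closed_form_vs_quadrature(self):
        rule = STDPRule(1e-3, 0.9, 0.0, 20.0)
        g = GammaKernel(amplitude=12.0, decay_tau=6.0, latency=2.0)
        val, _ = sciint.quad(
            lambda s: np.exp(-s / rule.tau) * float(g(s)), 0.0, 2000.0,
            epsrel=1e-10, limit=500,
        )
        assert kernel_overlap(rule, g) == pytest.approx(val / 1000.0, rel=1e-8)

    def test_zero_latency_product_formula(self):
        rule = STDPRule(1e-3, 0.9, 0.0, 20.0)
        g = GammaKernel(amplitude=10.0, decay_tau=10.0, latency=0.0)
        tau, tg = 0.020, 0.010
        assert kernel_overlap(rule, g) == pytest.approx(
            10.0 * tau * tg / (tau + tg), rel=1e-10
        )

    def test_overlap_vanishes_monotonically_with_latency(self):
        rule = STDPRule(1e-3, 0.9, 0.0, 20.0)
        vals = [
            kernel_overlap(rule, GammaKernel(10.0, 8.0, latency=l))
            for l in (0.0, 5.0, 20.0, 100.0, 400.0)
        ]
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 1e-6

    def test_gamma_shaped_stdp_filter_uses_quadrature(self):
        rule = STDPRule(1e-3, 0.9, 0.0, 20.0, kernel="gamma")
        g = GammaKernel(amplitude=10.0, decay_tau=8.0, latency=1.0)
        val, _ = sciint.quad(
            lambda s: float(rule.temporal_filter(s)) * float(g(s)),
            0.0, 3000.0, epsrel=1e-10, limit=500,
        )
        assert kernel_overlap(rule, g) == pytest.approx(val / 1000.0, rel=1e-6)


class TestDriftSingle:
    def test_weak_synapse_potentiates_below_one_alpha(self):
        rule = STDPRule(1e-3, 0.8, 0.0, 20.0)
        assert drift_single(0.0, rule, 10.0, 10.0, GAMMA) > 0

    def test_depression_dominated_rule_always_decays(self):
        rule = STDPRule(1e-3, 1.1, 0.0, 20.0)
        ws = np.linspace(0, 1, 21)
        assert all(drift_single(w, rule, 10.0, 10.0, GAMMA) <= 0 for w in ws)
        fp = fixed_point_single(rule, 10.0, 10.0, GAMMA)
        assert fp.weights["single"] == 0.0 and fp.boundary

    def test_fixed_point_equals_ode_long_time_limit(self):
        rule = STDPRule(1e-3, 0.8, 0.3, 20.0)
        fp = fixed_point_single(rule, 10.0, 10.0, GAMMA)
        for w0 in (0.05, 0.95):
            sol = sciint.solve_ivp(
                lambda _t, w: [drift_single(float(np.clip(w[0], 0, 1)), rule,
                                            10.0, 10.0, GAMMA)],
                (0, 2e5), [w0], rtol=1e-10, atol=1e-12,
            )
            assert sol.y[0, -1] == pytest.approx(fp.weights["single"], abs=1e-6)

    def test_alpha_monotonically_lowers_fixed_point(self):
        ws = [
            fixed_point_single(STDPRule(1e-3, a, 0.0, 20.0), 10.0, 10.0, GAMMA)
            .weights["single"]
            for a in (0.6, 0.7, 0.8, 0.9)
        ]
        assert np.all(np.diff(ws) < 0)

    def test_no_feedback_saturates_at_upper_bound(self):
        rule = STDPRule(1e-3, 0.8, 0.0, 20.0)
        fp = fixed_point_single(rule, 10.0, 10.0, GammaKernel(0.0, 5.0))
        assert fp.weights["single"] == 1.0 and fp.boundary

    @pytest.mark.parametrize(
        "alpha, mu",
        [(0.85, 0.0), (0.9, 0.0), (0.95, 0.0),
         (0.5, 0.5), (0.7, 0.5), (0.5, 1.0), (0.9, 1.0)],
    )
    def test_unique_interior_root_sign_scan(self, alpha, mu):
        rule = STDPRule(1e-3, alpha, mu, 20.0)
        ws = np.linspace(0, 1, 1001)
        vals = np.array([drift_single(w, rule, 10.0, 10.0, GAMMA) for w in ws])
        crossings = np.sum(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
        assert crossings == 1
        fp = fixed_point_single(rule, 10.0, 10.0, GAMMA)
        assert not fp.boundary and fp.stable


class TestHomogeneousFixedPoint:
    def test_uniform_drift_is_uniform(self):
        m = _inh_model()
        d, _ = drift_population(m, np.full(20, 0.3))
        assert np.allclose(d, d[0])

    def test_drift_vanishes_at_fixed_point(self):
        m = _inh_model()
        fp = homogeneous_fixed_point(m)
        d, _ = drift_population(m, np.full(20, fp.weights["inh"]))
        assert np.max(np.abs(d)) < 1e-10

    def test_unique_admissible_root_over_parameter_grid(self):
        for alpha in (0.2, 0.5, 0.9):
            for mu in (0.25, 0.5, 1.0):
                m = _inh_model(alpha=alpha, mu=mu)
                fp = homogeneous_fixed_point(m)
                assert not fp.boundary
                assert 0 < fp.weights["inh"] < 1
                assert fp.post_rate > 0

    def test_mu1_closed_form_matches_solver(self):
        m = _inh_model(mu=1.0)
        fp = homogeneous_fixed_point(m)
        assert fp.weights["inh"] == pytest.approx(
            fixed_point_inh_mu1_closed_form(m), abs=1e-10
        )

    def test_uncorrelated_large_population_reaches_complete_balance(self):
        """With c=0 and mu=0 the net inhibition converges to the drive."""
        ratios = []
        for n in (50, 200, 1000):
            pop = PopulationModel(n, STDPRule(1e-3, 0.8, 0.0, 20.0, "I"))
            m = MeanFieldModel(rate=10.0, drive=100.0, inh=pop, delay_ms=1.0)
            fp = homogeneous_fixed_point(m)
            ratios.append(n * fp.weights["inh"] * 10.0 / 100.0)
        assert np.all(np.diff(ratios) > 0)
        assert ratios[-1] > 0.95

    def test_inhibitory_weight_decreases_with_correlation(self):
        ws = []
        for c in (0.0, 0.05, 0.2, 0.5):
            spec = CorrelationSpec([20], 10.0, within_corr=c)
            pop = PopulationModel(20, STDPRule(1e-3, 0.8, 0.0, 20.0, "I"),
                                  build_correlation_matrix(spec))
            m = MeanFieldModel(rate=10.0, drive=100.0, inh=pop, delay_ms=1.0)
            ws.append(homogeneous_fixed_point(m).weights["inh"])
        assert np.all(np.diff(ws) < 0)

    def test_rate_floor_flagged(self):
        m = _inh_model(drive=1.0)
        with pytest.raises(RateFloorError):
            drift_population(m, np.full(20, 0.9))


def _fd_jacobian(model, w_inh, w_exc=None, h=1e-7):
    ni = 0 if w_inh is None else len(w_inh)
    parts = [w_inh] if w_inh is not None else []
    if w_exc is not None:
        parts.append(w_exc)
    y0 = np.concatenate(parts)

    def f(y):
        wi = y[:ni] if w_inh is not None else None
        we = y[ni:] if w_exc is not None else None
        di, de = drift_population(model, wi, we)
        return np.concatenate([x for x in (di, de) if x is not None])

    n = y0.size
    J = np.zeros((n, n))
    for j in range(n):
        yp, ym = y0.copy(), y0.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (f(yp) - f(ym)) / (2 * h)
    return J


class TestStabilitySpectrum:
    def test_inhibitory_spectrum_matches_fd_jacobian(self):
        m = _inh_model()
        fp = stability_spectrum(homogeneous_fixed_point(m), m)
        w0 = np.full(20, fp.weights["inh"])
        fd = np.sort(np.linalg.eigvals(_fd_jacobian(m, w0)).real)
        assert np.allclose(np.sort(fp.eigenvalues), fd, atol=1e-6)

    def test_inhibitory_uniform_solution_always_stable(self):
        for within, between, mu in [(0.0, 0.0, 0.0), (0.3, 0.1, 0.0),
                                    (0.5, 0.0, 0.5), (0.2, 0.2, 1.0)]:
            m = _inh_model(within=within, between=between, mu=mu)
            fp = stability_spectrum(homogeneous_fixed_point(m), m)
            assert fp.stable
            assert np.max(fp.eigenvalues) < 0

    def test_joint_spectrum_matches_fd_jacobian(self):
        ce = build_correlation_matrix(CorrelationSpec([15], 10.0, within_corr=0.1))
        exc = PopulationModel(15, STDPRule(1e-3, 1.2, 0.5, 20.0, "E"), ce)
        m = _inh_model()
        m = MeanFieldModel(rate=10.0, drive=5.0, inh=m.inh, exc=exc, delay_ms=1.0)
        fp = stability_spectrum(homogeneous_fixed_point(m), m)
        wI = np.full(20, fp.weights["inh"])
        wE = np.full(15, fp.weights["exc"])
        fd = np.sort(np.linalg.eigvals(_fd_jacobian(m, wI, wE)).real)
        assert np.allclose(np.sort(fp.eigenvalues), fd, atol=1e-6)
        assert np.all(fp.eigenvalues[fp.labels == "het-I"] < 0)

    def test_weak_weight_dependence_destabilizes_excitation(self):
        """Lowering mu_E flips the block-difference excitatory mode unstable.

        Two excitatory subgroups correlated within but not across put the
        block-difference direction at the same correlation eigenvalue as
        the uniform one, but without the stabilizing rate feedback; with
        weak weight dependence that mode crosses zero while the fixed
        point stays interior.
        """
        inh = PopulationModel(20, STDPRule(1e-3, 0.8, 0.0, 20.0, "I"))
        ce = build_correlation_matrix(
            CorrelationSpec([8, 8], 10.0, within_corr=0.5, between_corr=0.0)
        )

        def leading_het_e(mu_e):
            exc = PopulationModel(16, STDPRule(1e-3, 3.0, mu_e, 20.0, "E"), ce)
            m = MeanFieldModel(rate=10.0, drive=20.0, inh=inh, exc=exc,
                               delay_ms=1.0)
            fp = homogeneous_fixed_point(m)
            if fp.boundary:
                return None
            fp = stability_spectrum(fp, m)
            return np.max(fp.eigenvalues[fp.labels == "het-E"])

        lams = [leading_het_e(mu) for mu in (0.6, 0.4, 0.3)]
        assert all(l is not None for l in lams)
        assert np.all(np.diff(lams) > 0)   # destabilizes as mu_E shrinks
        assert lams[0] < 0 < lams[-1]

    def test_identity_correlations_spectrum_against_dense_eig(self):
        pop = PopulationModel(12, STDPRule(1e-3, 0.8, 0.3, 20.0, "I"))
        m = MeanFieldModel(rate=10.0, drive=60.0, inh=pop, delay_ms=1.0)
        fp = stability_spectrum(homogeneous_fixed_point(m), m)
        w0 = np.full(12, fp.weights["inh"])
        fd = np.sort(np.linalg.eigvals(_fd_jacobian(m, w0)).real)
        assert np.allclose(np.sort(fp.eigenvalues), fd, atol=1e-6)

    def test_nonpsd_correlation_rejected(self):
        c = np.eye(5)
        c[0, 1] = c[1, 0] = 1.5
        with pytest.raises(ValueError, match="positive semidefinite"):
            PopulationModel(5, STDPRule(1e-3, 0.8, 0.0, 20.0, "I"), c)


def test_ode_converges_to_stable_homogeneous_point():
    """Random positive initial conditions relax to the homogeneous solution
    whenever the spectrum is entirely negative."""
    rng = np.random.default_rng(3)
    m = _inh_model()
    fp = stability_spectrum(homogeneous_fixed_point(m), m)
    assert fp.stable
    w0 = rng.uniform(0.05, 0.95, 20)
    sol = integrate_population(m, w0, None, t_end=5e4)
    assert np.allclose(sol.y[:, -1], fp.weights["inh"], atol=1e-6)
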