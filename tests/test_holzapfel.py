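import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esomech import holzapfel as hz
from esomech.curves import AXIAL, CIRCUMFERENTIAL, BiaxialTest, StretchStressCurve

from conftest import CLEAN_PARAMS

PUBLISHED = {
    AXIAL: hz.HolzapfelParams(9.0966, 9.3158, 1.8472, 1.0002),
    CIRCUMFERENTIAL: hz.HolzapfelParams(5.0863, 1.1122, 1.7420, 1.5884),
}

params_strategy = st.builds(
    hz.HolzapfelParams,
    c=st.floats(0.5, 20.0),
    k1=st.floats(0.0, 10.0),
    k2=st.floats(0.1, 3.0),
    theta=st.floats(0.0, math.pi),
)


def finite_difference_stresses(params, lt, lz, h=1e-6):
    """Independent oracle: sigma_aa = lambda_a dW/dlambda_a with the radial
    stretch eliminated by incompressibility (plane stress)."""

    def W(a, b):
        return hz.strain_energy(params, hz.StretchState(a, b))

    s_tt = lt * (W(lt + h, lz) - W(lt - h, lz)) / (2 * h)
    s_zz = lz * (W(lt, lz + h) - W(lt, lz - h)) / (2 * h)
    return s_tt, s_zz


class TestInvariants:
    def test_reference_state(self):
        i1, i4 = hz.invariants(hz.StretchState(1.0, 1.0), 0.7)
        assert i1 == pytest.approx(3.0)
        assert i4 == pytest.approx(1.0)

    def test_hand_evaluated_state(self):
        # lambda_t=1.2, lambda_z=1.1, theta=0: lambda_r^2 = (1/1.32)^2
        i1, i4 = hz.invariants(hz.StretchState(1.2, 1.1), 0.0)
        assert i4 == pytest.approx(1.44, abs=1e-12)
        assert i1 == pytest.approx(1.44 + 1.21 + (1 / 1.32) ** 2, abs=1e-12)

    def test_theta_90_gives_axial_stretch_squared(self):
        _, i4 = hz.invariants(hz.StretchState(1.3, 1.17), math.pi / 2)
        assert i4 == pytest.approx(1.17**2, abs=1e-12)


class TestStrainEnergy:
    @given(params=params_strategy)
    @settings(max_examples=50, deadline=None)
    def test_reference_state_stores_no_energy(self, params):
        assert hz.strain_energy(params, hz.StretchState(1.0, 1.0)) == pytest.approx(0.0, abs=1e-12)

    def test_k1_zero_reduces_to_neo_hookean(self):
        p = hz.HolzapfelParams(c=4.0, k1=0.0, k2=1.0, theta=0.3)
        s = hz.StretchState(1.3, 1.2)
        i1, _ = hz.invariants(s, p.theta)
        assert hz.strain_energy(p, s) == pytest.approx(p.c / 2 * (i1 - 3), rel=1e-12)

    def test_published_axial_params_match_high_precision_oracle(self):
        # independent symbolic evaluation at lambda = 1.3 equibiaxial
        import sympy

        p = PUBLISHED[AXIAL]
        lam = sympy.Rational(13, 10)
        c, k1, k2, th = [sympy.Float(v, 30) for v in (p.c, p.k1, p.k2, p.theta)]
        i1 = 2 * lam**2 + lam**-4
        i4 = lam**2 * sympy.cos(th) ** 2 + lam**2 * sympy.sin(th) ** 2
        w_expected = c / 2 * (i1 - 3) + k1 / k2 * (sympy.exp(k2 * (i4 - 1) ** 2) - 1)
        w = hz.strain_energy(p, hz.StretchState(1.3, 1.3))
        assert w == pytest.approx(float(w_expected.evalf(30)), rel=1e-10)

    def test_overflow_guard_names_the_state(self):
        p = hz.HolzapfelParams(c=1.0, k1=1.0, k2=500.0, theta=0.0)
        with pytest.raises(OverflowError):
            hz.strain_energy(p, hz.StretchState(2.5, 2.5))

    def test_split_prefactor_halves_fiber_term(self):
        p = hz.HolzapfelParams(c=1e-9, k1=2.0, k2=1.0, theta=0.0)
        s = hz.StretchState(1.2, 1.2)
        w_full = hz.strain_energy(p, s)
        w_half = hz.strain_energy(p, s, split_prefactor=True)
        assert w_half == pytest.approx(w_full / 2, rel=1e-9)


class TestCauchyStresses:
    def test_reference_state_is_stress_free(self):
        sp = hz.cauchy_stresses(PUBLISHED[AXIAL], hz.StretchState(1.0, 1.0))
        assert sp.sigma_thetatheta == pytest.approx(0.0, abs=1e-12)
        assert sp.sigma_zz == pytest.approx(0.0, abs=1e-12)

    def test_matches_energy_derivative_at_equibiaxial_state(self):
        sp = hz.cauchy_stresses(CLEAN_PARAMS, hz.StretchState(1.3, 1.3))
        fd_tt, fd_zz = finite_difference_stresses(CLEAN_PARAMS, 1.3, 1.3)
        assert sp.sigma_thetatheta == pytest.approx(fd_tt, rel=1e-6)
        assert sp.sigma_zz == pytest.approx(fd_zz, rel=1e-6)

    def test_energy_consistency_on_random_draws(self):
        # 200 random (params, state) draws at 1e-5 relative tolerance
        rng = np.random.default_rng(2024)
        for _ in range(200):
            p = hz.HolzapfelParams(
                c=rng.uniform(0.5, 20),
                k1=rng.uniform(0.0, 10),
                k2=rng.uniform(0.1, 3),
                theta=rng.uniform(0, math.pi),
            )
            lt, lz = rng.uniform(1.02, 1.5, 2)
            sp = hz.cauchy_stresses(p, hz.StretchState(lt, lz))
            fd_tt, fd_zz = finite_difference_stresses(p, lt, lz)
            assert sp.sigma_thetatheta == pytest.approx(fd_tt, rel=1e-5, abs=1e-7)
            assert sp.sigma_zz == pytest.approx(fd_zz, rel=1e-5, abs=1e-7)

    def test_theta_zero_puts_fiber_entirely_in_hoop_direction(self):
        p = hz.HolzapfelParams(c=1.0, k1=5.0, k2=1.0, theta=0.0)
        iso = hz.HolzapfelParams(c=1.0, k1=0.0, k2=1.0, theta=0.0)
        s = hz.StretchState(1.3, 1.25)
        with_fiber = hz.cauchy_stresses(p, s)
        without = hz.cauchy_stresses(iso, s)
        assert with_fiber.sigma_zz == pytest.approx(without.sigma_zz, rel=1e-12)
        assert with_fiber.sigma_thetatheta > without.sigma_thetatheta

    def test_printed_variant_breaks_derivative_consistency(self):
        p = hz.HolzapfelParams(c=2.0, k1=4.0, k2=1.0, theta=1.0)
        s = hz.StretchState(1.4, 1.2)  # distinct stretches expose the factor
        sp = hz.cauchy_stresses(p, s, zz_fiber_factor="theta")
        _, fd_zz = finite_difference_stresses(p, 1.4, 1.2)
        assert sp.sigma_zz != pytest.approx(fd_zz, rel=1e-3)

    @given(params=params_strategy)
    @settings(max_examples=30, deadline=None)
    def test_isotropy_limit_equalizes_equibiaxial_stresses(self, params):
        p = hz.HolzapfelParams(c=params.c, k1=0.0, k2=params.k2, theta=params.theta)
        sig_tt, sig_zz = hz.equibiaxial_stresses(p, np.array([1.25]))
        assert sig_tt[0] == pytest.approx(sig_zz[0], rel=1e-12)

    @given(params=params_strategy)
    @settings(max_examples=30, deadline=None)
    def test_monotone_stiffening_along_fiber(self, params):
        p = hz.HolzapfelParams(c=params.c, k1=params.k1, k2=params.k2, theta=0.0)
        lam = np.linspace(1.0, 1.5, 40)
        sig_tt, _ = hz.equibiaxial_stresses(p, lam)
        assert np.all(np.diff(sig_tt) > 0)


class TestObjectiveAndMetrics:
    def test_perfect_fit_scores_zero(self, clean_holzapfel_test):
        assert hz.objective(CLEAN_PARAMS, clean_holzapfel_test) == pytest.approx(0.0, abs=1e-18)

    def test_constant_offset_closed_form(self, clean_holzapfel_test):
        t = clean_holzapfel_test
        d = 0.7
        shifted = BiaxialTest(
            test_id="s",
            axial=StretchStressCurve(t.stretch, t.axial.stress + d, AXIAL),
            circumferential=StretchStressCurve(
                t.stretch, t.circumferential.stress + d, CIRCUMFERENTIAL
            ),
        )
        n = t.stretch.size
        assert hz.objective(CLEAN_PARAMS, shifted) == pytest.approx(2 * n * d**2, rel=1e-12)

    def test_objective_equals_naive_loop(self, clean_holzapfel_test):
        p = hz.HolzapfelParams(c=3.0, k1=1.0, k2=2.0, theta=0.5)
        total = 0.0
        for i, lam in enumerate(clean_holzapfel_test.stretch):
            sp = hz.cauchy_stresses(p, hz.StretchState(lam, lam))
            total += (clean_holzapfel_test.circumferential.stress[i] - sp.sigma_thetatheta) ** 2
            total += (clean_holzapfel_test.axial.stress[i] - sp.sigma_zz) ** 2
        assert hz.objective(p, clean_holzapfel_test) == pytest.approx(total, rel=1e-12)

    def test_error_metric_hand_case(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        obs = pred + 1.0
        # residual 1 each, sqrt(5/5) = 1, sigma_ref = 3
        assert hz.fit_error_metric(pred, obs, q=0) == pytest.approx(1 / 3, rel=1e-12)
        assert hz.fit_error_metric(pred, pred, q=0) == 0.0

    def test_error_metric_grows_with_q(self):
        pred = np.linspace(1, 5, 9)
        obs = pred + 0.5
        assert hz.fit_error_metric(pred, obs, q=4) > hz.fit_error_metric(pred, obs, q=2)
        with pytest.raises(ValueError):
            hz.fit_error_metric(pred, obs, q=9)

    def test_correlation_affine_invariance_and_square(self):
        rng = np.random.default_rng(0)
        pred = np.sort(rng.uniform(0, 10, 50))
        assert hz.correlation_r2(pred, 2 * pred + 3) == pytest.approx(1.0)
        obs = rng.uniform(0, 10, 50)
        assert hz.correlation_r2(pred, obs) == pytest.approx(
            hz.correlation_coefficient(pred, obs) ** 2, rel=1e-12
        )

    def test_uncorrelated_noise_scores_near_zero(self):
        rng = np.random.default_rng(77)
        pred, obs = rng.normal(size=(2, 1000))
        assert hz.correlation_r2(pred, obs) < 0.05

    def test_constant_sequence_rejected(self):
        with pytest.raises(ValueError):
            hz.correlation_r2(np.ones(5), np.arange(5.0))


class TestThetaDegrees:
    def test_published_angles(self):
        assert round(hz.theta_degrees(PUBLISHED[AXIAL]), 1) == 57.3
        assert round(hz.theta_degrees(PUBLISHED[CIRCUMFERENTIAL]), 0) == 91
        assert hz.theta_degrees(math.pi / 2) == pytest.approx(90.0)


class TestFitting:
    def test_joint_recovery_from_perturbed_init(self, clean_holzapfel_test):
        rng = np.random.default_rng(42)
        init = hz.HolzapfelParams(
            *(CLEAN_PARAMS.as_array() * (1 + rng.uniform(-0.2, 0.2, 4)))
        )
        res = hz.fit_holzapfel(clean_holzapfel_test, init=init, mode="joint")
        assert res.converged
        rel = np.abs(res.params[AXIAL].as_array() / CLEAN_PARAMS.as_array() - 1)
        assert rel.max() < 0.01

    def test_noisy_replicates_recover_ground_matrix_stiffness(self, clean_holzapfel_test):
        # 2% multiplicative noise, 10 replicates: median c within 10% of truth
        t = clean_holzapfel_test
        rng_init = np.random.default_rng(42)
        init = hz.HolzapfelParams(
            *(CLEAN_PARAMS.as_array() * (1 + rng_init.uniform(-0.2, 0.2, 4)))
        )
        cs = []
        for i in range(10):
            rng = np.random.default_rng(100 + i)
            noisy = BiaxialTest(
                test_id="n",
                axial=StretchStressCurve(
                    t.stretch,
                    np.clip(t.axial.stress * (1 + rng.normal(0, 0.02, t.stretch.size)), 0, None),
                    AXIAL,
                ),
                circumferential=StretchStressCurve(
                    t.stretch,
                    np.clip(
                        t.circumferential.stress * (1 + rng.normal(0, 0.02, t.stretch.size)),
                        0,
                        None,
                    ),
                    CIRCUMFERENTIAL,
                ),
            )
            cs.append(hz.fit_holzapfel(noisy, init=init, mode="joint").params[AXIAL].c)
        assert abs(np.median(cs) / CLEAN_PARAMS.c - 1) < 0.10

    def test_per_direction_roundtrip_of_published_params(self):
        lam = np.linspace(1.0, 1.5, 60)
        pred = hz.predicted_test_stresses(PUBLISHED[AXIAL], PUBLISHED[CIRCUMFERENTIAL], lam)
        test = BiaxialTest(
            test_id="pub",
            axial=StretchStressCurve(lam, pred[AXIAL], AXIAL),
            circumferential=StretchStressCurve(lam, pred[CIRCUMFERENTIAL], CIRCUMFERENTIAL),
        )
        for d in (AXIAL, CIRCUMFERENTIAL):
            res = hz.fit_holzapfel(test, init=PUBLISHED[d], mode="per-direction")
            rel = np.abs(res.params[d].as_array() / PUBLISHED[d].as_array() - 1)
            assert rel.max() < 1e-3
            assert res.objective_value < 1e-12

    def test_fit_idempotence(self, clean_holzapfel_test):
        res = hz.fit_holzapfel(clean_holzapfel_test, mode="joint")
        res2 = hz.fit_holzapfel(clean_holzapfel_test, init=res.params[AXIAL], mode="joint")
        assert res2.objective_value <= res.objective_value + 1e-12

    def test_all_zero_stresses_rejected(self):
        lam = np.linspace(1, 1.5, 20)
        zero = BiaxialTest(
            test_id="z",
            axial=StretchStressCurve(lam, np.zeros(20), AXIAL),
            circumferential=StretchStressCurve(lam, np.zeros(20), CIRCUMFERENTIAL),
        )
        with pytest.raises(ValueError):
            hz.fit_holzapfel(zero)

    def test_too_few_samples_rejected(self, toy_test):
        with pytest.raises(ValueError):
            hz.fit_holzapfel(toy_test)
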