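"""Photocycle forward models against independent ODE and quadrature oracles."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from bleachmap.photokinetics import (
    PhotocycleParams,
    RateCoeffParams,
    SingletBleachParams,
    TripletParams,
    cross_section_from_extinction,
    extinction_from_cross_section,
    irradiance_to_photon_flux,
    multiexp_decay,
    multiexp_tiem,
    observed_bleach_rate,
    photon_energy,
    photon_flux_to_irradiance,
    ratecoeff_decay,
    ratecoeff_integral,
    saturation_occupancy,
    singlet_bleach_decay,
    singlet_bleach_integral,
    strexp,
    strexp_rate_coefficient,
    tiem_ratecoeff,
    tiem_singlet,
    tiem_triplet,
    triplet_eigenvalues,
    triplet_ode_solve,
    triplet_rea_decay,
)

# Fluorescein-like parameter set used for the triplet-model validation runs.
FL_KW = dict(k1=3.8e8, k_rel=2.134e8)


def _triplet(M=1000.0, k2=0.01, k3=6.6e4, k4=0.1, k5=5e4, **base_kw):
    base = PhotocycleParams(M=M, **(base_kw or FL_KW))
    return TripletParams(SingletBleachParams(base, k2=k2), k3=k3, k4=k4, k5=k5)


class TestUnitConversions:
    def test_photon_energy_printed_values(self):
        assert photon_energy(320) == pytest.approx(6.211e-19, rel=5e-4)
        # E ~ 1/lambda: doubling the wavelength halves the energy
        assert photon_energy(640) == pytest.approx(photon_energy(320) / 2, rel=1e-12)
        assert photon_energy(500) == pytest.approx(3.976e-19, rel=5e-4)
        assert 1.0 / photon_energy(500) == pytest.approx(2.515e18, rel=5e-4)

    def test_photon_flux_printed_values(self):
        assert irradiance_to_photon_flux(1.0, 320) == pytest.approx(1.61e18, rel=5e-3)
        assert irradiance_to_photon_flux(1.0, 500) == pytest.approx(2.515e18, rel=5e-4)
        assert irradiance_to_photon_flux(0.0, 500) == 0.0
        assert photon_flux_to_irradiance(
            irradiance_to_photon_flux(2.5, 410), 410
        ) == pytest.approx(2.5, rel=1e-12)

    def test_cross_section_extinction_roundtrip(self):
        # BChol cross-section corresponds to ~3.47e4 /M/cm
        assert extinction_from_cross_section(1.32842e-16) == pytest.approx(
            3.47e4, rel=2e-3
        )
        assert cross_section_from_extinction(0.0) == 0.0
        eps = 5e4
        assert cross_section_from_extinction(2 * eps) == pytest.approx(
            2 * cross_section_from_extinction(eps), rel=1e-14
        )
        assert extinction_from_cross_section(
            cross_section_from_extinction(eps)
        ) == pytest.approx(eps, rel=1e-12)

    @pytest.mark.parametrize("fn,args", [
        (photon_energy, (-5,)),
        (irradiance_to_photon_flux, (-1, 500)),
        (cross_section_from_extinction, (-1,)),
    ])
    def test_domain_errors(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)


class TestPhotocycleParams:
    def test_q_from_rate_constants(self):
        p = PhotocycleParams(M=1, k1=3.8e8, k_rel=2.134e8)
        assert p.q == pytest.approx(3.8e8 / 2.134e8)

    def test_q_from_photophysics(self):
        # q = sigma * I * tau_f
        p = PhotocycleParams(M=1, sigma_ex=1.32842e-16, i_ex=1e22, tau_f=5.5e-9)
        assert p.q == pytest.approx(1.32842e-16 * 1e22 * 5.5e-9)

    def test_missing_specification_raises(self):
        with pytest.raises(ValueError):
            PhotocycleParams(M=1)

    def test_rea_warning_when_rates_comparable(self):
        base = PhotocycleParams(M=1, k1=10.0, k_rel=5.0)
        with pytest.warns(UserWarning, match="rapid-equilibrium"):
            SingletBleachParams(base, k2=1.0)


class TestSaturation:
    def test_steady_state_values(self):
        assert saturation_occupancy(PhotocycleParams(M=2500, q=1.0)) == 1250.0
        assert saturation_occupancy(PhotocycleParams(M=2500, q=0.0)) == 0.0
        assert saturation_occupancy(PhotocycleParams(M=2500, q=np.inf)) == 2500.0

    def test_against_ode_steady_state(self):
        # long-time integration of the two-state photocycle without bleaching
        k1, krel, M = 2.0, 2.0, 2500.0
        sol = solve_ivp(
            lambda t, y: [-k1 * y[0] + krel * y[1], k1 * y[0] - krel * y[1]],
            (0, 50.0), [M, 0.0], rtol=1e-10, atol=1e-10,
        )
        p = PhotocycleParams(M=M, k1=k1, k_rel=krel)
        assert sol.y[1, -1] == pytest.approx(saturation_occupancy(p), rel=1e-8)

    def test_monotone_in_q(self):
        qs = np.linspace(0.01, 20, 50)
        occ = [saturation_occupancy(PhotocycleParams(M=1, q=q)) for q in qs]
        assert np.all(np.diff(occ) > 0)
        assert occ[-1] < 1.0


class TestSingletBleach:
    def test_initial_amplitude_is_saturation(self):
        p = SingletBleachParams(PhotocycleParams(M=2500, q=1.0), k2=0.1)
        assert singlet_bleach_decay(p, 0.0) == pytest.approx(1250.0)

    def test_k2_zero_is_constant(self):
        p = SingletBleachParams(PhotocycleParams(M=2500, q=1.0), k2=0.0)
        t = np.linspace(0, 100, 11)
        assert np.allclose(singlet_bleach_decay(p, t), 1250.0)

    def test_against_stiff_ode_oracle(self):
        # full two-state system with bleaching, k1, k_rel >= 1e6 * k2
        k1, krel, k2, M = 2e6, 1e6, 0.1, 1000.0
        p = SingletBleachParams(PhotocycleParams(M=M, k1=k1, k_rel=krel), k2=k2)
        # compare after the ns-scale photocycle equilibration transient
        t = np.linspace(0.1, 50, 50)
        sol = solve_ivp(
            lambda _t, y: [-k1 * y[0] + krel * y[1], k1 * y[0] - (krel + k2) * y[1]],
            (0, t[-1]), [M, 0.0], method="Radau", t_eval=t, rtol=1e-10, atol=1e-8,
            jac=lambda _t, y: [[-k1, krel], [k1, -(krel + k2)]],
        )
        amp = saturation_occupancy(p.base)
        err = np.max(np.abs(singlet_bleach_decay(p, t) - sol.y[1]) / amp)
        assert err < 1e-3

    def test_integral_matches_quadrature(self):
        p = SingletBleachParams(PhotocycleParams(M=1000, q=2.0), k2=0.05)
        for t_end in (0.5, 10.0, 200.0):
            ref = quad(lambda t: float(singlet_bleach_decay(p, t)), 0, t_end)[0]
            assert singlet_bleach_integral(p, t_end) == pytest.approx(ref, rel=1e-9)
        assert singlet_bleach_integral(p, 0.0) == 0.0

    def test_integral_plateaus_at_tiem(self):
        p = SingletBleachParams(PhotocycleParams(M=1000, q=2.0), k2=0.05)
        assert singlet_bleach_integral(p, 1e6) == pytest.approx(
            tiem_singlet(1000, 0.05), rel=1e-12
        )

    def test_observed_rate_saturates_in_q(self):
        rates = [
            observed_bleach_rate(
                SingletBleachParams(PhotocycleParams(M=1, q=q), k2=0.1)
            )
            for q in np.linspace(0.1, 50, 40)
        ]
        assert np.all(np.diff(rates) > 0)
        assert rates[-1] < 0.1


class TestTiemSinglet:
    def test_value_and_trivials(self):
        assert tiem_singlet(100, 0.1) == pytest.approx(1000.0)
        assert tiem_singlet(0, 0.3) == 0.0
        with pytest.raises(ValueError):
            tiem_singlet(100, 0.0)

    def test_q_independence_via_quadrature(self):
        vals = []
        for q in (0.5, 1.0, 2.0):
            p = SingletBleachParams(PhotocycleParams(M=100, q=q), k2=0.1)
            vals.append(quad(lambda t: float(singlet_bleach_decay(p, t)), 0, np.inf)[0])
        assert np.ptp(vals) / np.mean(vals) < 1e-6
        assert vals[0] == pytest.approx(tiem_singlet(100, 0.1), rel=1e-6)


class TestTripletOde:
    def test_conservation_without_bleaching(self):
        p = _triplet(M=100.0, k2=0.0, k4=0.0)
        t = np.geomspace(1e-10, 100.0, 120)
        tr = triplet_ode_solve(p, t)
        assert np.allclose(tr.total, 100.0, rtol=1e-6)

    def test_total_non_increasing_with_bleaching(self):
        p = _triplet(M=100.0)
        t = np.geomspace(1e-10, 200.0, 150)
        tr = triplet_ode_solve(p, t)
        assert np.all(np.diff(tr.total) <= 1e-9 * 100.0)

    def test_s1_rises_from_zero_on_ns_scale(self):
        p = _triplet(M=100.0)
        t = np.geomspace(1e-12, 1e-6, 80)
        tr = triplet_ode_solve(p, t)
        assert tr.S1[0] < 1e-3 * 100.0
        assert tr.S1[-1] > 0.1 * 100.0

    def test_eig_and_bdf_routes_agree(self):
        # moderately stiff parameter set keeps the adaptive route fast
        p = _triplet(M=100.0, k3=660.0, k5=500.0, k1=3.8e5, k_rel=2.134e5)
        t = np.linspace(1.0, 100.0, 25)
        a = triplet_ode_solve(p, t, method="eig")
        b = triplet_ode_solve(p, t, method="bdf")
        assert np.allclose(a.S1, b.S1, rtol=1e-5, atol=1e-10)

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError):
            triplet_ode_solve(_triplet(), np.linspace(0.1, 1, 5), method="rk4")


class TestTripletEigenvalues:
    def test_against_numeric_eigensolver(self):
        p = _triplet()
        qf = p.bleach.base.q_frac
        J = np.array(
            [
                [-(p.bleach.k2 + p.k3) * qf, p.k5],
                [p.k3 * qf, -(p.k4 + p.k5)],
            ]
        )
        ref = np.sort(np.linalg.eigvals(J).real)
        lam = triplet_eigenvalues(p)
        assert lam[0] == pytest.approx(ref[0], rel=1e-10)
        assert lam[1] == pytest.approx(ref[1], rel=1e-10)
        assert lam[0] <= lam[1] < 0

    def test_no_triplet_limit_recovers_singlet_rate(self):
        p = _triplet(k3=0.0, k4=0.0)
        lam = triplet_eigenvalues(p)
        kb = observed_bleach_rate(p.bleach)
        assert lam[0] == pytest.approx(-p.k5, rel=1e-12)
        assert lam[1] == pytest.approx(-kb, rel=1e-10)


class TestTripletRea:
    def test_reduces_to_singlet_without_isc(self):
        p = _triplet(M=500.0, k3=0.0)
        t = np.linspace(0, 100, 11)
        assert np.allclose(
            triplet_rea_decay(p, t), singlet_bleach_decay(p.bleach, t), rtol=1e-12
        )

    def test_initial_amplitude_matches_equilibrium_occupancy(self):
        # algebraic REA oracle: S1(0) solves the equilibrium conditions
        # S1 = q*S0, T = (k3/k5)*S1, S0+S1+T = M
        p = _triplet(M=1000.0)
        q, y = p.bleach.base.q, p.triplet_yield
        s1_expected = 1000.0 * q / (1.0 + q + q * y)
        assert triplet_rea_decay(p, 0.0) == pytest.approx(s1_expected, rel=1e-12)

    @pytest.mark.parametrize("k3", [6.6e3, 6.6e4, 6.6e5])
    def test_matches_full_ode_on_slow_timescale(self, k3):
        p = _triplet(M=1000.0, k3=k3)
        t = np.geomspace(1.0, 500.0, 60)
        ode = triplet_ode_solve(p, t)
        rea = triplet_rea_decay(p, t)
        assert np.max(np.abs(ode.S1 - rea) / rea) < 0.01

    def test_rea_fails_when_bleaching_beats_equilibration(self):
        # same triplet yield but 10^4-fold slower triplet kinetics: bleaching
        # overlaps electronic equilibration and the single exponential misses
        # more than the first second of the decay
        p = _triplet(M=1000.0, k3=6.6, k5=0.5)
        t = np.geomspace(1e-3, 50.0, 300)
        ode = triplet_ode_solve(p, t)
        rea = triplet_rea_decay(p, t)
        rel = np.abs(ode.S1 - rea) / np.maximum(rea, 1e-12)
        bad = t[rel > 0.01]
        assert bad.size and bad.max() > 1.0


class TestTiemTriplet:
    def test_reduces_to_singlet_tiem(self):
        assert tiem_triplet(_triplet(M=100.0, k2=0.1, k3=0.0)) == pytest.approx(1000.0)
        assert tiem_triplet(_triplet(M=100.0, k2=0.1, k4=0.0)) == pytest.approx(1000.0)

    def test_matches_quadrature(self):
        p = _triplet(M=1000.0)
        ref = quad(lambda t: float(triplet_rea_decay(p, t)), 0, np.inf)[0]
        assert tiem_triplet(p) == pytest.approx(ref, rel=1e-6)

    def test_decreasing_in_triplet_yield(self):
        vals = [
            tiem_triplet(_triplet(M=100.0, k3=k3)) for k3 in np.linspace(1e3, 1e6, 20)
        ]
        assert np.all(np.diff(vals) < 0)

    def test_zero_bleach_raises(self):
        with pytest.raises(ValueError):
            tiem_triplet(_triplet(k2=0.0, k4=0.0))


class TestMultiexp:
    def test_single_component_reduces_to_singlet(self):
        p = SingletBleachParams(PhotocycleParams(M=100, q=1.0), k2=0.1)
        amp = saturation_occupancy(p.base)
        tau = 1.0 / observed_bleach_rate(p)
        t = np.linspace(0, 50, 20)
        assert np.allclose(multiexp_decay([(amp, tau)], t), singlet_bleach_decay(p, t))
        assert multiexp_tiem([(amp, tau)]) == pytest.approx(tiem_singlet(100, 0.1))

    def test_two_components_quadrature_and_symmetry(self):
        comps = [(30.0, 2.0), (20.0, 20.0)]
        ref = quad(lambda t: float(multiexp_decay(comps, t)), 0, np.inf)[0]
        assert multiexp_tiem(comps) == pytest.approx(30 * 2 + 20 * 20, rel=1e-12)
        assert multiexp_tiem(comps) == pytest.approx(ref, rel=1e-8)
        assert multiexp_tiem(comps[::-1]) == multiexp_tiem(comps)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            multiexp_tiem([])
        with pytest.raises(ValueError):
            multiexp_decay([], [0.0])


class TestStrexp:
    def test_h1_is_monoexponential(self):
        t = np.linspace(0, 30, 40)
        assert np.allclose(strexp(t, 5.0, 4.0, 1.0), 5.0 * np.exp(-t / 4.0))

    def test_value_at_tau(self):
        for h in (0.5, 1.0, 2.0):
            assert strexp(4.0, 7.0, 4.0, h) == pytest.approx(7.0 / np.e)

    def test_rate_coefficient_satisfies_decay_ode(self):
        # finite-difference oracle for dn/dt = -k(t) * n(t)
        tau, h = 3.0, 1.4
        t = np.geomspace(0.05, 30, 400)
        n = strexp(t, 1.0, tau, h)
        k = strexp_rate_coefficient(t, tau, h)
        dndt = np.gradient(n, t)
        mid = slice(5, -5)
        rel = np.abs(dndt[mid] + k[mid] * n[mid]) / np.abs(k[mid] * n[mid])
        assert np.median(rel) < 1e-4

    def test_rate_coefficient_diverges_at_zero_for_h_below_one(self):
        assert np.isinf(strexp_rate_coefficient(0.0, 2.0, 0.5))


class TestRateCoeff:
    def test_b0_recovers_singlet_decay(self):
        base = PhotocycleParams(M=100, q=1.5)
        rc = RateCoeffParams(base, k2p=0.1, b=0.0)
        sg = SingletBleachParams(base, k2=0.1)
        t = np.linspace(0, 80, 60)
        assert np.allclose(ratecoeff_decay(rc, t), singlet_bleach_decay(sg, t), rtol=1e-14)

    def test_effective_rate_at_one_second(self):
        # k2(t) = k2p * t^-b equals k2p at t = 1 s for any b
        for b in (0.0, 0.2868, 0.7):
            assert 0.2742 * 1.0 ** (-b) == pytest.approx(0.2742)

    def test_matches_ode_oracle_droplet_parameters(self):
        # lipid-droplet-like parameters: k2p = 0.2742 s^(b-1), b = 0.2868
        base = PhotocycleParams(M=100, q=2.0)
        rc = RateCoeffParams(base, k2p=0.2742, b=0.2868)
        qf = base.q_frac
        t = np.linspace(0.01, 60, 200)
        sol = solve_ivp(
            lambda _t, y: [-qf * 0.2742 * _t ** (-0.2868) * y[0]],
            (t[0], t[-1]),
            [float(ratecoeff_decay(rc, t[0]))],
            t_eval=t, rtol=1e-10, atol=1e-12,
        )
        rel = np.abs(ratecoeff_decay(rc, t) - sol.y[0]) / sol.y[0]
        assert np.max(rel) < 1e-4

    def test_b_out_of_range_raises(self):
        base = PhotocycleParams(M=100, q=1.0)
        with pytest.raises(ValueError):
            RateCoeffParams(base, k2p=0.1, b=1.0)
        with pytest.raises(ValueError):
            RateCoeffParams(base, k2p=0.1, b=-0.1)


class TestTiemRateCoeff:
    def test_b0_equals_singlet_tiem_for_any_q(self):
        for q in (0.5, 1.0, 2.0, 8.0):
            rc = RateCoeffParams(PhotocycleParams(M=100, q=q), k2p=0.1, b=0.0)
            assert tiem_ratecoeff(rc) == pytest.approx(1000.0, rel=1e-12)

    @pytest.mark.parametrize("b", [0.1, 0.3])
    @pytest.mark.parametrize("q", [0.5, 1.0, 2.0])
    def test_matches_quadrature(self, b, q):
        rc = RateCoeffParams(PhotocycleParams(M=100, q=q), k2p=0.1, b=b)
        ref = quad(lambda t: float(ratecoeff_decay(rc, t)), 0, np.inf)[0]
        assert tiem_ratecoeff(rc) == pytest.approx(ref, rel=1e-5)

    def test_excess_over_singlet_shrinks_with_q(self):
        b = 0.3
        excesses = []
        for q in (0.5, 1.0, 2.0, 8.0):
            rc = RateCoeffParams(PhotocycleParams(M=100, q=q), k2p=0.1, b=b)
            excesses.append(tiem_ratecoeff(rc) - 1000.0)
        assert all(e > 0 for e in excesses)
        assert np.all(np.diff(excesses) < 0)

    def test_finite_integral_matches_quadrature_and_limit(self):
        rc = RateCoeffParams(PhotocycleParams(M=100, q=1.0), k2p=0.1, b=0.25)
        for t_end in (5.0, 50.0):
            ref = quad(lambda t: float(ratecoeff_decay(rc, t)), 0, t_end)[0]
            assert ratecoeff_integral(rc, t_end) == pytest.approx(ref, rel=1e-8)
        assert ratecoeff_integral(rc, 1e9) == pytest.approx(
            tiem_ratecoeff(rc), rel=1e-6
        )
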