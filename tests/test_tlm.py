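"""Transverse-resonance dispersion solver against independent oracles,
impedance-transform identities and the liquid-loading sweep."""

import cmath
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from lovewave import presets
from lovewave.materials import Material, MaterialKind, VACUUM, load_material
from lovewave.tlm import (
    Layer,
    LayerStack,
    NoGuidedModeError,
    penetration_depth,
    sensitivity,
    solve_dispersion,
    surface_impedance_down,
    surface_impedance_up,
    transform_impedance,
    viscosity_sweep,
)

OMEGA = 2 * math.pi * 30e6


def rigid(rho, mu, name="rigid"):
    return Material(name, MaterialKind.RIGID_SOLID, rho, shear_modulus=mu)


def two_layer_stack(rho_s, mu_s, rho_l, mu_l, h, top=VACUUM):
    return LayerStack(rigid(rho_s, mu_s, "sub"),
                      (Layer(rigid(rho_l, mu_l, "layer"), h),), top)


def love_oracle(rho_s, mu_s, rho_l, mu_l, h, f):
    """Classical two-layer Love dispersion relation tan(q h) = mu_s s / (mu_l q),
    solved by bisection in x = q*h on (0, min(pi/2, q_max h)) — fundamental mode."""
    om = 2 * math.pi * f
    v_l = math.sqrt(mu_l / rho_l)
    v_s = math.sqrt(mu_s / rho_s)
    q_max = om * math.sqrt(1 / v_l**2 - 1 / v_s**2)

    def g(x):
        q = x / h
        k2 = (om / v_l) ** 2 - q**2
        s = math.sqrt(max(k2 - (om / v_s) ** 2, 0.0))
        return math.tan(x) - mu_s * s / (mu_l * q)

    hi = min(math.pi / 2, q_max * h)
    x = brentq(g, 1e-9 * hi, hi * (1 - 1e-12), xtol=1e-15, rtol=8.9e-16)
    q = x / h
    k = math.sqrt((om / v_l) ** 2 - q**2)
    return om / k  # phase velocity


class TestTransformImpedance:
    def test_zero_thickness_returns_load(self):
        assert transform_impedance(5 + 1j, 2 - 3j, 1 + 1j, 0.0) == pytest.approx(2 - 3j)

    def test_matched_line_any_length(self):
        zc = 3.0 + 0.5j
        for h in (0.0, 1e-6, 1.0):
            assert transform_impedance(zc, zc, 2e5 + 100j, h) == pytest.approx(zc)

    def test_lossless_eighth_wave_shorted_line(self):
        # shorted line of electrical length pi/4: Z = j*Zc*tan(pi/4) = j*Zc
        zc = 7.0
        gamma = 1j
        assert transform_impedance(zc, 0.0, gamma, math.pi / 4) == pytest.approx(1j * zc)

    def test_infinite_line_returns_characteristic(self):
        zc = 4.0 + 1.0j
        z = transform_impedance(zc, 123.0, 1e5 + 1e3j, 1.0)
        assert z == pytest.approx(zc)

    def test_zero_characteristic_rejected(self):
        with pytest.raises(ValueError):
            transform_impedance(0.0, 1.0, 1.0, 1.0)


class TestSurfaceImpedances:
    def test_kanazawa_liquid_loading(self):
        """A semi-infinite Newtonian half-space presents sqrt(j*omega*rho*eta)."""
        stack = LayerStack(rigid(4650, 86.3e9), (), load_material("water_25C"))
        z = surface_impedance_up(stack, OMEGA, 0.0 + 0.0j)
        assert complex(z) == pytest.approx(cmath.sqrt(1j * OMEGA * 997.0 * 0.893e-3),
                                           rel=1e-12)

    def test_vacuum_top_is_zero(self):
        stack = LayerStack(rigid(4650, 86.3e9), (), VACUUM)
        assert surface_impedance_up(stack, OMEGA, 1e4 + 0j) == 0.0

    def test_substrate_transverse_scaling(self):
        """Down-impedance = bulk Zc times k_y/k (the cos phi projection)."""
        sub = rigid(4650, 86.3e9)
        stack = LayerStack(sub, (), VACUUM)
        k_sub = OMEGA / sub.shear_velocity
        k_x = 1.2 * k_sub + 0j
        z = complex(surface_impedance_down(stack, OMEGA, k_x))
        gamma = cmath.sqrt(k_x**2 - k_sub**2)
        zc = math.sqrt(4650 * 86.3e9)
        assert z == pytest.approx(zc * (-1j * gamma) / k_sub, rel=1e-12)

    def test_zero_thickness_layer_changes_nothing(self):
        base = LayerStack(rigid(4650, 86.3e9), (), load_material("water_25C"))
        padded = LayerStack(base.substrate,
                            (Layer(rigid(1100, 1.21e9), 0.0),), base.top)
        k_x = 5e4 + 10j
        assert surface_impedance_up(padded, OMEGA, k_x) == pytest.approx(
            surface_impedance_up(base, OMEGA, k_x))
        assert surface_impedance_down(padded, OMEGA, k_x) == pytest.approx(
            surface_impedance_down(base, OMEGA, k_x))


class TestDispersionOracle:
    def test_su8_on_niobate_matches_analytic_relation(self):
        args = (4650.0, 86.3e9, 1100.0, 1.21e9, 8e-6)
        stack = two_layer_stack(*args)
        sol = solve_dispersion(stack, 30e6)
        assert sol.phase_velocity == pytest.approx(love_oracle(*args, 30e6), rel=1e-6)
        assert sol.attenuation_db_per_m == pytest.approx(0.0, abs=1e-6)

    def test_randomized_lossless_stacks_match_oracle(self):
        rng = np.random.default_rng(20260925)
        checked = 0
        while checked < 50:
            rho_s = rng.uniform(2000, 8000)
            v_s = rng.uniform(3000, 6000)
            rho_l = rng.uniform(900, 3000)
            v_l = rng.uniform(0.15, 0.85) * v_s
            f = rng.uniform(10e6, 100e6)
            h = rng.uniform(0.2, 4.0) * v_l / f / (2 * math.pi)  # moderate q*h
            mu_s, mu_l = rho_s * v_s**2, rho_l * v_l**2
            sol = solve_dispersion(two_layer_stack(rho_s, mu_s, rho_l, mu_l, h), f)
            v_ref = love_oracle(rho_s, mu_s, rho_l, mu_l, h, f)
            assert sol.phase_velocity == pytest.approx(v_ref, rel=1e-6)
            checked += 1

    def test_thin_layer_limit_approaches_substrate_velocity(self):
        v_s = math.sqrt(86.3e9 / 4650)
        sol = solve_dispersion(two_layer_stack(4650, 86.3e9, 1100, 1.21e9, 0.2e-6), 30e6)
        assert sol.phase_velocity < v_s
        assert sol.phase_velocity == pytest.approx(v_s, rel=1e-4)

    def test_lossy_root_zeroes_independent_partial_wave_determinant(self):
        """Cross-check the full lossy solve against a boundary-condition
        determinant assembled independently of the impedance recursion."""
        su8 = load_material("SU8")
        water = load_material("water_25C")
        stack = LayerStack(rigid(4650, 86.3e9, "sub"), (Layer(su8, 8e-6),), water)
        sol = solve_dispersion(stack, 30e6)

        def det(k_x):
            om = OMEGA
            mu_s = 86.3e9
            mu_l = su8.shear_modulus + 1j * om * su8.viscosity
            mu_t = 1j * om * water.viscosity
            g_s = cmath.sqrt(k_x**2 - om**2 * 4650 / mu_s)
            g_l = cmath.sqrt(k_x**2 - om**2 * su8.density / mu_l)
            g_t = cmath.sqrt(k_x**2 - om**2 * water.density / mu_t)
            h = 8e-6
            em, ep = cmath.exp(-g_l * h), cmath.exp(g_l * h)
            scale = mu_s * abs(g_s)
            m = np.array([
                [1, -1, -1, 0],
                [mu_s * g_s / scale, mu_l * g_l / scale, -mu_l * g_l / scale, 0],
                [0, em, ep, -1],
                [0, -mu_l * g_l * em / scale, mu_l * g_l * ep / scale, mu_t * g_t / scale],
            ], dtype=complex)
            return np.linalg.det(m)

        d0 = abs(det(sol.wavenumber))
        d_off = min(abs(det(sol.wavenumber * (1 + 2e-3))),
                    abs(det(sol.wavenumber * (1 - 2e-3))))
        assert d0 < 1e-5 * d_off

    def test_no_guided_mode_for_fast_layer(self):
        # guiding layer faster than the substrate cannot trap a Love mode
        with pytest.raises(NoGuidedModeError):
            solve_dispersion(two_layer_stack(2200, 2200 * 3000**2, 2700, 2700 * 5000**2,
                                             5e-6), 30e6)


class TestDispersionProperties:
    def test_reference_plane_independence(self, ref_stack):
        wet = ref_stack.with_top(load_material("water_25C"))
        roots = [solve_dispersion(wet, 30e6, reference=r).wavenumber
                 for r in range(len(wet.layers) + 1)]
        for k in roots[1:]:
            assert abs(k - roots[0]) / abs(roots[0]) < 1e-8

    def test_liquid_loading_increases_attenuation(self, ref_stack):
        a_vac = solve_dispersion(ref_stack, 30e6).attenuation_db_per_m
        a_wet = solve_dispersion(ref_stack.with_top(load_material("water_25C")),
                                 30e6).attenuation_db_per_m
        a_4cp = solve_dispersion(ref_stack.with_top(load_material("glycerol_4cP")),
                                 30e6).attenuation_db_per_m
        assert 0 <= a_vac < a_wet < a_4cp

    @pytest.mark.parametrize("f", [20e6, 30e6, 45e6])
    @pytest.mark.parametrize("top", ["vacuum", "water_25C", "glycerol_4cP"])
    def test_passivity_over_grid(self, ref_stack, f, top):
        sol = solve_dispersion(ref_stack.with_top(load_material(top)), f)
        assert sol.attenuation_db_per_m >= -1e-9
        assert sol.residual < 1e-8

    def test_thickness_sensitivity_peaks_in_design_region(self, ref_stack):
        """|dv/dz| around z=0.05 (the chosen design point) far exceeds the
        thin-layer region z~0.005."""
        lam = presets.WAVELENGTH
        idx = len(ref_stack.layers) - 1

        def v_of_z(z):
            st = ref_stack.with_layer_thickness(idx, z * lam)
            return solve_dispersion(st, 30e6).phase_velocity

        def slope(z):
            dz = 0.002
            return (v_of_z(z + dz) - v_of_z(z - dz)) / (2 * dz)

        assert abs(slope(0.05)) > abs(slope(0.005))


class TestPenetrationDepth:
    def test_water_at_30_and_100_mhz(self):
        assert penetration_depth(1e-3, 1000.0, 30e6) == pytest.approx(103e-9, rel=0.05)
        assert penetration_depth(1e-3, 1000.0, 100e6) == pytest.approx(56e-9, rel=0.15)

    def test_inverse_square_root_frequency_law(self):
        d1 = penetration_depth(1e-3, 1000.0, 25e6)
        d4 = penetration_depth(1e-3, 1000.0, 100e6)
        assert d1 / d4 == pytest.approx(2.0, rel=1e-12)

    def test_matches_liquid_transverse_decay_length(self):
        """delta = sqrt(2 eta / (rho omega)): the 1/e depth of the Newtonian
        half-space partial wave, identical to the closed form."""
        eta, rho, f = 2.5e-3, 1082.0, 30e6
        om = 2 * math.pi * f
        k_liq = om * cmath.sqrt(rho / (1j * om * eta))
        decay = 1.0 / abs(k_liq.imag)
        assert penetration_depth(eta, rho, f) == pytest.approx(decay, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            penetration_depth(0.0, 1000.0, 30e6)


@pytest.fixture(scope="module")
def sweep(ref_stack):
    liquids = [(0.0, 0.0)] + presets.calibration_liquids()
    return viscosity_sweep(ref_stack, liquids, 30e6,
                           presets.DELAY_PATH_WAVELENGTHS * presets.WAVELENGTH,
                           wetted_path=presets.wetted_path())


class TestViscositySweep:
    def test_loss_monotone_in_viscosity_density_product(self, sweep):
        il = sweep["IL_dB"].to_numpy()
        assert np.all(np.diff(-il) > 0)  # loss magnitude grows with eta*rho

    def test_phase_shifts_negative_with_viscosity(self, sweep):
        ph = sweep["phase_deg"].to_numpy()
        assert np.all(np.diff(ph) < 0)

    def test_vacuum_row_equals_dry_baseline(self, ref_stack, sweep):
        L = presets.DELAY_PATH_WAVELENGTHS * presets.WAVELENGTH
        sol = solve_dispersion(ref_stack, 30e6)
        assert sweep["IL_dB"].iloc[0] == pytest.approx(-sol.attenuation_db_per_m * L)

    def test_path_length_linearity(self, ref_stack):
        liquids = [(2.5e-3, 1082.0)]
        L = 37 * presets.WAVELENGTH
        one = viscosity_sweep(ref_stack, liquids, 30e6, L)
        two = viscosity_sweep(ref_stack, liquids, 30e6, 2 * L)
        assert two["IL_dB"].iloc[0] == pytest.approx(2 * one["IL_dB"].iloc[0])
        assert two["phase_deg"].iloc[0] == pytest.approx(2 * one["phase_deg"].iloc[0])

    def test_sensitivity_needs_two_points(self, sweep):
        with pytest.raises(ValueError):
            sensitivity(sweep.iloc[:1])

    def test_sensitivity_of_linear_data_is_constant(self):
        import pandas as pd
        table = pd.DataFrame({"eta_cP": [1.0, 2.0, 3.0],
                              "IL_dB": [-30.0, -32.0, -34.0],
                              "phase_deg": [-10.0, -14.0, -18.0]})
        s = sensitivity(table)
        assert np.allclose(s["dIL_dEta_dB_per_cP"], -2.0)
        assert np.allclose(s["dPhase_dEta_deg_per_cP"], -4.0)
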