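"""Transmission-line model (TLM) of a layered shear-horizontal waveguide.

A Love-wave device is a stack: a fast rigid substrate half-space, one or
more finite layers (metallization, polymer guiding layer) and a top
half-space (vacuum for an air-loaded device, a Newtonian liquid for a wet
one).  For SH polarization each medium behaves, in the transverse (depth, y)
direction, like a section of transmission line whose conjugate field pair is
shear stress and particle velocity.

For a candidate propagation wavenumber ``k_x`` along the surface, a medium
with bulk wavenumber ``k_i`` contributes a transverse line with

    gamma_i = sqrt(k_x^2 - k_i^2)            (principal branch, Re >= 0)
    Z_t,i   = -j * gamma_i * mu_c,i / omega  (transverse characteristic impedance)

which equals the bulk impedance scaled by cos(phi) of the transverse
decomposition ``k_y = k*cos(phi)`` (here ``k_y = -j*gamma``).  Finite layers
transform a load impedance through the standard tanh formula; half-spaces
terminate the line with their own ``Z_t`` on the decaying branch.  A guided
mode exists where the impedances looking up and down from a reference plane
cancel: ``Z_up(k_x) + Z_down(k_x) = 0`` (transverse resonance).

The solver brackets the root on the real velocity axis using the lossless
(elastic) twin of the stack, then polishes the complex root of the lossy
stack.  ``Re(k_x)`` gives the phase velocity, ``-Im(k_x)`` the attenuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .materials import (
    Material,
    MaterialKind,
    VACUUM,
    complex_shear_modulus,
    pa_s_to_cp,
)

__all__ = [
    "Layer",
    "LayerStack",
    "DispersionSolution",
    "TransmissionLineSection",
    "transform_impedance",
    "surface_impedance_up",
    "surface_impedance_down",
    "solve_dispersion",
    "penetration_depth",
    "effective_wavenumber",
    "viscosity_sweep",
    "sensitivity",
    "NoGuidedModeError",
]

NP_TO_DB = 20.0 / math.log(10.0)  # 8.6859 dB per neper


class NoGuidedModeError(RuntimeError):
    """No guided Love mode exists for the requested stack/frequency."""


@dataclass(frozen=True)
class Layer:
    """A finite layer: a material and its thickness in metres."""

    material: Material
    thickness: float

    def __post_init__(self) -> None:
        if self.thickness < 0.0:
            raise ValueError("layer thickness must be >= 0")


@dataclass(frozen=True)
class LayerStack:
    """Substrate half-space, finite layers (substrate upward) and top half-space."""

    substrate: Material
    layers: tuple[Layer, ...] = ()
    top: Material = VACUUM

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.substrate.kind is MaterialKind.VACUUM:
            raise ValueError("substrate cannot be vacuum")

    def with_top(self, top: Material) -> "LayerStack":
        """Same guide with a different top half-space (liquid exchange)."""
        return LayerStack(self.substrate, self.layers, top)

    def with_layer_thickness(self, index: int, thickness: float) -> "LayerStack":
        layers = list(self.layers)
        layers[index] = Layer(layers[index].material, thickness)
        return LayerStack(self.substrate, tuple(layers), self.top)

    def lossless(self) -> "LayerStack":
        """Elastic twin: viscosities dropped, liquid top replaced by vacuum."""
        return LayerStack(
            self.substrate.lossless(),
            tuple(Layer(l.material.lossless(), l.thickness) for l in self.layers),
            self.top.lossless(),
        )

    def scaled_loss(self, scale: float) -> "LayerStack":
        """Stack with every viscosity multiplied by ``scale`` (loss homotopy)."""
        if scale == 1.0:
            return self
        if scale == 0.0:
            return self.lossless()

        def scaled(m: Material) -> Material:
            if m.viscosity is None or m.viscosity == 0.0:
                return m
            if m.kind is MaterialKind.NEWTONIAN_LIQUID:
                return Material(m.name, m.kind, m.density, viscosity=m.viscosity * scale)
            return Material(m.name, m.kind, m.density, m.shear_modulus,
                            m.viscosity * scale)

        return LayerStack(scaled(self.substrate),
                          tuple(Layer(scaled(l.material), l.thickness) for l in self.layers),
                          scaled(self.top))

    @property
    def substrate_velocity(self) -> float:
        return self.substrate.shear_velocity

    @property
    def slowest_layer_velocity(self) -> float:
        """Smallest shear velocity among solid finite layers (guiding condition)."""
        vs = [l.material.shear_velocity for l in self.layers
              if l.material.shear_velocity > 0.0 and l.thickness > 0.0]
        if not vs:
            return 0.0
        return min(vs)


@dataclass(frozen=True)
class TransmissionLineSection:
    """Transverse-line analog of one medium at (omega, k_x)."""

    Zc: complex        # transverse characteristic impedance, Pa*s/m
    gamma: complex     # transverse propagation constant (tanh argument), 1/m
    thickness: float   # m; math.inf for half-spaces

    @property
    def k_y(self) -> complex:
        """Transverse wavenumber k_y = k*cos(phi) = -j*gamma."""
        return -1j * self.gamma


@dataclass(frozen=True)
class DispersionSolution:
    """A guided-mode root of the transverse resonance condition at one frequency."""

    frequency: float                 # Hz
    phase_velocity: float            # m/s, omega / Re(k_x)
    attenuation_db_per_m: float      # propagation loss, >= 0 for passive stacks
    attenuation_db_per_wavelength: float
    wavenumber: complex              # k_x, 1/m (Im <= 0: decaying wave)
    residual: float                  # |Z_up+Z_down| / (|Z_up|+|Z_down|) at the root
    k_y: tuple[complex, ...] = ()    # transverse wavenumbers: substrate, layers..., top


def transform_impedance(z_char: complex, z_load: complex, gamma: complex,
                        thickness: float) -> complex:
    """Impedance seen through a line section of length ``thickness`` ending in ``z_load``.

    Standard formula ``Z = Zc*(ZL + Zc*tanh(gamma*h)) / (Zc + ZL*tanh(gamma*h))``.
    ``gamma`` is the transverse propagation constant (``j*k_y`` for an
    oscillatory lossless section).  Invariant under the sign of ``gamma``;
    for ``Re(gamma) > 0`` the ``h -> inf`` limit returns ``Zc``.
    """
    if z_char == 0:
        raise ValueError("characteristic impedance must be nonzero")
    if thickness < 0:
        raise ValueError("thickness must be >= 0")
    t = np.tanh(gamma * thickness)
    num = z_load + z_char * t
    den = z_char + z_load * t
    if abs(den) < 1e-30 * max(abs(num), abs(z_char)):
        raise ZeroDivisionError("transmission-line resonance: transformed impedance diverges")
    return z_char * num / den


def _section(material: Material, omega: float, k_x, thickness: float = math.inf):
    """Transverse gamma and Z_t for one medium; vectorized over k_x arrays."""
    mu_c = complex_shear_modulus(material, omega)
    k2 = omega**2 * material.density / mu_c
    gamma = np.sqrt(np.asarray(k_x, dtype=complex) ** 2 - k2)
    z_t = -1j * gamma * mu_c / omega
    return gamma, z_t


def surface_impedance_up(stack: LayerStack, omega: float, k_x,
                         reference: int = 0):
    """Impedance looking upward (toward the top half-space) from a reference plane.

    ``reference`` counts finite layers below the plane; 0 places it at the
    substrate / first-layer interface.  The top half-space terminates the
    line: vacuum with 0, any other medium with its transverse impedance on
    the decaying branch.  Vectorized over ``k_x``.
    """
    if not 0 <= reference <= len(stack.layers):
        raise ValueError("reference plane index out of range")
    if stack.top.kind is MaterialKind.VACUUM:
        z = np.zeros(np.shape(np.asarray(k_x, dtype=complex)), dtype=complex)
        if np.isscalar(k_x):
            z = 0.0 + 0.0j
    else:
        _, z = _section(stack.top, omega, k_x)
    for layer in reversed(stack.layers[reference:]):
        if layer.thickness == 0.0:
            continue
        gamma, z_t = _section(layer.material, omega, k_x, layer.thickness)
        t = np.tanh(gamma * layer.thickness)
        z = z_t * (z + z_t * t) / (z_t + z * t)
    return z


def surface_impedance_down(stack: LayerStack, omega: float, k_x,
                           reference: int = 0):
    """Impedance looking downward (into the substrate) from a reference plane.

    The substrate half-space presents its transverse impedance on the branch
    decaying away from the guide; layers below the reference plane (if any)
    transform it upward.  Vectorized over ``k_x``.
    """
    if not 0 <= reference <= len(stack.layers):
        raise ValueError("reference plane index out of range")
    _, z = _section(stack.substrate, omega, k_x)
    for layer in stack.layers[:reference]:
        if layer.thickness == 0.0:
            continue
        gamma, z_t = _section(layer.material, omega, k_x, layer.thickness)
        t = np.tanh(gamma * layer.thickness)
        z = z_t * (z + z_t * t) / (z_t + z * t)
    return z


def _resonance(stack: LayerStack, omega: float, k_x, reference: int = 0):
    """Z_up + Z_down, normalized by the substrate bulk impedance."""
    scale = abs(characteristic_scale(stack))
    return (surface_impedance_up(stack, omega, k_x, reference)
            + surface_impedance_down(stack, omega, k_x, reference)) / scale


def characteristic_scale(stack: LayerStack) -> float:
    """Normalization impedance: bulk |Zc| of the substrate's elastic part."""
    m = stack.substrate
    return math.sqrt(m.density * (m.shear_modulus or 0.0))


def _damped_newton(f, x0: complex, xtol: float, maxiter: int = 100) -> complex:
    """Newton iteration in the complex plane with a numerical derivative and
    backtracking on |f| (robust where the plain secant overshoots)."""
    x = complex(x0)
    fx = f(x)
    for _ in range(maxiter):
        if fx == 0:
            return x
        h = 1e-7 * max(abs(x), 1.0)
        dfdx = (f(x + h) - f(x - h)) / (2.0 * h)
        if dfdx == 0:
            raise RuntimeError("zero derivative in complex Newton")
        step = -fx / dfdx
        for _ in range(40):
            x_new = x + step
            f_new = f(x_new)
            if abs(f_new) < abs(fx):
                break
            step *= 0.5
        else:
            if abs(fx) < 1e-10:  # stalled at numerical noise level: converged
                return x
            raise RuntimeError(f"line search stalled at x={x:.6g}, |f|={abs(fx):.3e}")
        x, fx = x_new, f_new
        if abs(step) < xtol:
            return x
    raise RuntimeError(f"no convergence after {maxiter} Newton iterations (|f|={abs(fx):.3e})")


def _lossless_roots(stack: LayerStack, omega: float, n_scan: int = 4000) -> list[float]:
    """Real phase-velocity roots of the lossless transverse resonance, ascending."""
    v_hi = stack.substrate_velocity
    v_lo = stack.slowest_layer_velocity
    if v_lo <= 0.0 or v_lo >= v_hi:
        raise NoGuidedModeError(
            f"no slow guiding layer: layer velocity {v_lo:g} m/s vs substrate {v_hi:g} m/s")
    # Open interval; crowd extra points toward the substrate cutoff (where the
    # thin-layer root hides) and around each layer's tan-type poles q*h =
    # (n+1/2)*pi (a high stiffness contrast pins a root arbitrarily close to
    # a pole, invisible to a uniform scan).
    v_uniform = np.linspace(v_lo * (1 + 1e-9), v_hi * (1 - 1e-12), n_scan)
    extras = [v_hi * (1.0 - np.geomspace(1e-11, 1e-4, 200))]
    offsets = np.geomspace(1e-12, 1e-3, 60)
    for layer in stack.layers:
        v_i = layer.material.shear_velocity
        if v_i <= 0.0 or layer.thickness <= 0.0:
            continue
        k_i = omega / v_i
        n = 0
        while True:
            q = (n + 0.5) * math.pi / layer.thickness
            if q >= k_i:
                break
            v_pole = omega / math.sqrt(k_i**2 - q**2)
            if v_lo < v_pole < v_hi:
                extras.append(v_pole * (1.0 + offsets))
                extras.append(v_pole * (1.0 - offsets))
            n += 1
    v_grid = np.unique(np.concatenate([v_uniform, *extras]))
    v_grid = v_grid[(v_grid > v_lo) & (v_grid < v_hi)]
    k_grid = omega / v_grid
    f_grid = np.asarray(_resonance(stack, omega, k_grid)).imag

    def f_of_v(v: float) -> float:
        return complex(_resonance(stack, omega, omega / v)).imag

    roots: list[float] = []
    sign = np.sign(f_grid)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    for i in idx:
        a, b = v_grid[i], v_grid[i + 1]
        try:
            v_root = optimize.brentq(f_of_v, a, b, xtol=1e-12 * b, rtol=8.9e-16)
        except ValueError:
            continue
        # Reject tan-type poles, where brentq "converges" onto a discontinuity.
        if abs(f_of_v(v_root)) < 1e-3:
            roots.append(v_root)
    return sorted(roots)


def solve_dispersion(stack: LayerStack, frequency: float, mode: int = 0,
                     reference: int = 0, residual_tol: float = 1e-8) -> DispersionSolution:
    """Solve the transverse resonance condition for a guided Love mode.

    The real root is bracketed by scanning phase velocity between the
    slowest-layer and substrate shear velocities on the lossless twin of the
    stack, then polished in the complex ``k_x`` plane with the full lossy
    stack (secant iteration).  ``mode=0`` is the fundamental (slowest) mode;
    higher indices select faster roots when they exist.

    Raises :class:`NoGuidedModeError` when no root lies in the physical
    bracket, and ``RuntimeError`` when the complex polish fails to reach
    ``residual_tol``.
    """
    if frequency <= 0.0:
        raise ValueError("frequency must be > 0")
    omega = 2.0 * math.pi * frequency
    roots = _lossless_roots(stack.lossless(), omega)
    if not roots:
        raise NoGuidedModeError(
            f"no guided mode at {frequency/1e6:g} MHz for stack "
            f"(bracket {stack.slowest_layer_velocity:g}-{stack.substrate_velocity:g} m/s)")
    if mode >= len(roots):
        raise NoGuidedModeError(f"mode {mode} not guided ({len(roots)} mode(s) found)")
    k0 = omega / roots[mode]

    def polish(st: LayerStack, k_start: complex) -> complex:
        def f(k_x: complex) -> complex:
            return complex(_resonance(st, omega, k_x, reference))
        return _damped_newton(f, complex(k_start), xtol=1e-13 * abs(k0))

    def rel_residual(k_x: complex) -> float:
        z_up = complex(surface_impedance_up(stack, omega, k_x, reference))
        z_down = complex(surface_impedance_down(stack, omega, k_x, reference))
        denom = abs(z_up) + abs(z_down)
        return abs(z_up + z_down) / denom if denom > 0 else abs(z_up + z_down)

    # Track the root from the elastic stack to the full lossy one.  A direct
    # jump works when losses are mild; strongly loaded modes (thick lossy
    # layer, high z) need the viscosity ramp to stay in the right basin.
    k_root = None
    try:
        k_direct = polish(stack, complex(k0))
        if rel_residual(k_direct) <= residual_tol:
            k_root = k_direct
    except RuntimeError:
        pass
    if k_root is None:
        k_root = complex(k0)
        try:
            for scale in np.geomspace(0.02, 1.0, 12):
                k_root = polish(stack.scaled_loss(float(scale)), k_root)
        except RuntimeError as exc:
            raise RuntimeError(
                f"complex root polish failed from k0={k0:g}: {exc}") from exc

    residual = rel_residual(k_root)
    if residual > residual_tol:
        raise RuntimeError(
            f"dispersion root did not converge: residual {residual:.3e} at "
            f"k_x={k_root:.6g} (f={frequency/1e6:g} MHz)")

    v_phase = omega / k_root.real
    alpha_np = -k_root.imag          # Np/m; >= 0 for passive stacks
    alpha_db = NP_TO_DB * alpha_np
    wavelength = v_phase / frequency
    k_y = []
    for medium in (stack.substrate, *(l.material for l in stack.layers), stack.top):
        if medium.kind is MaterialKind.VACUUM:
            k_y.append(complex("nan"))
            continue
        gamma, _ = _section(medium, omega, k_root)
        k_y.append(-1j * complex(gamma))
    return DispersionSolution(
        frequency=frequency,
        phase_velocity=v_phase,
        attenuation_db_per_m=alpha_db,
        attenuation_db_per_wavelength=alpha_db * wavelength,
        wavenumber=k_root,
        residual=residual,
        k_y=tuple(k_y),
    )


def penetration_depth(viscosity: float, density: float, frequency: float) -> float:
    """1/e decay depth of a shear wave into a Newtonian liquid, in metres.

    ``delta = sqrt(eta / (rho * pi * f))``.  For water-like liquids this is
    ~100 nm at 30 MHz and ~50 nm at 100 MHz, which is what motivates a
    low-frequency device when the target lies beyond the focal-adhesion zone
    of a cell monolayer.
    """
    if viscosity <= 0 or density <= 0 or frequency <= 0:
        raise ValueError("viscosity, density and frequency must be > 0")
    return math.sqrt(viscosity / (density * math.pi * frequency))


def effective_wavenumber(k_wet: complex, k_dry: complex, wetted_path: float,
                         total_path: float) -> complex:
    """Path-averaged wavenumber of a delay line whose liquid covers part of it.

    ``exp(-j*k_eff*L) = exp(-j*(k_wet*L_w + k_dry*(L - L_w)))``, i.e. the
    phase and loss accumulate over the wetted sensing region at the
    liquid-loaded wavenumber and over the rest at the air-loaded one.
    """
    if not 0.0 <= wetted_path <= total_path:
        raise ValueError("need 0 <= wetted_path <= total_path")
    return (k_wet * wetted_path + k_dry * (total_path - wetted_path)) / total_path


def viscosity_sweep(stack: LayerStack, liquids: Sequence[tuple[float, float]],
                    frequency: float, delay_path: float,
                    wetted_path: Optional[float] = None) -> pd.DataFrame:
    """Liquid-loading sweep: dispersion per liquid, loss and phase over a delay path.

    ``liquids`` is a sequence of ``(viscosity Pa*s, density kg/m^3)`` pairs
    defining Newtonian top half-spaces (use viscosity 0 for vacuum/air).
    ``wetted_path`` restricts the liquid to the first ``wetted_path`` metres
    of the delay path (the region under a fluidic chamber), the remainder
    being air-loaded; ``None`` (default) wets the full path.  Returns a
    DataFrame with columns ``eta_cP, rho_kgm3, v_phase_mps, alpha_dB_per_m,
    IL_dB, phase_deg`` where ``IL_dB`` is the (negative) propagation-loss
    contribution and ``phase_deg`` the accumulated phase ``-Re(k_x)*L`` in
    degrees.  Liquids whose dispersion solve fails are reported as NaN rows;
    the sweep continues.
    """
    if len(liquids) == 0:
        raise ValueError("at least one liquid required")
    wet = delay_path if wetted_path is None else wetted_path
    if not 0.0 <= wet <= delay_path:
        raise ValueError("wetted_path must lie in [0, delay_path]")
    k_dry: complex | None = None
    if wet < delay_path:
        k_dry = solve_dispersion(stack.with_top(VACUUM), frequency).wavenumber
    rows = []
    for eta, rho in liquids:
        if eta == 0.0:
            top = VACUUM
        else:
            top = Material(f"liquid_{pa_s_to_cp(eta):g}cP", MaterialKind.NEWTONIAN_LIQUID,
                           density=rho, viscosity=eta)
        row = {"eta_cP": pa_s_to_cp(eta), "rho_kgm3": rho}
        try:
            sol = solve_dispersion(stack.with_top(top), frequency)
        except (NoGuidedModeError, RuntimeError) as exc:
            row.update(v_phase_mps=math.nan, alpha_dB_per_m=math.nan,
                       IL_dB=math.nan, phase_deg=math.nan, error=str(exc))
        else:
            k_eff = sol.wavenumber if k_dry is None else effective_wavenumber(
                sol.wavenumber, k_dry, wet, delay_path)
            row.update(
                v_phase_mps=sol.phase_velocity,
                alpha_dB_per_m=sol.attenuation_db_per_m,
                IL_dB=NP_TO_DB * k_eff.imag * delay_path,
                phase_deg=-math.degrees(k_eff.real * delay_path),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def sensitivity(sweep: pd.DataFrame) -> pd.DataFrame:
    """Finite-difference sensitivities of IL and phase with respect to viscosity.

    Central differences on the sweep grid, one-sided at the endpoints.
    Returns columns ``eta_cP, dIL_dEta_dB_per_cP, dPhase_dEta_deg_per_cP``.
    """
    if len(sweep) < 2:
        raise ValueError("sensitivity needs at least 2 sweep points")
    eta = sweep["eta_cP"].to_numpy(dtype=float)
    out = {"eta_cP": eta}
    for col, name in (("IL_dB", "dIL_dEta_dB_per_cP"),
                      ("phase_deg", "dPhase_dEta_deg_per_cP")):
        y = sweep[col].to_numpy(dtype=float)
        out[name] = np.gradient(y, eta)
    return pd.DataFrame(out)
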