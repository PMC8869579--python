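"""Cross-field equivalent-circuit model of interdigital transducers (IDTs)
and synthesis of the full delay-line transmission coefficient S21.

The cross-field (Campbell) model represents an N-pair IDT as a radiation
conductance Ga(f) in parallel with an acoustic susceptance Ba(f) and the
static finger capacitance C_T:

    X     = N_p * pi * (f - f0) / f0
    Ga(f) = Ga0 * (sin X / X)^2,      Ga0 = 8 * K2 * f0 * Cs * W * N_p^2
    Ba(f) = Ga0 * (sin 2X - 2X) / (2 X^2)
    C_T   = N_p * Cs * W

with K2 the electromechanical coupling coefficient of the substrate, Cs the
finger-pair capacitance per unit aperture, W the acoustic aperture and f0
the synchronous frequency v/lambda.  Driving the IDT from a source
resistance R converts electrical to acoustic power with loss

    CL = -10*log10( 2*Ga*R / ((1 + Ga*R)^2 + ((Ba + omega*C_T)*R)^2) )

plus an optional 3 dB for the bidirectionality of an untuned transducer.
The delay-line S21 chains two conversion transfers with the propagation
factor exp(-j*k_x*L) supplied by the dispersion solver.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np

from .sparams import TwoPortSpectrum

__all__ = [
    "IDTDesign",
    "SubstrateElectrical",
    "DelayLineDesign",
    "IDTResponse",
    "synchronous_frequency",
    "idt_response",
    "conversion_transfer",
    "delay_line_s21",
    "triple_transit",
    "BIDIRECTIONALITY_LOSS_DB",
]

BIDIRECTIONALITY_LOSS_DB = 3.0


@dataclass(frozen=True)
class IDTDesign:
    """Geometry of one interdigital transducer.

    ``finger_count`` counts electrodes; with ``fingers_are_pairs=False``
    (default) 12 fingers mean 6 electrode pairs.  ``wavelength`` is the IDT
    period (m), ``aperture`` the overlap length W (m), ``metallization`` the
    finger width over half-period ratio.
    """

    finger_count: int = 12
    wavelength: float = 144e-6
    aperture: float = 21 * 144e-6
    metallization: float = 0.5
    fingers_are_pairs: bool = False

    def __post_init__(self) -> None:
        if self.finger_count < 2:
            raise ValueError("IDT needs at least 2 fingers")
        if self.wavelength <= 0 or self.aperture <= 0:
            raise ValueError("wavelength and aperture must be > 0")
        if not 0.0 < self.metallization < 1.0:
            raise ValueError("metallization ratio must be in (0, 1)")

    @property
    def n_pairs(self) -> int:
        return self.finger_count if self.fingers_are_pairs else self.finger_count // 2


@dataclass(frozen=True)
class SubstrateElectrical:
    """Electrical constants of the piezoelectric substrate under the IDTs.

    Defaults are literature-grade values for 36Y-X lithium niobate, which the
    source device uses precisely for its strong coupling: ``k2`` ~ 0.16
    (electromechanical coupling coefficient, dimensionless) and ``cs`` ~ 5e-10
    F/m of finger-pair capacitance per unit aperture.  ``free_velocity`` is
    the free-surface shear velocity used when no dispersion solution is
    supplied.
    """

    k2: float = 0.16
    cs: float = 5.0e-10
    free_velocity: float = 4307.9

    def __post_init__(self) -> None:
        if not 0.0 < self.k2 < 0.35:
            raise ValueError("coupling coefficient K2 out of physical range (0, 0.35)")
        if self.cs <= 0 or self.free_velocity <= 0:
            raise ValueError("cs and free_velocity must be > 0")


@dataclass(frozen=True)
class DelayLineDesign:
    """Two IDTs, a delay path and the electrical environment."""

    input_idt: IDTDesign
    output_idt: IDTDesign
    delay_path: float                     # centre-to-centre, m
    electrical: SubstrateElectrical = field(default_factory=SubstrateElectrical)
    source_impedance: float = 50.0        # ohm, source and load
    include_bidirectionality: bool = True

    def __post_init__(self) -> None:
        if self.delay_path <= 0:
            raise ValueError("delay path must be > 0")
        if self.source_impedance <= 0:
            raise ValueError("source impedance must be > 0")


@dataclass(frozen=True)
class IDTResponse:
    """Sampled admittance and conversion loss of one IDT."""

    frequency: np.ndarray       # Hz
    Ga: np.ndarray              # radiation conductance, S
    Ba: np.ndarray              # acoustic susceptance, S
    C_T: float                  # static capacitance, F
    conversion_loss_db: np.ndarray
    f0: float                   # synchronous frequency, Hz


def synchronous_frequency(design: IDTDesign, velocity: float) -> float:
    """Synchronous frequency f0 = v / lambda."""
    if velocity <= 0:
        raise ValueError("velocity must be > 0")
    return velocity / design.wavelength


def _sinc_ratio(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with the x=0 limit."""
    return np.sinc(x / math.pi)


def _ba_shape(x: np.ndarray) -> np.ndarray:
    """(sin 2x - 2x) / (2 x^2), odd, with the x=0 limit 0."""
    out = np.zeros_like(x, dtype=float)
    small = np.abs(x) < 1e-6
    xs = x[~small]
    out[~small] = (np.sin(2.0 * xs) - 2.0 * xs) / (2.0 * xs**2)
    # Taylor: (2x - (2x)^3/6 - 2x) / (2x^2) = -(2/3) x
    out[small] = -(2.0 / 3.0) * x[small]
    return out


def idt_response(design: IDTDesign, electrical: SubstrateElectrical,
                 f_grid: Sequence[float], f0: float | None = None,
                 source_impedance: float = 50.0,
                 include_bidirectionality: bool = True) -> IDTResponse:
    """Cross-field admittance and conversion loss of one IDT on a frequency grid.

    ``f0`` defaults to the synchronous frequency for the substrate
    free-surface velocity; pass the guided-mode value when known.  A grid
    that does not cover f0 triggers a warning (the main lobe is then not
    sampled).
    """
    f = np.asarray(f_grid, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency grid must be positive")
    if f0 is None:
        f0 = synchronous_frequency(design, electrical.free_velocity)
    if not (f.min() <= f0 <= f.max()):
        warnings.warn(f"synchronous frequency {f0/1e6:.2f} MHz outside the grid "
                      f"[{f.min()/1e6:.2f}, {f.max()/1e6:.2f}] MHz", stacklevel=2)
    n_p = design.n_pairs
    W = design.aperture
    x = n_p * math.pi * (f - f0) / f0
    ga0 = 8.0 * electrical.k2 * f0 * electrical.cs * W * n_p**2
    ga = ga0 * _sinc_ratio(x) ** 2
    ba = ga0 * _ba_shape(x)
    c_t = n_p * electrical.cs * W
    t = conversion_transfer(ga, ba, c_t, f, source_impedance,
                            include_bidirectionality=include_bidirectionality)
    with np.errstate(divide="ignore"):
        cl = -20.0 * np.log10(np.abs(t))
    return IDTResponse(frequency=f, Ga=ga, Ba=ba, C_T=c_t,
                       conversion_loss_db=cl, f0=f0)


def conversion_transfer(ga: np.ndarray, ba: np.ndarray, c_t: float,
                        f: np.ndarray, r: float,
                        include_bidirectionality: bool = True) -> np.ndarray:
    """Complex electrical-to-acoustic conversion transfer of one IDT.

    ``|t|^2 = 2*Ga*R / ((1+Ga*R)^2 + ((Ba + omega*C_T)*R)^2)`` — the power
    delivered to the forward acoustic wave relative to the source available
    power, with the phase of the loaded admittance divider.  The optional
    3 dB bidirectionality factor accounts for the half of the power launched
    toward the wrong direction by an untuned transducer.
    """
    omega = 2.0 * math.pi * np.asarray(f, dtype=float)
    denom = (1.0 + ga * r) + 1j * (ba + omega * c_t) * r
    t = np.sqrt(2.0 * ga * r) / denom
    if include_bidirectionality:
        t = t / math.sqrt(2.0)  # 3 dB per transducer
    return t


def delay_line_s21(design: DelayLineDesign,
                   dispersion: Union[Callable[[float], complex], tuple],
                   f_grid: Sequence[float],
                   f0: float | None = None) -> TwoPortSpectrum:
    """Synthesize the two-port S21 of the delay line over a frequency grid.

    ``dispersion`` supplies the guided-mode wavenumber k_x(f): either a
    callable ``f -> complex k_x`` or a pair of arrays ``(f_samples,
    k_samples)`` interpolated linearly (real and imaginary parts separately).
    The composition is

        S21(f) = t_in(f) * t_out(f) * exp(-j * k_x(f) * L)

    so ``|S21|`` in dB is minus the sum of the two conversion losses and the
    propagation loss ``alpha(f)*L``, and the phase is ``-Re(k_x)*L`` plus the
    electrical phase of the two matching networks.  ``f0`` overrides the
    IDT synchronous frequency; the default uses the substrate free-surface
    velocity of ``design.electrical``.
    """
    f = np.asarray(f_grid, dtype=float)
    k_x = _eval_dispersion(dispersion, f)
    r = design.source_impedance
    s21 = np.exp(-1j * k_x * design.delay_path).astype(complex)
    for idt in (design.input_idt, design.output_idt):
        resp = idt_response(idt, design.electrical, f, f0=f0,
                            source_impedance=r,
                            include_bidirectionality=design.include_bidirectionality)
        s21 = s21 * conversion_transfer(resp.Ga, resp.Ba, resp.C_T, f, r,
                                        include_bidirectionality=design.include_bidirectionality)
    return TwoPortSpectrum(frequency=f, s21=s21)


def _eval_dispersion(dispersion, f: np.ndarray) -> np.ndarray:
    if callable(dispersion):
        return np.asarray([complex(dispersion(fi)) for fi in f])
    f_s, k_s = dispersion
    f_s = np.asarray(f_s, dtype=float)
    k_s = np.asarray(k_s, dtype=complex)
    return np.interp(f, f_s, k_s.real) + 1j * np.interp(f, f_s, k_s.imag)


def triple_transit(spectrum: TwoPortSpectrum, reflection: float,
                   k_x: Sequence[complex], delay_path: float) -> TwoPortSpectrum:
    """Add the triple-transit echo to a delay-line spectrum.

    The echo reflects once off each IDT (amplitude coefficient
    ``reflection`` per bounce) and travels an extra ``2*L``:

        S21' = S21 * (1 + r^2 * exp(-j * 2 * k_x * L))

    which produces an impulse-response copy at three times the main transit
    delay and frequency ripple with period ``1/(2*T_transit)``.
    """
    if not 0.0 <= reflection < 1.0:
        raise ValueError("reflection coefficient must be in [0, 1)")
    if reflection == 0.0:
        return spectrum
    k = np.asarray(k_x, dtype=complex)
    factor = 1.0 + reflection**2 * np.exp(-2j * k * delay_path)
    return TwoPortSpectrum(frequency=spectrum.frequency,
                           s21=spectrum.s21 * factor,
                           timestamp=spectrum.timestamp)
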