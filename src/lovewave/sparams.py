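"""Two-port S-parameter containers, Touchstone v1 I/O and the sensor
post-processing chain: time-domain gating, minimum-insertion-loss search and
fixed-frequency phase tracking (sensorgram assembly).

The gating follows standard VNA practice: the transmission spectrum is
taken to the time domain by an inverse DFT over the measured band (after a
Tukey taper of the band edges to control ringing), everything outside the
gate window is zeroed (rectangular gate with a short cosine roll-off), and
the result is transformed back.  For a delay line the gate keeps the main
acoustic transit and rejects electromagnetic feedthrough (near t = 0) and
the triple-transit echo (at three times the transit delay).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TwoPortSpectrum",
    "GateWindow",
    "Sensorgram",
    "read_touchstone",
    "write_touchstone",
    "time_gate",
    "extract_min_il",
    "build_sensorgram",
    "TouchstoneParseError",
]


class TouchstoneParseError(ValueError):
    """Malformed Touchstone file; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


@dataclass(frozen=True)
class TwoPortSpectrum:
    """A sampled two-port transmission spectrum.

    ``frequency`` must be strictly increasing (Hz).  Only ``s21`` is
    required; the remaining S-parameters default to 0 when written out.
    ``timestamp`` (s) orders spectra within a measurement series.
    """

    frequency: np.ndarray
    s21: np.ndarray
    s11: Optional[np.ndarray] = None
    s12: Optional[np.ndarray] = None
    s22: Optional[np.ndarray] = None
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency, dtype=float)
        s = np.asarray(self.s21, dtype=complex)
        if f.ndim != 1 or f.size < 1:
            raise ValueError("frequency grid must be a 1-D array")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if s.shape != f.shape:
            raise ValueError("s21 must match the frequency grid shape")
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "s21", s)
        for name in ("s11", "s12", "s22"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=complex)
                if v.shape != f.shape:
                    raise ValueError(f"{name} must match the frequency grid shape")
                object.__setattr__(self, name, v)

    @property
    def il_db(self) -> np.ndarray:
        """|S21| in dB (negative for a lossy two-port)."""
        with np.errstate(divide="ignore"):
            return 20.0 * np.log10(np.abs(self.s21))

    @property
    def phase_deg(self) -> np.ndarray:
        """Wrapped phase of S21 in degrees."""
        return np.degrees(np.angle(self.s21))

    def phase_at(self, f0: float) -> float:
        """Wrapped phase (degrees) at a fixed frequency, linearly interpolated."""
        self._check_in_band(f0)
        re = np.interp(f0, self.frequency, self.s21.real)
        im = np.interp(f0, self.frequency, self.s21.imag)
        return math.degrees(math.atan2(im, re))

    def _check_in_band(self, f0: float) -> None:
        if not (self.frequency[0] <= f0 <= self.frequency[-1]):
            raise ValueError(f"frequency {f0:g} Hz outside the measured band "
                             f"[{self.frequency[0]:g}, {self.frequency[-1]:g}] Hz")


@dataclass(frozen=True)
class GateWindow:
    """Time gate: keep [t_start, t_stop] seconds of the impulse response.

    ``taper`` is "cosine" (default; raised-cosine roll-off over
    ``taper_fraction`` of the gate length on each side) or "rectangular".
    """

    t_start: float = 0.2e-6
    t_stop: float = 1.9e-6
    taper: str = "cosine"
    taper_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_start < self.t_stop:
            raise ValueError("require 0 <= t_start < t_stop")
        if self.taper not in ("cosine", "rectangular"):
            raise ValueError("taper must be 'cosine' or 'rectangular'")
        if not 0.0 <= self.taper_fraction < 0.5:
            raise ValueError("taper fraction must be in [0, 0.5)")

    def weights(self, t: np.ndarray) -> np.ndarray:
        """Gate weight at each time sample."""
        w = ((t >= self.t_start) & (t <= self.t_stop)).astype(float)
        if self.taper == "cosine" and self.taper_fraction > 0.0:
            ramp = self.taper_fraction * (self.t_stop - self.t_start)
            for edge, sign in ((self.t_start, 1.0), (self.t_stop, -1.0)):
                zone = np.abs(t - edge) < ramp
                inside = sign * (t[zone] - edge)  # 0 at edge, +ramp inward
                w[zone] = 0.5 * (1.0 + np.sin(0.5 * math.pi * inside / ramp))
        return w


# ---------------------------------------------------------------------------
# Touchstone v1 I/O
# ---------------------------------------------------------------------------

_UNIT_SCALE = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}


def _pair_to_complex(a: float, b: float, fmt: str) -> complex:
    if fmt == "RI":
        return complex(a, b)
    if fmt == "MA":
        return a * cmath.exp(1j * math.radians(b))
    if fmt == "DB":
        return 10.0 ** (a / 20.0) * cmath.exp(1j * math.radians(b))
    raise ValueError(f"unknown format {fmt}")


def _complex_to_pair(z: complex, fmt: str) -> tuple[float, float]:
    if fmt == "RI":
        return z.real, z.imag
    mag = abs(z)
    ang = math.degrees(cmath.phase(z)) if mag > 0 else 0.0
    if fmt == "MA":
        return mag, ang
    if fmt == "DB":
        return (20.0 * math.log10(mag) if mag > 0 else -float("inf")), ang
    raise ValueError(f"unknown format {fmt}")


def read_touchstone(path) -> TwoPortSpectrum:
    """Read a two-port Touchstone v1 ``.s2p`` file.

    Accepts RI, MA and DB formats and Hz/kHz/MHz/GHz frequency units.
    Data rows follow the v1 two-port column order
    ``f S11 S21 S12 S22`` (two numbers per parameter).  Raises
    :class:`TouchstoneParseError` with the line number on malformed input.
    """
    path = Path(path)
    unit_scale = 1e9  # Touchstone default unit is GHz
    fmt = "MA"        # Touchstone default format
    rows: list[list[float]] = []
    option_seen = False
    timestamp: Optional[float] = None
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            comment = raw.split("!", 1)[1] if "!" in raw else ""
            if "timestamp_s" in comment and "=" in comment:
                try:
                    timestamp = float(comment.split("=", 1)[1])
                except ValueError:
                    pass
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#"):
                if option_seen:
                    raise TouchstoneParseError(path, line_no, "duplicate option line")
                option_seen = True
                tokens = line[1:].upper().split()
                i = 0
                while i < len(tokens):
                    tok = tokens[i]
                    if tok in _UNIT_SCALE:
                        unit_scale = _UNIT_SCALE[tok]
                    elif tok in ("RI", "MA", "DB"):
                        fmt = tok
                    elif tok == "S":
                        pass
                    elif tok == "R":
                        i += 1  # reference impedance value, ignored
                    else:
                        raise TouchstoneParseError(path, line_no,
                                                   f"unknown option token {tok!r}")
                    i += 1
                continue
            try:
                values = [float(v) for v in line.split()]
            except ValueError:
                raise TouchstoneParseError(path, line_no, f"non-numeric data: {line!r}")
            if len(values) != 9:
                raise TouchstoneParseError(
                    path, line_no,
                    f"expected 9 columns for a two-port row, got {len(values)}")
            rows.append(values)
    if not rows:
        raise TouchstoneParseError(path, 0, "no data rows")
    data = np.asarray(rows, dtype=float)
    f = data[:, 0] * unit_scale
    s = {}
    for idx, name in enumerate(("s11", "s21", "s12", "s22")):
        col = 1 + 2 * idx
        s[name] = np.asarray([_pair_to_complex(a, b, fmt)
                              for a, b in zip(data[:, col], data[:, col + 1])])
    return TwoPortSpectrum(frequency=f, s21=s["s21"], s11=s["s11"],
                           s12=s["s12"], s22=s["s22"], timestamp=timestamp)


def write_touchstone(spectrum: TwoPortSpectrum, path, fmt: str = "RI",
                     unit: str = "Hz") -> None:
    """Write a two-port Touchstone v1 ``.s2p`` file.

    Missing S-parameters are written as 0 except S12, which defaults to S21
    (a passive reciprocal delay line).  Values are printed with 17
    significant digits, so an RI round trip is exact to double precision.
    """
    fmt = fmt.upper()
    unit_u = unit.upper()
    if fmt not in ("RI", "MA", "DB"):
        raise ValueError("format must be RI, MA or DB")
    if unit_u not in _UNIT_SCALE:
        raise ValueError("unit must be Hz, kHz, MHz or GHz")
    scale = _UNIT_SCALE[unit_u]
    zeros = np.zeros_like(spectrum.s21)
    s11 = spectrum.s11 if spectrum.s11 is not None else zeros
    s12 = spectrum.s12 if spectrum.s12 is not None else spectrum.s21
    s22 = spectrum.s22 if spectrum.s22 is not None else zeros
    with open(path, "w") as fh:
        fh.write("! two-port S-parameters written by lovewave\n")
        if spectrum.timestamp is not None:
            fh.write(f"! timestamp_s = {spectrum.timestamp!r}\n")
        fh.write(f"# {unit} S {fmt} R 50\n")
        for i, f in enumerate(spectrum.frequency):
            fields = [f"{f / scale:.17g}"]
            for s in (s11, spectrum.s21, s12, s22):
                a, b = _complex_to_pair(complex(s[i]), fmt)
                fields += [f"{a:.17g}", f"{b:.17g}"]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Time-domain gating
# ---------------------------------------------------------------------------

def _tukey(n: int, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return np.ones(n)
    from scipy.signal.windows import tukey
    return tukey(n, alpha)


def _resample_uniform(spectrum: TwoPortSpectrum) -> TwoPortSpectrum:
    f = spectrum.frequency
    df = np.diff(f)
    if np.allclose(df, df[0], rtol=1e-9, atol=0.0):
        return spectrum
    f_u = np.linspace(f[0], f[-1], f.size)
    s_u = np.interp(f_u, f, spectrum.s21.real) + 1j * np.interp(f_u, f, spectrum.s21.imag)
    return replace(spectrum, frequency=f_u, s21=s_u, s11=None, s12=None, s22=None)


def time_gate(spectrum: TwoPortSpectrum, window: GateWindow = GateWindow(),
              band_taper: float = 0.1) -> TwoPortSpectrum:
    """Filter S21 by gating its band-limited impulse response.

    The band edges are tapered with a Tukey window (``band_taper`` of the
    band, cosine roll) before the inverse DFT, the impulse response is
    multiplied by the gate weights and transformed back.  The output band
    edges retain the Tukey taper; the central ~90% of the band is
    unaffected by it.  Non-uniform grids are resampled linearly first.

    Raises ``ValueError`` when the gate lies entirely beyond the
    unambiguous time span ``1/df`` of the sampled band.
    """
    spectrum = _resample_uniform(spectrum)
    f = spectrum.frequency
    n = f.size
    if n < 8:
        raise ValueError("too few frequency points to gate")
    df = f[1] - f[0]
    t_span = 1.0 / df
    if window.t_start >= t_span:
        raise ValueError(
            f"gate start {window.t_start:g} s beyond the resolvable span {t_span:g} s "
            f"(frequency step {df:g} Hz)")
    w_band = _tukey(n, band_taper)
    h = np.fft.ifft(spectrum.s21 * w_band)
    t = np.arange(n) / (n * df)
    gated = np.fft.fft(h * window.weights(t))
    return replace(spectrum, s21=gated, s11=None, s12=None, s22=None)


# ---------------------------------------------------------------------------
# Sensorgram extraction
# ---------------------------------------------------------------------------

def extract_min_il(spectrum: TwoPortSpectrum,
                   band: Optional[tuple[float, float]] = None) -> tuple[float, float]:
    """Frequency and level (dB) of the transmission maximum (minimum loss).

    ``band`` restricts the search to ``(f_lo, f_hi)`` Hz.  Ties break toward
    the lower frequency (argmax returns the first maximum).
    """
    f = spectrum.frequency
    mask = np.ones(f.size, dtype=bool)
    if band is not None:
        lo, hi = band
        mask = (f >= lo) & (f <= hi)
        if not mask.any():
            raise ValueError(f"band [{lo:g}, {hi:g}] Hz contains no grid points")
    il = spectrum.il_db[mask]
    idx = int(np.argmax(il))
    return float(f[mask][idx]), float(il[idx])


@dataclass(frozen=True)
class Sensorgram:
    """Time series of minimum insertion loss and phase at a fixed frequency."""

    time: np.ndarray          # s
    min_il_db: np.ndarray
    f_min_hz: np.ndarray
    phase_deg: np.ndarray     # unwrapped across the series
    f0: float

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_s": self.time, "min_il_db": self.min_il_db,
                             "f_min_hz": self.f_min_hz, "phase_deg": self.phase_deg})


def build_sensorgram(spectra: Sequence[TwoPortSpectrum], f0: float,
                     band: Optional[tuple[float, float]] = None,
                     gate: Optional[GateWindow] = GateWindow(),
                     use_gated_phase: bool = True) -> Sensorgram:
    """Per-spectrum (min IL, phase at f0) with temporal phase unwrapping.

    Spectra are gated first when ``gate`` is given (pass ``None`` for raw
    processing); ``use_gated_phase=False`` reads the phase from the raw
    spectrum while still gating for the IL search.  Phase is unwrapped
    along the series (modulo 360 degrees), matching how sensorgrams are
    plotted — excursions beyond +/-180 degrees stay continuous.
    """
    if len(spectra) == 0:
        raise ValueError("at least one spectrum required")
    times, ils, fmins, phases = [], [], [], []
    for i, spec in enumerate(spectra):
        spec._check_in_band(f0)
        gated = time_gate(spec, gate) if gate is not None else spec
        f_min, il = extract_min_il(gated, band)
        phase_src = gated if use_gated_phase else spec
        times.append(spec.timestamp if spec.timestamp is not None else float(i))
        ils.append(il)
        fmins.append(f_min)
        phases.append(phase_src.phase_at(f0))
    t = np.asarray(times, dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("spectra timestamps must be monotone non-decreasing")
    phase = np.unwrap(np.asarray(phases, dtype=float), period=360.0)
    return Sensorgram(time=t, min_il_db=np.asarray(ils), f_min_hz=np.asarray(fmins),
                      phase_deg=phase, f0=f0)
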