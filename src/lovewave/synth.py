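"""Synthetic delay-line spectra and measurement series.

Emulates what a vector network analyzer records during a liquid-exchange
experiment: one two-port spectrum every few seconds while the liquid on top
of the guiding layer steps through a schedule (air, water, glycerol
dilutions, rinse).  Each spectrum is the physical delay-line model
(dispersion + cross-field IDTs) decorated with fixture-grade imperfections:
a triple-transit echo, a constant electromagnetic feedthrough floor and
additive complex Gaussian noise.  Liquid exchanges blend exponentially with
a configurable time constant, mimicking mixing in the fluidic chamber.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .idt import DelayLineDesign, delay_line_s21, triple_transit
from .materials import GlycerolSolution, Material, MaterialKind
from .sparams import TwoPortSpectrum, write_touchstone
from .tlm import LayerStack, solve_dispersion

__all__ = ["SynthConfig", "synth_spectrum", "synth_series", "write_series"]

LiquidLike = Union[Material, GlycerolSolution]


def _as_material(liquid: LiquidLike) -> Material:
    if isinstance(liquid, GlycerolSolution):
        return liquid.as_material()
    return liquid


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of a synthetic measurement run.

    ``schedule`` lists ``(start_time_s, liquid)`` steps with monotone start
    times; ``stack`` is the guide without regard to its ``top`` (replaced per
    step).  ``noise_sigma`` is the per-point complex-noise standard
    deviation on S21 (linear units), ``feedthrough_db`` a constant parasitic
    transmission floor (use ``-inf`` for none), ``reflection`` the IDT
    reflection coefficient feeding the triple-transit echo.  ``gain_db``
    shifts the overall level, letting fixtures match a measured air
    baseline.  ``seed`` is mandatory: series are reproducible by
    construction.
    """

    device: DelayLineDesign
    stack: LayerStack
    wetted_path: Optional[float] = None   # m of liquid-covered path; None = all
    schedule: tuple = ()
    f_start: float = 10e6
    f_stop: float = 50e6
    n_points: int = 2001
    sample_interval: float = 10.0
    duration: Optional[float] = None
    mixing_tau: float = 30.0
    noise_sigma: float = 1e-4
    feedthrough_db: float = -80.0
    reflection: float = 0.2
    gain_db: float = 0.0
    n_dispersion_samples: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule", tuple(self.schedule))
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")
        if self.f_stop <= self.f_start or self.f_start <= 0:
            raise ValueError("need 0 < f_start < f_stop")
        starts = [t for t, _ in self.schedule]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("schedule start times must be strictly increasing")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def f_grid(self) -> np.ndarray:
        return np.linspace(self.f_start, self.f_stop, self.n_points)


def _dispersion_samples(config: SynthConfig, liquid: LiquidLike):
    """Path-effective k_x(f) samples across the band for one top medium.

    With a partial ``wetted_path`` the wavenumber is the path average of the
    liquid-loaded and air-loaded solutions (phase and loss accumulate over
    the wetted sensing region and the dry remainder respectively).
    """
    f_s = np.linspace(config.f_start, config.f_stop, config.n_dispersion_samples)
    stack = config.stack.with_top(_as_material(liquid))
    k_wet = np.asarray([solve_dispersion(stack, fi).wavenumber for fi in f_s])
    L = config.device.delay_path
    wet = L if config.wetted_path is None else config.wetted_path
    if wet >= L or config.stack.with_top(_as_material(liquid)).top.kind is MaterialKind.VACUUM:
        return f_s, k_wet
    dry_stack = config.stack.with_top(Material("vacuum", MaterialKind.VACUUM))
    k_dry = np.asarray([solve_dispersion(dry_stack, fi).wavenumber for fi in f_s])
    return f_s, (k_wet * wet + k_dry * (L - wet)) / L


def _clean_spectrum(config: SynthConfig, liquid: LiquidLike,
                    cache: Optional[dict] = None) -> TwoPortSpectrum:
    """Noise-free spectrum (model + echo + feedthrough + gain) for one liquid."""
    key = _as_material(liquid).name
    if cache is not None and key in cache:
        return cache[key]
    f_s, k_s = _dispersion_samples(config, liquid)
    spec = delay_line_s21(config.device, (f_s, k_s), config.f_grid)
    if config.reflection > 0.0:
        k_grid = (np.interp(config.f_grid, f_s, k_s.real)
                  + 1j * np.interp(config.f_grid, f_s, k_s.imag))
        spec = triple_transit(spec, config.reflection, k_grid, config.device.delay_path)
    s21 = spec.s21 * 10.0 ** (config.gain_db / 20.0)
    if math.isfinite(config.feedthrough_db):
        s21 = s21 + 10.0 ** (config.feedthrough_db / 20.0)
    spec = replace(spec, s21=s21)
    if cache is not None:
        cache[key] = spec
    return spec


def _add_noise(spec: TwoPortSpectrum, sigma: float, rng: np.random.Generator,
               timestamp: Optional[float]) -> TwoPortSpectrum:
    n = spec.s21.size
    noise = 0.0
    if sigma > 0.0:
        noise = sigma * (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / math.sqrt(2)
    return replace(spec, s21=spec.s21 + noise, timestamp=timestamp)


def synth_spectrum(config: SynthConfig, liquid: LiquidLike,
                   rng: Optional[np.random.Generator] = None,
                   timestamp: Optional[float] = None) -> TwoPortSpectrum:
    """One synthetic spectrum for a given top liquid.

    With ``noise_sigma=0``, ``reflection=0`` and ``feedthrough_db=-inf`` the
    output equals the bare :func:`lovewave.idt.delay_line_s21` model.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spec = _clean_spectrum(config, liquid)
    return _add_noise(spec, config.noise_sigma, rng, timestamp)


def synth_series(config: SynthConfig) -> list[TwoPortSpectrum]:
    """Timestamped spectra following the liquid schedule.

    At each sampling instant the noise-free spectrum is an exponential blend
    between the previous plateau and the current step's plateau with time
    constant ``mixing_tau`` (first-order mixing in the chamber); noise is
    then drawn from the seeded generator.  The series ends ``duration``
    seconds after t=0 (default: one mixing-settled step length past the last
    step).
    """
    if not config.schedule:
        raise ValueError("schedule must contain at least one step")
    rng = np.random.default_rng(config.seed)
    cache: dict = {}
    plateaus = [_clean_spectrum(config, liq, cache) for _, liq in config.schedule]
    starts = [t for t, _ in config.schedule]
    t_end = config.duration if config.duration is not None else (
        starts[-1] + max(5.0 * config.mixing_tau, 60.0))
    out = []
    t = starts[0]
    while t <= t_end + 1e-9:
        idx = max(i for i, t0 in enumerate(starts) if t0 <= t)
        target = plateaus[idx]
        s21 = target.s21
        if idx > 0 and config.mixing_tau > 0.0:
            prev = plateaus[idx - 1]
            blend = math.exp(-(t - starts[idx]) / config.mixing_tau)
            s21 = target.s21 + (prev.s21 - target.s21) * blend
        spec = replace(target, s21=s21)
        out.append(_add_noise(spec, config.noise_sigma, rng, timestamp=t))
        t += config.sample_interval
    return out


def write_series(series: Sequence[TwoPortSpectrum], directory,
                 prefix: str = "meas") -> Path:
    """Write a series as timestamped ``.s2p`` files plus a ``manifest.csv``.

    Returns the manifest path.  File names encode the sample index; the
    manifest maps them to timestamps, mirroring how VNA acquisitions are
    archived.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(series):
        name = f"{prefix}_{i:05d}.s2p"
        write_touchstone(spec, directory / name)
        rows.append((name, spec.timestamp if spec.timestamp is not None else float(i)))
    manifest = directory / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write("file,time_s\n")
        for name, ts in rows:
            fh.write(f"{name},{ts!r}\n")
    return manifest
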