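"""Large amplitude oscillatory shear (LAOS) waveform analysis.

Given a strain-controlled oscillation gamma(t) = gamma0 sin(omega t) and
the measured stress response, this module extracts the odd-harmonic
Fourier moduli

    sigma(t) = gamma0 * sum_k [ G'_k sin(k omega t) + G''_k cos(k omega t) ]

by projection over an integer number of steady cycles (the first cycle
is discarded as transient), builds elastic (stress vs strain) and
viscous (stress vs strain rate) Lissajous-Bowditch loops from the final
cycle, and reports standard nonlinearity measures:

* the third-harmonic intensity ratio I3/I1, and
* the strain-stiffening ratio S = (G'_L - G'_M) / G'_L, where
  G'_M = d sigma / d gamma at gamma = 0 (minimum-strain modulus) and
  G'_L = sigma / gamma at gamma = gamma0 (large-strain modulus).
  S = 0 for a linear response, S > 0 for intracycle strain stiffening.

A strain sweep of first-harmonic moduli locates the linear viscoelastic
region (LVR): the critical strain is the first amplitude at which G'
drops by more than a tolerance below its small-strain plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "OscillationWaveform",
    "HarmonicSpectrum",
    "LissajousCurve",
    "StrainSweepResult",
    "waveform_from_arrays",
    "harmonic_coefficients",
    "harmonic_decompose",
    "lissajous",
    "loop_area",
    "nonlinearity_metrics",
    "strain_sweep",
    "plot_lissajous_grid",
    "find_lvr",
]


@dataclass
class OscillationWaveform:
    """Strain-controlled oscillation record (s, -, Pa) with its metadata."""

    time: np.ndarray
    strain: np.ndarray
    stress: np.ndarray
    strain_amplitude: float
    angular_frequency: float
    n_cycles: int

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if not (self.time.shape == self.strain.shape == self.stress.shape):
            raise ValueError("time, strain and stress must have equal length")
        if self.strain_amplitude <= 0 or self.angular_frequency <= 0:
            raise ValueError("strain amplitude and frequency must be positive")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        amp = float(np.max(np.abs(self.strain)))
        if not math.isclose(amp, self.strain_amplitude, rel_tol=0.01):
            raise ValueError(
                f"strain amplitude {amp:g} inconsistent with metadata "
                f"{self.strain_amplitude:g}"
            )

    @property
    def samples_per_cycle(self) -> int:
        if self.time.size % self.n_cycles:
            raise ValueError("sample count is not an integer number of cycles")
        return self.time.size // self.n_cycles


@dataclass
class HarmonicSpectrum:
    """Per-harmonic moduli G'_k, G''_k (Pa) and intensity ratios I_k/I_1."""

    harmonics: tuple[int, ...]
    elastic: dict[int, float]
    viscous: dict[int, float]

    def intensity(self, k: int) -> float:
        """Stress amplitude of harmonic k (per unit strain amplitude)."""
        return math.hypot(self.elastic[k], self.viscous[k])

    def intensity_ratio(self, k: int) -> float:
        i1 = self.intensity(1)
        if i1 == 0:
            raise ValueError("zero first harmonic; intensity ratio undefined")
        return self.intensity(k) / i1


@dataclass
class LissajousCurve:
    """Closed elastic (strain, stress) and viscous (rate, stress) loops."""

    strain: np.ndarray
    strain_rate: np.ndarray
    stress: np.ndarray


@dataclass
class StrainSweepResult:
    """First-harmonic moduli across strain amplitudes (amplitude sweep)."""

    strain_levels: np.ndarray
    storage_modulus: np.ndarray
    loss_modulus: np.ndarray
    critical_strain: Optional[float] = None

    def __post_init__(self) -> None:
        self.strain_levels = np.asarray(self.strain_levels, dtype=float)
        self.storage_modulus = np.asarray(self.storage_modulus, dtype=float)
        self.loss_modulus = np.asarray(self.loss_modulus, dtype=float)
        if np.any(np.diff(self.strain_levels) <= 0):
            raise ValueError("strain levels must be strictly increasing")


def waveform_from_arrays(
    time: np.ndarray, strain: np.ndarray, stress: np.ndarray
) -> OscillationWaveform:
    """Rebuild an :class:`OscillationWaveform` from bare arrays.

    The fundamental frequency and strain amplitude are inferred from the
    dominant FFT bin of the strain signal; sampling must be uniform and
    span an integer number of cycles (true for generator output).
    """
    time = np.asarray(time, dtype=float)
    strain = np.asarray(strain, dtype=float)
    n = time.size
    dt = time[1] - time[0]
    if not np.allclose(np.diff(time), dt, rtol=1e-6):
        raise ValueError("non-uniform sampling")
    spec = np.fft.rfft(strain)
    k = int(np.argmax(np.abs(spec[1:])) + 1)  # skip DC
    gamma0 = 2.0 * np.abs(spec[k]) / n
    omega = 2.0 * math.pi * k / (n * dt)
    return OscillationWaveform(time, strain, stress, gamma0, omega, n_cycles=k)


# ----------------------------------------------------------------------
# harmonic analysis
# ----------------------------------------------------------------------

def _steady_samples(wave: OscillationWaveform) -> slice:
    """Samples after discarding the first (transient) cycle."""
    if wave.n_cycles < 2:
        raise ValueError("need at least 2 full cycles (first is discarded)")
    spc = wave.samples_per_cycle
    return slice(spc, spc * wave.n_cycles)


def harmonic_coefficients(wave: OscillationWaveform, k: int) -> tuple[float, float]:
    """Moduli (G'_k, G''_k) of harmonic ``k`` by discrete Fourier projection.

    Exact for band-limited signals sampled uniformly over whole cycles;
    the projection is a rectangle rule, which coincides with the
    trapezoidal rule for periodic integrands over full periods.
    """
    if k < 1:
        raise ValueError("harmonic index must be >= 1")
    spc = wave.samples_per_cycle
    if k >= spc / 2:
        raise ValueError(
            f"harmonic {k} at {spc} samples/cycle exceeds the Nyquist limit"
        )
    sel = _steady_samples(wave)
    t = wave.time[sel]
    sig = wave.stress[sel]
    phase = k * wave.angular_frequency * t
    g_e = 2.0 * float(np.mean(sig * np.sin(phase))) / wave.strain_amplitude
    g_v = 2.0 * float(np.mean(sig * np.cos(phase))) / wave.strain_amplitude
    return g_e, g_v


def harmonic_decompose(
    wave: OscillationWaveform, max_harmonic: int = 9
) -> HarmonicSpectrum:
    """Odd-harmonic spectrum of the stress response up to ``max_harmonic``."""
    if max_harmonic % 2 == 0:
        raise ValueError("max_harmonic must be odd")
    harmonics = tuple(range(1, max_harmonic + 1, 2))
    elastic: dict[int, float] = {}
    viscous: dict[int, float] = {}
    for k in harmonics:
        elastic[k], viscous[k] = harmonic_coefficients(wave, k)
    return HarmonicSpectrum(harmonics, elastic, viscous)


def lissajous(wave: OscillationWaveform) -> LissajousCurve:
    """Closed Lissajous-Bowditch loops from the final steady cycle.

    The strain-rate axis is computed analytically from the fundamental,
    gamma_dot = gamma0 * omega * cos(omega t), avoiding the noise
    amplification of numerical differentiation.
    """
    if wave.n_cycles < 2:
        raise ValueError("need at least 2 cycles")
    spc = wave.samples_per_cycle
    start = (wave.n_cycles - 1) * spc
    idx = np.arange(start, start + spc)
    idx = np.append(idx, start)  # close the loop
    t = wave.time[idx % wave.time.size]
    gamma = wave.strain[idx % wave.strain.size]
    sigma = wave.stress[idx % wave.stress.size]
    rate = wave.strain_amplitude * wave.angular_frequency * np.cos(
        wave.angular_frequency * wave.time[idx % wave.time.size]
    )
    return LissajousCurve(strain=gamma, strain_rate=rate, stress=sigma)


def loop_area(x: np.ndarray, y: np.ndarray) -> float:
    """Unsigned enclosed area of a closed loop (shoelace formula)."""
    return float(abs(0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])))


def nonlinearity_metrics(
    spectrum: HarmonicSpectrum, wave: OscillationWaveform
) -> tuple[float, float]:
    """Third-harmonic intensity ratio and strain-stiffening ratio S.

    From the odd-harmonic elastic moduli, the minimum- and large-strain
    elastic moduli are G'_M = sum_k k G'_k and
    G'_L = sum_k G'_k sin(k pi / 2); S = (G'_L - G'_M) / G'_L.
    """
    i3_over_i1 = spectrum.intensity_ratio(3) if 3 in spectrum.elastic else 0.0
    g_m = sum(k * spectrum.elastic[k] for k in spectrum.harmonics)
    g_l = sum(
        spectrum.elastic[k] * math.sin(k * math.pi / 2.0) for k in spectrum.harmonics
    )
    if g_l == 0:
        raise ValueError("zero large-strain modulus; S undefined")
    s_ratio = (g_l - g_m) / g_l
    return i3_over_i1, s_ratio


# ----------------------------------------------------------------------
# strain sweeps / LVR
# ----------------------------------------------------------------------

def strain_sweep(
    waveforms: Sequence[OscillationWaveform],
) -> StrainSweepResult:
    """First-harmonic moduli at each amplitude of a strain sweep.

    Waveforms must be ordered by increasing strain amplitude.
    """
    levels, gp, gpp = [], [], []
    for wave in waveforms:
        e1, v1 = harmonic_coefficients(wave, 1)
        levels.append(wave.strain_amplitude)
        gp.append(e1)
        gpp.append(v1)
    return StrainSweepResult(np.array(levels), np.array(gp), np.array(gpp))


def plot_lissajous_grid(
    loops: dict[tuple[float, float], LissajousCurve], path, viscous: bool = False
) -> None:
    """Figure of Lissajous loops on a (strain amplitude x frequency) grid.

    ``loops`` maps (strain_amplitude, frequency_hz) to the loop to draw;
    the elastic view plots stress vs strain, the viscous view stress vs
    strain rate.  Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    amplitudes = sorted({k[0] for k in loops})
    freqs = sorted({k[1] for k in loops})
    fig, axes = plt.subplots(
        len(freqs), len(amplitudes),
        figsize=(2.2 * len(amplitudes), 2.2 * len(freqs)),
        squeeze=False,
    )
    for i, f in enumerate(freqs):
        for j, a in enumerate(amplitudes):
            ax = axes[i][j]
            loop = loops.get((a, f))
            if loop is not None:
                x = loop.strain_rate if viscous else loop.strain
                ax.plot(x, loop.stress, lw=1.0)
            ax.set_title(f"{100 * a:g}% / {f:g} Hz", fontsize=8)
            ax.tick_params(labelsize=6)
    fig.supxlabel("strain rate (1/s)" if viscous else "strain")
    fig.supylabel("stress (Pa)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def find_lvr(sweep: StrainSweepResult, tolerance: float = 0.10) -> Optional[float]:
    """Critical strain ending the linear viscoelastic region.

    The plateau storage modulus is the median of the first three sweep
    levels; the critical strain is the first level where G' falls below
    ``(1 - tolerance)`` of the plateau.  Returns ``None`` (absent) when
    no level qualifies.
    """
    if sweep.strain_levels.size < 5:
        raise ValueError("need >= 5 sweep points")
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    plateau = float(np.median(sweep.storage_modulus[:3]))
    below = np.nonzero(sweep.storage_modulus < (1.0 - tolerance) * plateau)[0]
    if below.size == 0:
        return None
    return float(sweep.strain_levels[below[0]])
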