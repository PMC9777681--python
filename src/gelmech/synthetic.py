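"""Synthetic test data with known ground truth.

Stands in for the three lab instruments the analysis pipeline normally
consumes data from:

* a texture analyzer producing force-displacement records for ring
  tensile and uniaxial compression runs,
* a rheometer producing strain-controlled oscillation waveforms with
  configurable odd-harmonic distortion, and
* a camera producing speckle image pairs under a known deformation.

The ring-tensile forward model is, by construction, exactly the
elastic + Johnson-Cook law the analysis pipeline fits: elastic response
up to yield, hardening flow beyond, termination when the accumulated
damage reaches 1, and stress converted to pin force through the ring
geometry.  This makes recovery tests well-posed closures rather than
independent physics; the methods note spells out what that does and
does not demonstrate.

Defaults mirror the study conditions: crosshead speed 1 mm/s, 50
samples/s (matching 50 fps video), compression to 80% strain,
oscillation frequencies of 1 and 10 Hz with strain amplitudes from the
linear region to 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy import ndimage

from .mechanics import (
    CompressionGeometry,
    ForceDisplacementRecord,
    RingGeometry,
)
from .johnson_cook import (
    JohnsonCookMaterial,
    UNIAXIAL_TRIAXIALITY,
    _return_map,
    jc_fracture_strain,
    jc_stress,
)
from .laos import OscillationWaveform

__all__ = [
    "GeneratorSpec",
    "CompressionLaw",
    "WaveformSpec",
    "SpeckleSpec",
    "AffineDeformation",
    "SpeckleImagePair",
    "generate_ring_tensile_record",
    "generate_compression_record",
    "generate_laos_waveform",
    "generate_speckle_pair",
    "calibrate_ring_material",
    "nominal_ring_strain_rate",
]


# ----------------------------------------------------------------------
# force-displacement generators
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CompressionLaw:
    """Convex strain-hardening compression response with a failure drop.

    sigma(eps) = k1*eps + k2*eps**exponent up to ``failure_strain``,
    with k1, k2 set so the linear term carries ``linear_share`` of the
    configured ``peak_stress`` at failure; beyond failure the stress
    drops by ``drop_fraction`` and stays flat (fragmented specimen).
    """

    peak_stress: float
    failure_strain: float
    exponent: float = 2.0
    drop_fraction: float = 0.6
    linear_share: float = 0.5

    def __post_init__(self) -> None:
        if self.peak_stress <= 0:
            raise ValueError("peak_stress must be positive (all-zero record rejected)")
        if not 0 < self.failure_strain < 0.8:
            raise ValueError("failure strain must lie in (0, 0.8)")
        if self.exponent <= 1:
            raise ValueError("exponent must exceed 1 (convex hardening)")
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in (0, 1)")
        if not 0 <= self.linear_share <= 1:
            raise ValueError("linear_share must be in [0, 1]")

    def stress(self, strain: np.ndarray) -> np.ndarray:
        k1 = self.linear_share * self.peak_stress / self.failure_strain
        k2 = (1.0 - self.linear_share) * self.peak_stress / (
            self.failure_strain**self.exponent
        )
        sig = k1 * strain + k2 * strain**self.exponent
        peak = k1 * self.failure_strain + k2 * self.failure_strain**self.exponent
        return np.where(
            strain <= self.failure_strain, sig, (1.0 - self.drop_fraction) * peak
        )


@dataclass(frozen=True)
class GeneratorSpec:
    """Instrument emulation settings for force-displacement records.

    ``crosshead_speed`` in m/s (default 1 mm/s), ``sample_rate`` in Hz
    (default 50, matching the video frame rate), ``noise_sd`` as a
    fraction of the peak force.
    """

    material: JohnsonCookMaterial
    geometry: Union[RingGeometry, CompressionGeometry]
    crosshead_speed: float = 1.0e-3
    sample_rate: float = 50.0
    noise_sd: float = 0.0
    seed: int = 0
    compression_law: Optional[CompressionLaw] = None

    def __post_init__(self) -> None:
        if self.crosshead_speed <= 0:
            raise ValueError("crosshead_speed must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def nominal_ring_strain_rate(spec: GeneratorSpec) -> float:
    """Engineering ring strain rate 2*v/C0 implied by the crosshead speed."""
    geom = spec.geometry
    if not isinstance(geom, RingGeometry):
        raise TypeError("ring strain rate requires a RingGeometry")
    return 2.0 * spec.crosshead_speed / geom.initial_circumference


def _add_force_noise(
    force: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Gaussian noise scaled to the peak force; sample 0 stays 0."""
    if noise_sd == 0:
        return force
    eta = rng.standard_normal(force.size)
    eta[0] = 0.0
    return force + noise_sd * float(np.max(force)) * eta


def generate_ring_tensile_record(
    spec: GeneratorSpec, max_engineering_strain: float = 1.5
) -> ForceDisplacementRecord:
    """Forward-model a ring tensile run to failure.

    The true-strain history implied by the constant crosshead speed is
    integrated through the elastic/Johnson-Cook material point (return
    mapping onto the hardening curve, trapezoidal damage accumulation at
    uniaxial triaxiality); the run terminates at the first sample with
    damage >= 1.  True stress maps back to pin force via the ring
    geometry: F = sigma_r * w * D_i = sigma_true * w * C0 / pi.
    """
    geom = spec.geometry
    if not isinstance(geom, RingGeometry):
        raise TypeError("ring tensile generation requires a RingGeometry")
    mat = spec.material
    rate = nominal_ring_strain_rate(spec)
    # validates the damage parameters up front (finite fracture strain)
    eps_f = jc_fracture_strain(mat, UNIAXIAL_TRIAXIALITY, rate)

    dt = 1.0 / spec.sample_rate
    dd = spec.crosshead_speed * dt
    c0 = geom.initial_circumference
    n_max = int(math.ceil(max_engineering_strain * c0 / (2.0 * dd)))

    time = [0.0]
    disp = [0.0]
    sigma_true = [0.0]
    eps_p = 0.0
    damage = 0.0
    inv_f = 1.0 / eps_f
    failed = False
    for k in range(1, n_max + 1):
        ds = k * dd
        eps_r = 2.0 * ds / c0
        eps_t = math.log1p(eps_r)
        trial = mat.youngs_modulus * (eps_t - eps_p)
        if trial > jc_stress(mat, eps_p, rate):
            eps_p_new = _return_map(mat, eps_t, eps_p, rate)
            sig = mat.youngs_modulus * (eps_t - eps_p_new)
            damage += inv_f * (eps_p_new - eps_p)  # eps_f constant on this path
            eps_p = eps_p_new
        else:
            sig = trial
        time.append(k * dt)
        disp.append(ds)
        sigma_true.append(sig)
        if damage >= 1.0:
            failed = True
            break
    if not failed:
        raise RuntimeError(
            "material never reached damage 1 within the elongation range; "
            f"check damage parameters (d1={mat.d1}, d2={mat.d2}, "
            f"d3={mat.d3}, d4={mat.d4})"
        )

    force = np.asarray(sigma_true) * geom.width * c0 / math.pi
    rng = np.random.default_rng(spec.seed)
    force = _add_force_noise(force, spec.noise_sd, rng)
    return ForceDisplacementRecord(
        np.asarray(time), np.asarray(disp), force, mode="tension"
    )


def generate_compression_record(spec: GeneratorSpec) -> ForceDisplacementRecord:
    """Emulate a uniaxial compression run to 80% engineering strain.

    Uses the convex two-term stress law of :class:`CompressionLaw`
    (strain hardening, then a sharp failure drop), converted to force
    through the constant contact area.
    """
    geom = spec.geometry
    if not isinstance(geom, CompressionGeometry):
        raise TypeError("compression generation requires a CompressionGeometry")
    if spec.compression_law is None:
        raise ValueError("GeneratorSpec.compression_law is required for compression")
    law = spec.compression_law

    dt = 1.0 / spec.sample_rate
    dd = spec.crosshead_speed * dt
    max_disp = 0.8 * geom.initial_length
    n = int(math.floor(max_disp / dd))
    disp = np.arange(n + 1) * dd
    disp[-1] = min(disp[-1], max_disp)
    strain = disp / geom.initial_length
    stress = law.stress(strain)
    force = stress * geom.contact_area
    rng = np.random.default_rng(spec.seed)
    force = _add_force_noise(force, spec.noise_sd, rng)
    return ForceDisplacementRecord(
        np.arange(n + 1) * dt, disp, force, mode="compression"
    )


def calibrate_ring_material(
    failure_stress: float,
    failure_strain: float,
    loading_rate: float,
    plastic_fraction: float = 0.4,
    yield_fraction: float = 0.6,
    hardening_exponent: float = 0.5,
    rate_sensitivity: float = 0.01,
    ref_rate: float = 1.0,
    poisson: float = 0.48,
) -> JohnsonCookMaterial:
    """Construct a material whose ring-tensile run fails at a target point.

    Targets are the *engineering* failure stress (Pa) and strain of the
    ring test.  They are converted to true measures; the failure true
    strain is split into a plastic part (``plastic_fraction``) and an
    elastic part that fixes E; yield is placed at ``yield_fraction`` of
    the failure true stress; B follows from requiring the flow stress to
    pass exactly through the failure point at ``loading_rate``; damage
    is a constant fracture strain equal to the plastic part.
    """
    if not 0 < plastic_fraction < 1:
        raise ValueError("plastic_fraction must be in (0, 1)")
    if not 0 < yield_fraction < 1:
        raise ValueError("yield_fraction must be in (0, 1)")
    sigma_t = failure_stress * (1.0 + failure_strain)
    eps_t = math.log1p(failure_strain)
    eps_p_f = plastic_fraction * eps_t
    youngs = sigma_t / (eps_t - eps_p_f)
    bracket = 1.0 + rate_sensitivity * math.log(loading_rate / ref_rate)
    yield_a = yield_fraction * sigma_t / bracket
    hardening_b = (sigma_t / bracket - yield_a) / eps_p_f**hardening_exponent
    return JohnsonCookMaterial(
        youngs_modulus=youngs,
        poisson=poisson,
        yield_strength=yield_a,
        hardening_modulus=hardening_b,
        hardening_exponent=hardening_exponent,
        rate_sensitivity=rate_sensitivity,
        ref_rate=ref_rate,
        d1=eps_p_f,
    )


# ----------------------------------------------------------------------
# LAOS waveform generator
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformSpec:
    """Oscillation signal model parameters.

    The stress response is

        sigma(t) = gamma0 * [ G' sin(wt) + G'' cos(wt)
                              + e3 sin(3wt) + v3 cos(3wt) ] + noise

    with the third-harmonic coefficients ``third_harmonic_elastic``
    (e3) and ``third_harmonic_viscous`` (v3) in Pa.  A negative e3
    corresponds to intracycle strain stiffening under the standard
    large/minimum-strain modulus convention.
    """

    storage_modulus: float
    loss_modulus: float
    third_harmonic_elastic: float = 0.0
    third_harmonic_viscous: float = 0.0
    strain_amplitude: float = 0.01
    frequency: float = 1.0
    n_cycles: int = 4
    samples_per_cycle: int = 256
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strain_amplitude <= 0:
            raise ValueError("strain_amplitude must be positive")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.samples_per_cycle < 16:
            raise ValueError("samples_per_cycle must be >= 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_laos_waveform(spec: WaveformSpec) -> OscillationWaveform:
    """Strain-controlled oscillation with configurable third-harmonic content."""
    omega = 2.0 * math.pi * spec.frequency
    n = spec.n_cycles * spec.samples_per_cycle
    t = np.arange(n) / (spec.samples_per_cycle * spec.frequency)
    wt = omega * t
    gamma = spec.strain_amplitude * np.sin(wt)
    sigma = spec.strain_amplitude * (
        spec.storage_modulus * np.sin(wt)
        + spec.loss_modulus * np.cos(wt)
        + spec.third_harmonic_elastic * np.sin(3.0 * wt)
        + spec.third_harmonic_viscous * np.cos(3.0 * wt)
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = sigma + spec.noise_sd * rng.standard_normal(n)
    return OscillationWaveform(
        time=t,
        strain=gamma,
        stress=sigma,
        strain_amplitude=spec.strain_amplitude,
        angular_frequency=omega,
        n_cycles=spec.n_cycles,
    )


# ----------------------------------------------------------------------
# speckle image generator
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class AffineDeformation:
    """Material deformation x' = F x + t in image (x, y) coordinates."""

    gradient: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    translation: tuple[float, float] = (0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.gradient, dtype=float)

    @property
    def shift(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    def displacement(self, x: np.ndarray, y: np.ndarray):
        """Forward displacement (u, v) at reference positions (x, y)."""
        f = self.matrix
        u = (f[0, 0] - 1.0) * x + f[0, 1] * y + self.shift[0]
        v = f[1, 0] * x + (f[1, 1] - 1.0) * y + self.shift[1]
        return u, v

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.matrix, np.eye(2)) and np.allclose(self.shift, 0.0)


@dataclass(frozen=True)
class SpeckleSpec:
    """Speckle pattern and deformation settings for a DIC image pair."""

    image_shape: tuple[int, int] = (256, 256)  # (rows, cols)
    speckle_density: float = 0.01  # speckles per pixel^2
    speckle_radius: float = 3.0  # Gaussian sigma, pixels
    deformation: AffineDeformation = field(default_factory=AffineDeformation)
    intensity_noise_sd: float = 0.0  # gray levels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_shape[0] < 64 or self.image_shape[1] < 64:
            raise ValueError("image_shape must be at least 64x64")
        if self.speckle_density <= 0 or self.speckle_radius <= 0:
            raise ValueError("speckle density and radius must be positive")
        if self.intensity_noise_sd < 0:
            raise ValueError("intensity_noise_sd must be non-negative")


@dataclass
class SpeckleImagePair:
    """Reference/deformed 8-bit images plus the ground-truth deformation."""

    reference: np.ndarray
    deformed: np.ndarray
    deformation: AffineDeformation

    def displacement_truth(self, x: np.ndarray, y: np.ndarray):
        """Ground-truth displacement (u, v) at reference pixel positions."""
        return self.deformation.displacement(np.asarray(x, float), np.asarray(y, float))


def _render_speckles(
    shape: tuple[int, int],
    centers: np.ndarray,
    amplitudes: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Light background with dark Gaussian speckles, clipped to 8 bits."""
    img = np.full(shape, 255.0)
    half = int(math.ceil(4.0 * sigma))
    rows, cols = shape
    for (cx, cy), amp in zip(centers, amplitudes):
        x0 = max(int(math.floor(cx)) - half, 0)
        x1 = min(int(math.ceil(cx)) + half + 1, cols)
        y0 = max(int(math.floor(cy)) - half, 0)
        y1 = min(int(math.ceil(cy)) + half + 1, rows)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)[:, None]
        img[y0:y1, x0:x1] -= amp * np.exp(
            -((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * sigma**2)
        )
    return np.clip(img, 0.0, 255.0)


def generate_speckle_pair(spec: SpeckleSpec) -> SpeckleImagePair:
    """Reference speckle image and its warp under the specified deformation.

    The reference is a light background with randomly placed dark
    Gaussian speckles.  The deformed image is the reference warped by
    the affine field with cubic-spline sub-pixel interpolation (exact
    identity deformations skip the warp so the pair is bitwise equal).
    Raises if the deformation would push speckle content out of frame.
    """
    rows, cols = spec.image_shape
    rng = np.random.default_rng(spec.seed)
    n_speckles = max(int(round(spec.speckle_density * rows * cols)), 1)
    margin = 2.0 * spec.speckle_radius
    centers = np.column_stack(
        [
            rng.uniform(margin, cols - margin, n_speckles),
            rng.uniform(margin, rows - margin, n_speckles),
        ]
    )
    amplitudes = rng.uniform(120.0, 230.0, n_speckles)

    deform = spec.deformation
    moved = (deform.matrix @ centers.T).T + deform.shift
    if (
        np.any(moved[:, 0] < 0)
        or np.any(moved[:, 0] > cols - 1)
        or np.any(moved[:, 1] < 0)
        or np.any(moved[:, 1] > rows - 1)
    ):
        raise ValueError("deformation pushes speckle content out of frame")

    reference = _render_speckles(spec.image_shape, centers, amplitudes, spec.speckle_radius)

    if deform.is_identity:
        deformed = reference.copy()
    else:
        # inverse map: reference position of every deformed-image pixel
        yy, xx = np.mgrid[0:rows, 0:cols]
        inv = np.linalg.inv(deform.matrix)
        src = np.tensordot(
            inv,
            np.stack([xx - deform.shift[0], yy - deform.shift[1]]),
            axes=([1], [0]),
        )
        deformed = ndimage.map_coordinates(
            reference, [src[1], src[0]], order=3, mode="constant", cval=255.0
        )
        deformed = np.clip(deformed, 0.0, 255.0)

    if spec.intensity_noise_sd > 0:
        reference = np.clip(
            reference + spec.intensity_noise_sd * rng.standard_normal(reference.shape),
            0.0,
            255.0,
        )
        deformed = np.clip(
            deformed + spec.intensity_noise_sd * rng.standard_normal(deformed.shape),
            0.0,
            255.0,
        )

    return SpeckleImagePair(
        reference=reference.astype(np.uint8),
        deformed=deformed.astype(np.uint8),
        deformation=deform,
    )
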