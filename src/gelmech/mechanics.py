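"""Stress-strain analysis for gel compression and ring-tensile tests.

Converts raw force-displacement records into engineering and true
stress-strain curves, extracts Young's modulus from the linear region,
splits total strain into elastic and plastic parts, and locates the
failure point.

The ring tensile test stretches an oval ring specimen between two pins.
The wall stress follows from Laplace's law for a thin ring under
circumferential tension:

    sigma_r = F / (w * D_i)

where ``F`` is the measured force, ``w`` the specimen width and ``D_i``
the instantaneous inside diameter.  The inside circumference grows by
twice the pin elongation (both straight segments lengthen),

    C_i = C_0 + 2 * ds,        D_i = C_i / pi,

and the engineering ring strain is the relative circumference change
``eps_r = (C_i - C_0) / C_0``.  Large-deformation (true) measures are
``sigma_true = sigma_r (1 + eps_r)`` and ``eps_true = ln(1 + eps_r)``.

All quantities are SI internally (m, N, Pa); file I/O converts at the
boundary (see :mod:`gelmech.pipeline`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "RingGeometry",
    "CompressionGeometry",
    "ForceDisplacementRecord",
    "StressStrainCurve",
    "StrainDecomposition",
    "FailurePoint",
    "compression_curve",
    "ring_circumference",
    "ring_diameter",
    "ring_stress",
    "ring_strain",
    "ring_curve",
    "to_true",
    "to_engineering",
    "youngs_modulus",
    "decompose_strain",
    "detect_failure",
    "shear_modulus",
]


# ----------------------------------------------------------------------
# geometry and curve containers
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RingGeometry:
    """Ring specimen geometry (SI units, metres).

    Parameters
    ----------
    pin_diameter : float
        Diameter ``d`` of each loading pin.
    initial_circumference : float
        Initial inside circumference ``C0`` of the ring.
    width : float
        Specimen width ``w`` (in-plane, perpendicular to loading).
    thickness : float
        Ring wall thickness ``Tr`` (out-of-plane).
    """

    pin_diameter: float
    initial_circumference: float
    width: float
    thickness: float

    def __post_init__(self) -> None:
        for name in ("pin_diameter", "initial_circumference", "width", "thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RingGeometry.{name} must be positive")
        if self.initial_circumference < math.pi * self.pin_diameter:
            raise ValueError(
                "initial_circumference must be at least pi * pin_diameter "
                "(the ring must fit around the pins)"
            )


@dataclass(frozen=True)
class CompressionGeometry:
    """Cylindrical compression specimen: contact area (m^2) and height (m)."""

    contact_area: float
    initial_length: float

    def __post_init__(self) -> None:
        if self.contact_area <= 0 or self.initial_length <= 0:
            raise ValueError("contact_area and initial_length must be positive")


@dataclass
class ForceDisplacementRecord:
    """Sampled time / crosshead displacement / force series (s, m, N)."""

    time: np.ndarray
    displacement: np.ndarray
    force: np.ndarray
    mode: str = "tension"  # "tension" | "compression"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (self.time.shape == self.displacement.shape == self.force.shape):
            raise ValueError("time, displacement and force must have equal length")
        if self.mode not in ("tension", "compression"):
            raise ValueError(f"unknown record mode {self.mode!r}")

    def __len__(self) -> int:
        return self.time.size


CURVE_KINDS = ("engineering_compression", "engineering_ring", "true")


@dataclass
class StressStrainCurve:
    """Paired strain / stress arrays with a kind tag and optional failure index."""

    strain: np.ndarray
    stress: np.ndarray
    kind: str
    failure_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape:
            raise ValueError("strain and stress must have equal length")
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if np.any(np.diff(self.strain) < 0):
            raise ValueError("strain must be non-decreasing")
        if self.failure_index is not None and not (
            0 <= self.failure_index < self.strain.size
        ):
            raise ValueError("failure_index out of bounds")

    def __len__(self) -> int:
        return self.strain.size


@dataclass
class StrainDecomposition:
    """Elastic/plastic strain split of a true-strain curve.

    ``elastic + plastic == total`` holds pointwise by construction;
    ``yield_index`` marks the first sample whose stress deviates from the
    linear-elastic line by more than the detection tolerance.
    """

    youngs_modulus: float
    elastic_strain: np.ndarray
    plastic_strain: np.ndarray
    yield_index: int


@dataclass(frozen=True)
class FailurePoint:
    """Failure stress/strain and sample index; ``censored`` marks curves
    that never showed a qualifying stress drop (no failure observed)."""

    stress: float
    strain: float
    index: int
    censored: bool = False


# ----------------------------------------------------------------------
# engineering curves
# ----------------------------------------------------------------------

def compression_curve(
    record: ForceDisplacementRecord, geom: CompressionGeometry
) -> StressStrainCurve:
    """Engineering compression curve: sigma = F/A, eps = dL/L."""
    if record.mode != "compression":
        raise ValueError("record is not a compression run")
    if np.any(record.displacement > geom.initial_length):
        raise ValueError("displacement exceeds specimen length (over-compression)")
    stress = record.force / geom.contact_area
    strain = record.displacement / geom.initial_length
    return StressStrainCurve(strain, stress, "engineering_compression")


def ring_circumference(geom: RingGeometry, elongation: float | np.ndarray):
    """Instantaneous inside circumference ``C_i = C0 + 2 * ds``.

    Both straight segments of the oval ring lengthen by the pin travel,
    so the circumference grows at twice the crosshead displacement.
    """
    ds = np.asarray(elongation, dtype=float)
    if np.any(ds < 0):
        raise ValueError("elongation must be non-negative")
    out = geom.initial_circumference + 2.0 * ds
    return float(out) if np.isscalar(elongation) else out


def ring_diameter(circumference: float | np.ndarray):
    """Equivalent inside diameter ``D_i = C_i / pi``."""
    ci = np.asarray(circumference, dtype=float)
    if np.any(ci <= 0):
        raise ValueError("circumference must be positive")
    out = ci / math.pi
    return float(out) if np.isscalar(circumference) else out


def ring_stress(force: float | np.ndarray, geom: RingGeometry, diameter):
    """Ring wall stress ``sigma_r = F / (w * D_i)`` (Laplace's law)."""
    f = np.asarray(force, dtype=float)
    di = np.asarray(diameter, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    if geom.width <= 0 or np.any(di <= 0):
        raise ValueError("width and diameter must be positive")
    out = f / (geom.width * di)
    return float(out) if (np.isscalar(force) and np.isscalar(diameter)) else out


def ring_strain(circumference, initial_circumference: float):
    """Engineering ring strain ``(C_i - C0) / C0``."""
    ci = np.asarray(circumference, dtype=float)
    if initial_circumference <= 0:
        raise ValueError("initial circumference must be positive")
    if np.any(ci < initial_circumference * (1 - 1e-12)):
        raise ValueError("instantaneous circumference smaller than initial")
    out = (ci - initial_circumference) / initial_circumference
    return float(out) if np.isscalar(circumference) else out


def ring_curve(
    record: ForceDisplacementRecord, geom: RingGeometry
) -> StressStrainCurve:
    """Full engineering ring-tensile curve from a force-displacement record."""
    if record.mode != "tension":
        raise ValueError("record is not a tensile run")
    ci = ring_circumference(geom, record.displacement)
    di = ring_diameter(ci)
    stress = ring_stress(record.force, geom, di)
    strain = ring_strain(ci, geom.initial_circumference)
    return StressStrainCurve(strain, stress, "engineering_ring")


# ----------------------------------------------------------------------
# true stress / strain
# ----------------------------------------------------------------------

def to_true(curve: StressStrainCurve) -> StressStrainCurve:
    """Convert an engineering ring curve to true stress and strain.

    sigma_true = sigma_r (1 + eps_r);  eps_true = ln(1 + eps_r).
    """
    if curve.kind != "engineering_ring":
        raise ValueError("to_true expects an engineering_ring curve")
    if np.any(curve.strain <= -1):
        raise ValueError("engineering strain must exceed -1")
    stress = curve.stress * (1.0 + curve.strain)
    strain = np.log1p(curve.strain)
    return StressStrainCurve(strain, stress, "true", failure_index=curve.failure_index)


def to_engineering(curve: StressStrainCurve) -> StressStrainCurve:
    """Inverse of :func:`to_true` (true -> engineering ring)."""
    if curve.kind != "true":
        raise ValueError("to_engineering expects a true curve")
    eps = np.expm1(curve.strain)
    stress = curve.stress / (1.0 + eps)
    return StressStrainCurve(
        eps, stress, "engineering_ring", failure_index=curve.failure_index
    )


# ----------------------------------------------------------------------
# modulus, elastic/plastic split, failure
# ----------------------------------------------------------------------

def youngs_modulus(
    curve: StressStrainCurve, linear_fraction: float = 0.4
) -> float:
    """Origin-anchored least-squares slope of the initial linear region.

    The region is the first ``linear_fraction`` of the pre-failure strain
    range (failure taken from ``curve.failure_index`` when present, else
    the stress maximum).  At least 5 samples are required.
    """
    if not 0 < linear_fraction <= 1:
        raise ValueError("linear_fraction must be in (0, 1]")
    end = curve.failure_index
    if end is None:
        end = int(np.argmax(curve.stress))
    strain_max = curve.strain[end] * linear_fraction
    mask = (curve.strain <= strain_max) & (np.arange(len(curve)) <= end)
    if mask.sum() < 5:
        raise ValueError(
            f"only {int(mask.sum())} samples in the linear region; need >= 5"
        )
    eps = curve.strain[mask]
    sig = curve.stress[mask]
    denom = float(np.dot(eps, eps))
    if denom == 0:
        raise ValueError("degenerate linear region (zero strain)")
    return float(np.dot(eps, sig) / denom)


def decompose_strain(
    curve: StressStrainCurve, youngs_modulus_value: float, yield_tol: float = 0.02
) -> StrainDecomposition:
    """Split total true strain into elastic (sigma/E) and plastic parts.

    The yield index is the first sample where stress falls below the
    elastic line ``E * eps`` by more than ``yield_tol`` relative.
    """
    if curve.kind != "true":
        raise ValueError("decompose_strain expects a true curve")
    if youngs_modulus_value <= 0:
        raise ValueError("Young's modulus must be positive")
    total = curve.strain
    elastic = np.minimum(curve.stress / youngs_modulus_value, total)
    plastic = total - elastic
    linear = youngs_modulus_value * total
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_dev = np.where(linear > 0, np.abs(curve.stress - linear) / linear, 0.0)
    beyond = np.nonzero(rel_dev > yield_tol)[0]
    yield_index = int(beyond[0]) if beyond.size else len(curve)
    return StrainDecomposition(
        youngs_modulus=float(youngs_modulus_value),
        elastic_strain=elastic,
        plastic_strain=plastic,
        yield_index=yield_index,
    )


def detect_failure(
    curve: StressStrainCurve, drop_fraction: float = 0.5
) -> FailurePoint:
    """Locate specimen failure on a stress-strain curve.

    Failure is the first local stress maximum followed (anywhere later)
    by a drop exceeding ``drop_fraction`` of that peak — a complete
    separation rather than a gradual fracture plateau.  If no peak
    qualifies, the global maximum is returned with ``censored=True``.
    """
    if len(curve) < 3:
        raise ValueError("need at least 3 samples to detect failure")
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must be in (0, 1)")
    sig = curve.stress
    # running minimum of the future suffix: min stress at or after each sample
    future_min = np.minimum.accumulate(sig[::-1])[::-1]
    for i in range(1, len(sig) - 1):
        if sig[i] >= sig[i - 1] and sig[i] > sig[i + 1]:  # local max
            if future_min[i + 1] < (1.0 - drop_fraction) * sig[i]:
                return FailurePoint(float(sig[i]), float(curve.strain[i]), i)
    j = int(np.argmax(sig))
    return FailurePoint(float(sig[j]), float(curve.strain[j]), j, censored=True)


def shear_modulus(youngs_modulus_value: float, poisson: float) -> float:
    """Isotropic shear modulus ``G = E / (2 (1 + nu))``."""
    if youngs_modulus_value <= 0:
        raise ValueError("Young's modulus must be positive")
    if not -1 < poisson <= 0.5:
        raise ValueError("Poisson's ratio must lie in (-1, 0.5]")
    return youngs_modulus_value / (2.0 * (1.0 + poisson))
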