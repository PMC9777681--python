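"""Johnson-Cook plasticity and ductile-damage model for gel networks.

The flow stress of the hardening law is

    sigma = (A + B * eps_p**n) * (1 + C * ln(rate / rate0))

with initial yield strength ``A``, hardening modulus ``B``, hardening
exponent ``n``, rate-sensitivity ``C`` and reference plastic strain rate
``rate0``.  Thermal softening is disabled: frictional heating is
negligible for gels tested at room temperature, so the temperature
bracket is identically 1 and carries no parameters.

Failure follows the companion damage model.  The fracture strain at the
current stress state is

    eps_f = [d1 + d2 * exp(-d3 * eta)] * [1 + d4 * ln(rate / rate0)]

with stress triaxiality ``eta = sigma_m / sigma_eq`` (1/3 in uniaxial
tension).  Damage accumulates as D = integral of d eps_p / eps_f and the
material fails when D reaches 1.  ``d5`` belongs to the (disabled)
temperature factor; it is stored for completeness but inert.

A strain-driven material-point simulator integrates the model along a
constant-rate tensile program: elastic predictor, return mapping onto
the hardening curve, damage update, stop at failure.  It stands in for
full 3-D explicit-dynamics finite elements at desk scale, which is
adequate because the ring-tensile strain field is essentially
homogeneous until failure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .mechanics import StressStrainCurve

__all__ = [
    "JohnsonCookMaterial",
    "LoadingProgram",
    "DamageState",
    "HardeningFit",
    "jc_stress",
    "jc_fracture_strain",
    "accumulate_damage",
    "damage_integral",
    "fit_hardening",
    "fit_damage",
    "simulate_tensile",
    "UNIAXIAL_TRIAXIALITY",
]

#: Stress triaxiality sigma_m / sigma_eq of uniaxial tension.
UNIAXIAL_TRIAXIALITY = 1.0 / 3.0

#: Floor applied to the rate bracket (fraction of A) when driven below zero
#: by deeply sub-reference rates; such rates are outside the model's
#: intended regime and trigger a warning.
RATE_BRACKET_FLOOR = 0.01


@dataclass(frozen=True)
class JohnsonCookMaterial:
    """Elastic constants plus Johnson-Cook hardening and damage parameters.

    Stresses in Pa, rates in 1/s, density in kg/m^3; the damage constants
    ``d1..d4`` are dimensionless.  ``d5`` is retained for file-format
    compatibility but has no effect (temperature factor disabled).
    """

    youngs_modulus: float
    poisson: float = 0.48
    density: float = 1000.0
    yield_strength: float = 1.0  # A
    hardening_modulus: float = 0.0  # B
    hardening_exponent: float = 0.0  # n
    rate_sensitivity: float = 0.0  # C
    ref_rate: float = 1.0  # eps0
    d1: float = 0.0
    d2: float = 0.0
    d3: float = 0.0
    d4: float = 0.0
    d5: float = 0.0

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if self.yield_strength <= 0:
            raise ValueError("yield strength A must be positive")
        if self.hardening_modulus < 0 or self.hardening_exponent < 0:
            raise ValueError("hardening B and exponent n must be non-negative")
        if self.ref_rate <= 0:
            raise ValueError("reference strain rate must be positive")


@dataclass(frozen=True)
class LoadingProgram:
    """Constant-rate strain-driven loading: total strain rate, duration, step."""

    strain_rate: float
    duration: float
    step: float

    def __post_init__(self) -> None:
        if self.strain_rate <= 0 or self.duration <= 0 or self.step <= 0:
            raise ValueError("strain_rate, duration and step must be positive")
        if self.step > self.duration:
            raise ValueError("step must not exceed duration")


@dataclass(frozen=True)
class DamageState:
    """Accumulated damage ``D`` and failure flag (failed iff D >= 1)."""

    damage: float = 0.0

    @property
    def failed(self) -> bool:
        return self.damage >= 1.0


# ----------------------------------------------------------------------
# constitutive evaluation
# ----------------------------------------------------------------------

def _rate_bracket(mat: JohnsonCookMaterial, plastic_rate: float) -> float:
    if plastic_rate <= 0:
        raise ValueError("plastic strain rate must be positive")
    bracket = 1.0 + mat.rate_sensitivity * math.log(plastic_rate / mat.ref_rate)
    if bracket <= RATE_BRACKET_FLOOR:
        warnings.warn(
            f"rate bracket {bracket:.3g} at rate {plastic_rate:g} /s floored "
            f"to {RATE_BRACKET_FLOOR}; deeply sub-reference rates are outside "
            "the model's regime",
            RuntimeWarning,
            stacklevel=3,
        )
        bracket = RATE_BRACKET_FLOOR
    return bracket


def jc_stress(
    mat: JohnsonCookMaterial,
    plastic_strain: float | np.ndarray,
    plastic_rate: float,
) -> float | np.ndarray:
    """Johnson-Cook flow stress at the given plastic strain and rate.

    ``0**n`` is taken as 0 so the stress at yield onset is exactly
    ``A`` times the rate bracket.
    """
    eps_p = np.asarray(plastic_strain, dtype=float)
    if np.any(eps_p < 0):
        raise ValueError("plastic strain must be non-negative")
    bracket = _rate_bracket(mat, plastic_rate)
    with np.errstate(divide="ignore"):
        hard = np.where(
            eps_p > 0, mat.hardening_modulus * eps_p ** mat.hardening_exponent, 0.0
        )
    out = (mat.yield_strength + hard) * bracket
    return float(out) if np.isscalar(plastic_strain) else out


def jc_fracture_strain(
    mat: JohnsonCookMaterial, triaxiality: float, plastic_rate: float
) -> float:
    """Fracture strain of the damage model at a stress state and rate.

    Raises if the parameters give a non-positive fracture strain, which
    would make the damage integral meaningless.
    """
    bracket = 1.0
    if mat.d4 != 0.0:
        if plastic_rate <= 0:
            raise ValueError("plastic strain rate must be positive")
        bracket = 1.0 + mat.d4 * math.log(plastic_rate / mat.ref_rate)
    elif plastic_rate <= 0:
        raise ValueError("plastic strain rate must be positive")
    eps_f = (mat.d1 + mat.d2 * math.exp(-mat.d3 * triaxiality)) * bracket
    if eps_f <= 0:
        raise ValueError(
            "non-positive fracture strain "
            f"(d1={mat.d1}, d2={mat.d2}, d3={mat.d3}, d4={mat.d4}; "
            f"triaxiality={triaxiality}, rate={plastic_rate})"
        )
    return eps_f


def accumulate_damage(
    state: DamageState, delta_plastic: float, fracture_strain: float
) -> DamageState:
    """One damage increment: ``D <- D + d_eps_p / eps_f``."""
    if delta_plastic < 0:
        raise ValueError("plastic strain increment must be non-negative")
    if fracture_strain <= 0:
        raise ValueError("fracture strain must be positive")
    return DamageState(state.damage + delta_plastic / fracture_strain)


def damage_integral(
    plastic_strain_path: np.ndarray, fracture_strain_path: np.ndarray
) -> float:
    """Trapezoidal integral of 1/eps_f along a plastic-strain path."""
    eps_p = np.asarray(plastic_strain_path, dtype=float)
    eps_f = np.asarray(fracture_strain_path, dtype=float)
    if np.any(eps_f <= 0):
        raise ValueError("fracture strain must be positive along the path")
    return float(np.trapezoid(1.0 / eps_f, eps_p))


# ----------------------------------------------------------------------
# parameter estimation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class HardeningFit:
    """Fitted hardening parameters (A, B, n) with the residual norm."""

    yield_strength: float
    hardening_modulus: float
    hardening_exponent: float
    residual_norm: float


def _hardening_varpro(eps_p: np.ndarray, sigma: np.ndarray, n: float):
    """Linear A, B solve at fixed n; returns (A, B, sum of squared residuals)."""
    design = np.column_stack([np.ones_like(eps_p), eps_p**n])
    coef, *_ = np.linalg.lstsq(design, sigma, rcond=None)
    resid = sigma - design @ coef
    return coef[0], coef[1], float(resid @ resid)


def fit_hardening(
    plastic_strain: np.ndarray,
    stress: np.ndarray,
    ref_rate: float = 1.0,
    n_bounds: tuple[float, float] = (1e-6, 2.0),
) -> HardeningFit:
    """Estimate (A, B, n) from true stress vs plastic strain at reference rate.

    The exponent ``n`` enters nonlinearly and, for the nearly
    rate-insensitive gels modelled here, can sit close to zero where the
    A/B split is ill-conditioned.  The fit therefore profiles ``n``:
    for each candidate the optimal (A, B) follow from a linear
    least-squares solve, and the profiled residual is minimised over a
    log-spaced grid refined by bounded scalar minimisation.  A final
    Levenberg refinement polishes all three parameters jointly.
    """
    eps_p = np.asarray(plastic_strain, dtype=float)
    sig = np.asarray(stress, dtype=float)
    if eps_p.shape != sig.shape:
        raise ValueError("plastic strain and stress must have equal length")
    mask = eps_p > 0
    eps_p, sig = eps_p[mask], sig[mask]
    if eps_p.size == 0:
        raise ValueError("no post-yield (plastic) samples to fit")
    if eps_p.size < 10:
        raise ValueError(f"need >= 10 post-yield samples, got {eps_p.size}")

    lo, hi = n_bounds
    grid = np.geomspace(lo, hi, 256)
    ssr = np.array([_hardening_varpro(eps_p, sig, n)[2] for n in grid])
    k = int(np.argmin(ssr))
    bl = grid[max(k - 1, 0)]
    bh = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda n: _hardening_varpro(eps_p, sig, n)[2],
        bounds=(bl, bh),
        method="bounded",
        options={"xatol": 1e-14},
    )
    n_hat = float(res.x)
    a_hat, b_hat, _ = _hardening_varpro(eps_p, sig, n_hat)

    # joint polish from the profiled solution
    def model(theta):
        a, b, n = theta
        return a + b * eps_p ** abs(n) - sig

    ls = optimize.least_squares(
        model,
        x0=[a_hat, b_hat, n_hat],
        x_scale=[max(abs(a_hat), 1.0), max(abs(b_hat), 1.0), max(n_hat, 1e-3)],
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if not ls.success:
        raise RuntimeError(
            f"hardening fit failed to converge (residual {np.linalg.norm(ls.fun):g})"
        )
    a_hat, b_hat, n_hat = ls.x[0], ls.x[1], abs(ls.x[2])
    return HardeningFit(
        yield_strength=float(a_hat),
        hardening_modulus=float(b_hat),
        hardening_exponent=float(n_hat),
        residual_norm=float(np.linalg.norm(ls.fun)),
    )


def fit_damage(
    observations: Sequence[tuple[float, float, float]],
    ref_rate: float = 1.0,
    fixed: Optional[dict] = None,
) -> tuple[float, float, float, float]:
    """Fit damage constants (d1, d2, d3, d4) to fracture observations.

    Parameters
    ----------
    observations : sequence of (fracture_strain, triaxiality, rate)
    fixed : dict, optional
        Constants to freeze, e.g. ``{"d3": 0.0}``.  Required when the
        design cannot identify them (single triaxiality with d3 free, or
        single rate with d4 free).
    """
    obs = [(float(f), float(t), float(r)) for f, t, r in observations]
    if not obs:
        raise ValueError("no observations")
    fixed = dict(fixed or {})
    free = [k for k in ("d1", "d2", "d3", "d4") if k not in fixed]
    tri = {t for _, t, _ in obs}
    rates = {r for _, _, r in obs}
    if "d3" in free and len(tri) < 2:
        raise ValueError(
            "d3 is unidentifiable from a single triaxiality; freeze it via fixed="
        )
    if "d4" in free and len(rates) < 2:
        raise ValueError(
            "d4 is unidentifiable from a single rate; freeze it via fixed="
        )
    if len(obs) < len(free):
        raise ValueError(f"{len(obs)} observations cannot identify {len(free)} constants")

    f_obs = np.array([o[0] for o in obs])
    t_obs = np.array([o[1] for o in obs])
    r_obs = np.array([o[2] for o in obs])

    def unpack(theta):
        params = dict(fixed)
        params.update(zip(free, theta))
        return params

    def resid(theta):
        p = unpack(theta)
        pred = (p["d1"] + p["d2"] * np.exp(-p["d3"] * t_obs)) * (
            1.0 + p["d4"] * np.log(r_obs / ref_rate)
        )
        return pred - f_obs

    x0 = []
    defaults = {"d1": float(np.min(f_obs)), "d2": float(np.ptp(f_obs)) or 0.01,
                "d3": 1.0, "d4": 0.0}
    for k in free:
        x0.append(defaults[k])
    if not free:
        return (fixed["d1"], fixed["d2"], fixed["d3"], fixed["d4"])
    ls = optimize.least_squares(resid, x0=x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not ls.success:
        raise RuntimeError("damage fit failed to converge")
    p = unpack(ls.x)
    return (float(p["d1"]), float(p["d2"]), float(p["d3"]), float(p["d4"]))


# ----------------------------------------------------------------------
# material-point tensile simulator
# ----------------------------------------------------------------------

def _return_map(
    mat: JohnsonCookMaterial, total_strain: float, eps_p_old: float, rate: float
) -> float:
    """Solve E*(eps - eps_p) = flow stress(eps_p) for the new plastic strain."""

    def f(eps_p):
        return mat.youngs_modulus * (total_strain - eps_p) - jc_stress(
            mat, eps_p, rate
        )

    lo, hi = eps_p_old, total_strain
    if f(hi) > 0:
        # even full plastic relaxation cannot reach the yield surface;
        # step too coarse for the hardening curvature
        raise RuntimeError(
            "return mapping failed to bracket the yield surface; "
            "use a smaller integration step"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-15, rtol=1e-14))


def simulate_tensile(
    mat: JohnsonCookMaterial,
    prog: LoadingProgram,
    triaxiality: float = UNIAXIAL_TRIAXIALITY,
    with_damage: bool = True,
) -> tuple[StressStrainCurve, DamageState]:
    """Strain-driven material-point tension test.

    Integrates total true strain at the program's constant rate; each
    step applies an elastic predictor and, when the trial stress exceeds
    the current yield surface, a return mapping onto the hardening
    curve.  Damage accumulates by trapezoidal quadrature of
    ``1/eps_f d eps_p`` and the run stops at the first sample with
    ``D >= 1``.  Returns the true stress-strain curve (``failure_index``
    set at failure, ``None`` when censored) and the final damage state.
    """
    n_steps = int(round(prog.duration / prog.step))
    d_eps = prog.strain_rate * prog.step
    rate = prog.strain_rate

    strain = [0.0]
    stress = [0.0]
    eps_p = 0.0
    damage = 0.0
    failure_index: Optional[int] = None
    inv_f_prev = None
    if with_damage:
        inv_f_prev = 1.0 / jc_fracture_strain(mat, triaxiality, rate)

    for k in range(1, n_steps + 1):
        eps = k * d_eps
        trial = mat.youngs_modulus * (eps - eps_p)
        yield_stress = jc_stress(mat, eps_p, rate)
        if trial > yield_stress:
            eps_p_new = _return_map(mat, eps, eps_p, rate)
            sig = mat.youngs_modulus * (eps - eps_p_new)
            d_plastic = eps_p_new - eps_p
            eps_p = eps_p_new
        else:
            sig = trial
            d_plastic = 0.0
        strain.append(eps)
        stress.append(sig)
        if with_damage and d_plastic > 0:
            inv_f_new = 1.0 / jc_fracture_strain(mat, triaxiality, rate)
            damage += 0.5 * (inv_f_prev + inv_f_new) * d_plastic
            inv_f_prev = inv_f_new
            if damage >= 1.0:
                failure_index = k
                break

    curve = StressStrainCurve(
        np.array(strain), np.array(stress), "true", failure_index=failure_index
    )
    return curve, DamageState(damage)
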