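"""File formats, configuration and pipeline orchestration.

All on-disk artefacts are plain text: delimited records with a one-line
header for instrument-style data, JSON for summary reports, 8-bit
grayscale PNG/TIFF for images.  Units at the file boundary follow lab
convention (mm, N, Pa, s, kPa in material configs); everything in
memory is SI.

``run_pipeline`` executes the requested stages in dependency order —
generate -> mechanics -> hardening fit, generate -> LAOS analysis,
generate -> DIC — and assembles a structured summary.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import dic as dic_mod
from . import laos as laos_mod
from . import mechanics as mech
from . import johnson_cook as jc
from . import synthetic as synth

__all__ = [
    "read_record",
    "write_record",
    "read_waveform",
    "write_waveform",
    "write_curve",
    "read_curve",
    "write_image",
    "read_image",
    "write_displacement_field",
    "write_strain_field",
    "material_from_config",
    "ring_geometry_from_config",
    "compression_geometry_from_config",
    "load_config",
    "analyze_ring_record",
    "run_pipeline",
]

MM = 1.0e-3
KPA = 1.0e3


# ----------------------------------------------------------------------
# delimited-text formats
# ----------------------------------------------------------------------

def write_record(path, record: mech.ForceDisplacementRecord) -> None:
    """Write time_s, displacement_mm, force_N columns."""
    df = pd.DataFrame(
        {
            "time_s": record.time,
            "displacement_mm": record.displacement / MM,
            "force_N": record.force,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_record(path, mode: str = "tension") -> mech.ForceDisplacementRecord:
    df = pd.read_csv(path)
    return mech.ForceDisplacementRecord(
        time=df["time_s"].to_numpy(),
        displacement=df["displacement_mm"].to_numpy() * MM,
        force=df["force_N"].to_numpy(),
        mode=mode,
    )


def write_waveform(path, wave: laos_mod.OscillationWaveform) -> None:
    """Write time_s, strain, stress_Pa columns."""
    pd.DataFrame(
        {"time_s": wave.time, "strain": wave.strain, "stress_Pa": wave.stress}
    ).to_csv(path, index=False, float_format="%.10g")


def read_waveform(path) -> laos_mod.OscillationWaveform:
    df = pd.read_csv(path)
    return laos_mod.waveform_from_arrays(
        df["time_s"].to_numpy(), df["strain"].to_numpy(), df["stress_Pa"].to_numpy()
    )


def write_curve(path, curve: mech.StressStrainCurve) -> None:
    pd.DataFrame(
        {"strain": curve.strain, "stress_Pa": curve.stress, "kind": curve.kind}
    ).to_csv(path, index=False, float_format="%.10g")


def read_curve(path) -> mech.StressStrainCurve:
    df = pd.read_csv(path)
    return mech.StressStrainCurve(
        df["strain"].to_numpy(), df["stress_Pa"].to_numpy(), str(df["kind"].iloc[0])
    )


def write_image(path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def write_displacement_field(path, field: dic_mod.DisplacementField) -> None:
    gx, gy = np.meshgrid(field.x, field.y)
    pd.DataFrame(
        {
            "x": gx.ravel(),
            "y": gy.ravel(),
            "u": field.u.ravel(),
            "v": field.v.ravel(),
            "score": field.score.ravel(),
        }
    ).to_csv(path, index=False, float_format="%.8g")


def write_strain_field(path, strains: dic_mod.StrainField) -> None:
    gx, gy = np.meshgrid(strains.x, strains.y)
    pd.DataFrame(
        {
            "x": gx.ravel(),
            "y": gy.ravel(),
            "exx": strains.exx.ravel(),
            "eyy": strains.eyy.ravel(),
            "exy": strains.exy.ravel(),
        }
    ).to_csv(path, index=False, float_format="%.8g")


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def material_from_config(block: dict) -> jc.JohnsonCookMaterial:
    """Material from config keys mirroring the gel property table (kPa)."""
    return jc.JohnsonCookMaterial(
        youngs_modulus=float(block["young_modulus_kpa"]) * KPA,
        poisson=float(block.get("poisson_ratio", 0.48)),
        density=float(block.get("density_kg_m3", 1000.0)),
        yield_strength=float(block["initial_yield_strength_kpa"]) * KPA,
        hardening_modulus=float(block.get("hardening_modulus_kpa", 0.0)) * KPA,
        hardening_exponent=float(block.get("strain_hardening_exponent", 0.0)),
        rate_sensitivity=float(block.get("strain_rate_constant", 0.0)),
        ref_rate=float(block.get("reference_strain_rate", 1.0)),
        d1=float(block.get("d1", 0.0)),
        d2=float(block.get("d2", 0.0)),
        d3=float(block.get("d3", 0.0)),
        d4=float(block.get("d4", 0.0)),
        d5=float(block.get("d5", 0.0)),
    )


def ring_geometry_from_config(block: dict) -> mech.RingGeometry:
    return mech.RingGeometry(
        pin_diameter=float(block.get("pin_diameter_mm", 6.0)) * MM,
        initial_circumference=float(block.get("initial_circumference_mm", 60.0)) * MM,
        width=float(block.get("width_mm", 5.0)) * MM,
        thickness=float(block.get("thickness_mm", 5.0)) * MM,
    )


def compression_geometry_from_config(block: dict) -> mech.CompressionGeometry:
    diameter = float(block.get("diameter_mm", 25.4)) * MM
    return mech.CompressionGeometry(
        contact_area=math.pi * (diameter / 2.0) ** 2,
        initial_length=float(block.get("height_mm", 20.0)) * MM,
    )


# ----------------------------------------------------------------------
# stage drivers
# ----------------------------------------------------------------------

def analyze_ring_record(
    record: mech.ForceDisplacementRecord,
    geom: mech.RingGeometry,
    linear_fraction: float = 0.4,
) -> dict[str, Any]:
    """Ring record -> engineering + true curves, modulus, split, failure."""
    eng = mech.ring_curve(record, geom)
    failure = mech.detect_failure(eng)
    eng.failure_index = failure.index
    true = mech.to_true(eng)
    modulus = mech.youngs_modulus(true, linear_fraction=linear_fraction)
    decomp = mech.decompose_strain(true, modulus)
    true_failure = mech.detect_failure(true)
    return {
        "engineering_curve": eng,
        "true_curve": true,
        "failure": failure,
        "true_failure": true_failure,
        "youngs_modulus_pa": modulus,
        "decomposition": decomp,
        "summary": {
            "failure_stress_mpa": failure.stress / 1e6,
            "failure_strain": failure.strain,
            "censored": failure.censored,
            "youngs_modulus_kpa": modulus / KPA,
            "yield_index": decomp.yield_index,
            "plastic_strain_at_failure": float(
                decomp.plastic_strain[failure.index]
            ),
        },
    }


def _run_ring_stage(block: dict, out: Path, seed: int) -> dict:
    geom = ring_geometry_from_config(block.get("geometry", {}))
    if "material" in block:
        material = material_from_config(block["material"])
    else:
        tgt = block["target"]
        rate = 2.0 * float(block.get("crosshead_speed_mm_s", 1.0)) * MM / (
            geom.initial_circumference
        )
        material = synth.calibrate_ring_material(
            failure_stress=float(tgt["failure_stress_mpa"]) * 1e6,
            failure_strain=float(tgt["failure_strain"]),
            loading_rate=rate,
        )
    spec = synth.GeneratorSpec(
        material=material,
        geometry=geom,
        crosshead_speed=float(block.get("crosshead_speed_mm_s", 1.0)) * MM,
        sample_rate=float(block.get("sample_rate_hz", 50.0)),
        noise_sd=float(block.get("noise_sd", 0.0)),
        seed=seed,
    )
    record = synth.generate_ring_tensile_record(spec)
    write_record(out / "ring_record.csv", record)
    result = analyze_ring_record(record, geom)
    write_curve(out / "ring_curve_engineering.csv", result["engineering_curve"])
    write_curve(out / "ring_curve_true.csv", result["true_curve"])
    summary = result["summary"]

    if block.get("fit_hardening", False):
        true = result["true_curve"]
        decomp = result["decomposition"]
        mask = decomp.plastic_strain > 1e-9
        if mask.sum() >= 10:
            fit = jc.fit_hardening(
                decomp.plastic_strain[mask], true.stress[mask],
                ref_rate=material.ref_rate,
            )
            summary["hardening_fit"] = {
                "yield_strength_kpa": fit.yield_strength / KPA,
                "hardening_modulus_kpa": fit.hardening_modulus / KPA,
                "hardening_exponent": fit.hardening_exponent,
                "residual_norm_pa": fit.residual_norm,
            }
    return summary


def _run_compression_stage(block: dict, out: Path, seed: int) -> dict:
    geom = compression_geometry_from_config(block.get("geometry", {}))
    law = synth.CompressionLaw(
        peak_stress=float(block.get("peak_stress_mpa", 0.69)) * 1e6,
        failure_strain=float(block.get("failure_strain", 0.33)),
    )
    material = jc.JohnsonCookMaterial(youngs_modulus=1.0, yield_strength=1.0)
    spec = synth.GeneratorSpec(
        material=material,
        geometry=geom,
        crosshead_speed=float(block.get("crosshead_speed_mm_s", 1.0)) * MM,
        sample_rate=float(block.get("sample_rate_hz", 50.0)),
        noise_sd=float(block.get("noise_sd", 0.0)),
        seed=seed,
        compression_law=law,
    )
    record = synth.generate_compression_record(spec)
    write_record(out / "compression_record.csv", record)
    curve = mech.compression_curve(record, geom)
    failure = mech.detect_failure(curve)
    write_curve(out / "compression_curve.csv", curve)
    return {
        "failure_stress_mpa": failure.stress / 1e6,
        "failure_strain": failure.strain,
        "censored": failure.censored,
    }


def _run_laos_stage(block: dict, out: Path, seed: int) -> dict:
    levels = block.get("strain_levels", [0.01, 0.1, 0.5, 1.0])
    max_harmonic = int(block.get("max_harmonic", 9))
    table = []
    for i, gamma0 in enumerate(levels):
        spec = synth.WaveformSpec(
            storage_modulus=float(block.get("storage_modulus_pa", 10e3)),
            loss_modulus=float(block.get("loss_modulus_pa", 1e3)),
            third_harmonic_elastic=float(block.get("third_harmonic_elastic_pa", 0.0))
            * (gamma0 / levels[-1]),
            third_harmonic_viscous=float(block.get("third_harmonic_viscous_pa", 0.0))
            * (gamma0 / levels[-1]),
            strain_amplitude=float(gamma0),
            frequency=float(block.get("frequency_hz", 1.0)),
            n_cycles=int(block.get("n_cycles", 4)),
            samples_per_cycle=int(block.get("samples_per_cycle", 256)),
            noise_sd=float(block.get("noise_sd_pa", 0.0)),
            seed=seed + i,
        )
        wave = synth.generate_laos_waveform(spec)
        write_waveform(out / f"waveform_strain{gamma0:g}.csv", wave)
        spectrum = laos_mod.harmonic_decompose(wave, max_harmonic=max_harmonic)
        loop = laos_mod.lissajous(wave)
        i3, s_ratio = laos_mod.nonlinearity_metrics(spectrum, wave)
        table.append(
            {
                "strain_amplitude": float(gamma0),
                "G1_elastic_pa": spectrum.elastic[1],
                "G1_viscous_pa": spectrum.viscous[1],
                "I3_over_I1": i3,
                "stiffening_ratio_S": s_ratio,
                "elastic_loop_area_pa": laos_mod.loop_area(loop.strain, loop.stress),
            }
        )
    return {"harmonics": table}


def _run_dic_stage(block: dict, out: Path, seed: int) -> dict:
    stretch = float(block.get("stretch_exx", 0.01))
    translation = tuple(block.get("translation_px", (3.0, -2.0)))
    deform = synth.AffineDeformation(
        gradient=((1.0 + stretch, 0.0), (0.0, 1.0)), translation=translation
    )
    spec = synth.SpeckleSpec(
        image_shape=tuple(block.get("image_shape", (256, 256))),
        deformation=deform,
        intensity_noise_sd=float(block.get("intensity_noise_sd", 0.0)),
        seed=seed,
    )
    pair = synth.generate_speckle_pair(spec)
    write_image(out / "speckle_reference.png", pair.reference)
    write_image(out / "speckle_deformed.png", pair.deformed)
    cfg = dic_mod.DicConfig(
        subset_size=int(block.get("subset_size", 21)),
        grid_spacing=int(block.get("grid_spacing", 10)),
        search_radius=int(block.get("search_radius", 10)),
    )
    field = dic_mod.track_subsets(pair.reference, pair.deformed, cfg)
    strains = dic_mod.strain_field(field)
    write_displacement_field(out / "displacement_field.csv", field)
    write_strain_field(out / "strain_field.csv", strains)
    gx, gy = np.meshgrid(field.x, field.y)
    ut, vt = pair.displacement_truth(gx, gy)
    m = field.mask
    rms_u = float(np.sqrt(np.mean((field.u[m] - ut[m]) ** 2 + (field.v[m] - vt[m]) ** 2)))
    return {
        "rms_displacement_error_px": rms_u,
        "mean_exx": float(np.nanmean(strains.exx)),
        "strain_concentration_index": dic_mod.strain_concentration_index(strains),
        "n_tracked": int(m.sum()),
    }


def run_pipeline(config: dict, out_dir, seed: Optional[int] = None) -> dict:
    """Execute the configured stages and write a JSON summary.

    Recognised top-level blocks: ``ring``, ``compression``, ``laos``,
    ``dic`` (each optional), plus ``seed``.  Outputs land in
    ``out_dir``; the summary is also returned.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))
    known = {"ring", "compression", "laos", "dic", "seed"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    summary: dict[str, Any] = {"seed": seed}
    if "ring" in config:
        summary["ring"] = _run_ring_stage(config["ring"] or {}, out, seed)
    if "compression" in config:
        summary["compression"] = _run_compression_stage(
            config["compression"] or {}, out, seed
        )
    if "laos" in config:
        summary["laos"] = _run_laos_stage(config["laos"] or {}, out, seed)
    if "dic" in config:
        summary["dic"] = _run_dic_stage(config["dic"] or {}, out, seed)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
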