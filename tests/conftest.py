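import math

import pytest

import gelmech as g

# Gel property columns for the three agarose:xanthan ratios
# (stresses in Pa; keyed by mixture ratio).
GEL_COLUMNS = {
    "1:0": dict(E=37891e3, A=2969e3, B=2054e3, n=0.00067, G=12801e3),
    "0.75:0.25": dict(E=23619e3, A=2183e3, B=2487e3, n=0.0729, G=7979e3),
    "0.5:0.5": dict(E=8388e3, A=683e3, B=2339e3, n=0.081, G=2834e3),
}

# Ring-tensile failure targets (engineering stress Pa, strain) per ratio.
RING_FAILURE = {
    "1:0": (2.65e6, 0.08),
    "0.75:0.25": (1.97e6, 0.09),
    "0.5:0.5": (1.82e6, 0.13),
}


@pytest.fixture
def ring_geometry():
    return g.RingGeometry(
        pin_diameter=6e-3,
        initial_circumference=60e-3,
        width=5e-3,
        thickness=5e-3,
    )


@pytest.fixture
def compression_geometry():
    return g.CompressionGeometry(
        contact_area=math.pi * (25.4e-3 / 2.0) ** 2, initial_length=20e-3
    )


def make_material(ratio: str, **damage) -> g.JohnsonCookMaterial:
    col = GEL_COLUMNS[ratio]
    return g.JohnsonCookMaterial(
        youngs_modulus=col["E"],
        poisson=0.48,
        yield_strength=col["A"],
        hardening_modulus=col["B"],
        hardening_exponent=col["n"],
        rate_sensitivity=0.01,
        ref_rate=1.0,
        **damage,
    )
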