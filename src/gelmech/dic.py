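"""Minimal subset-based 2-D digital image correlation (DIC).

Tracks a regular grid of square subsets from a speckled reference image
into a deformed image.  Each subset is matched by zero-normalized cross
correlation (ZNCC) over an integer-pixel search window; the correlation
peak is refined to sub-pixel precision with a paraboloid fit of the 3x3
correlation neighbourhood.  Strains are obtained from local least-squares
plane fits of the displacement components.

Coordinate convention: origin at the top-left pixel, x rightward
(columns), y downward (rows); displacements (u, v) and strains are
reported in these image axes, in pixels and pixel/pixel.

The matcher uses integer search plus quadratic peak interpolation
rather than iterative subset shape-function optimization; this is
accurate to a few hundredths of a pixel for translation-dominated and
small-strain affine fields, which is the regime of gel ring-tensile
surface tracking, but degrades for strong local rotations or strains of
several percent within one subset.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from skimage.feature import match_template

__all__ = [
    "DicConfig",
    "DisplacementField",
    "StrainField",
    "track_subsets",
    "strain_field",
    "strain_concentration_index",
]


@dataclass(frozen=True)
class DicConfig:
    """Subset matching parameters (pixels)."""

    subset_size: int = 21
    grid_spacing: int = 10
    search_radius: int = 20
    min_correlation: float = 0.5

    def __post_init__(self) -> None:
        if self.subset_size < 11 or self.subset_size % 2 == 0:
            raise ValueError("subset_size must be odd and >= 11")
        if self.grid_spacing < 1:
            raise ValueError("grid_spacing must be >= 1")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")
        if not 0 < self.min_correlation <= 1:
            raise ValueError("min_correlation must be in (0, 1]")


@dataclass
class DisplacementField:
    """Grid displacements: arrays of shape (ny, nx); masked points are NaN."""

    x: np.ndarray  # grid x (columns), shape (nx,)
    y: np.ndarray  # grid y (rows), shape (ny,)
    u: np.ndarray  # (ny, nx) displacement along x
    v: np.ndarray  # (ny, nx) displacement along y
    score: np.ndarray  # (ny, nx) ZNCC peak value

    @property
    def mask(self) -> np.ndarray:
        """True where the point is valid."""
        return np.isfinite(self.u) & np.isfinite(self.v)


@dataclass
class StrainField:
    """Small-strain components on the DIC grid; masked points are NaN."""

    x: np.ndarray
    y: np.ndarray
    exx: np.ndarray
    eyy: np.ndarray
    exy: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.exx)


# pseudo-inverse of the 3x3 quadratic-surface design matrix
# c0 + c1*x + c2*y + c3*x^2 + c4*x*y + c5*y^2 on x, y in {-1, 0, 1}
_X3, _Y3 = np.meshgrid([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0])
_DESIGN_PINV = np.linalg.pinv(
    np.column_stack(
        [
            np.ones(9),
            _X3.ravel(),
            _Y3.ravel(),
            _X3.ravel() ** 2,
            _X3.ravel() * _Y3.ravel(),
            _Y3.ravel() ** 2,
        ]
    )
)


def _parabolic_offset(m: np.ndarray) -> tuple[float, float]:
    """Sub-pixel peak offset from a paraboloid fit of the 3x3 neighbourhood.

    Fits a full quadratic surface and returns its stationary point,
    clipped to half a pixel; falls back to the integer peak when the
    surface is not concave there.
    """
    c = _DESIGN_PINV @ m.ravel()
    hess = np.array([[2.0 * c[3], c[4]], [c[4], 2.0 * c[5]]])
    if not (hess[0, 0] < 0 and np.linalg.det(hess) > 0):  # not a maximum
        return 0.0, 0.0
    off = np.linalg.solve(hess, [-c[1], -c[2]])
    return (
        float(np.clip(off[0], -0.5, 0.5)),
        float(np.clip(off[1], -0.5, 0.5)),
    )


def track_subsets(
    reference: np.ndarray, deformed: np.ndarray, cfg: DicConfig
) -> DisplacementField:
    """Match reference subsets into the deformed image on a regular grid.

    Each grid point takes the odd square subset centred on it in the
    reference image and locates the maximum-ZNCC position inside a
    ``(2*search_radius + 1)``-pixel window of the deformed image,
    refined to sub-pixel by a 3x3 paraboloid fit.  Points whose search
    window leaves the image, or whose peak correlation falls below
    ``min_correlation``, are masked (NaN).
    """
    ref = np.asarray(reference, dtype=float)
    def_ = np.asarray(deformed, dtype=float)
    if ref.shape != def_.shape:
        raise ValueError("reference and deformed images must have the same shape")
    h = cfg.subset_size // 2
    r = cfg.search_radius
    margin = h + r
    rows, cols = ref.shape
    xs = np.arange(margin, cols - margin, cfg.grid_spacing)
    ys = np.arange(margin, rows - margin, cfg.grid_spacing)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("grid does not fit inside the image with these margins")

    u = np.full((ys.size, xs.size), np.nan)
    v = np.full((ys.size, xs.size), np.nan)
    score = np.full((ys.size, xs.size), np.nan)

    for iy, y0 in enumerate(ys):
        for ix, x0 in enumerate(xs):
            template = ref[y0 - h : y0 + h + 1, x0 - h : x0 + h + 1]
            if template.std() == 0:
                continue  # featureless subset cannot be matched
            window = def_[y0 - h - r : y0 + h + r + 1, x0 - h - r : x0 + h + r + 1]
            corr = match_template(window, template)  # (2r+1, 2r+1)
            peak = np.unravel_index(np.argmax(corr), corr.shape)
            peak_val = float(corr[peak])
            if peak_val < cfg.min_correlation:
                continue
            py, px = peak
            dx = dy = 0.0
            # a numerically perfect integer match needs no refinement
            if peak_val < 1.0 - 1e-9 and (
                0 < py < corr.shape[0] - 1 and 0 < px < corr.shape[1] - 1
            ):
                dx, dy = _parabolic_offset(corr[py - 1 : py + 2, px - 1 : px + 2])
            u[iy, ix] = (px - r) + dx
            v[iy, ix] = (py - r) + dy
            score[iy, ix] = peak_val

    if not np.any(np.isfinite(u)):
        raise ValueError("all grid points masked; no correlation found")
    return DisplacementField(x=xs.astype(float), y=ys.astype(float), u=u, v=v, score=score)


def strain_field(field: DisplacementField, window: int = 3) -> StrainField:
    """Small-strain field from local plane fits of the displacements.

    For each grid point, u and v over the surrounding ``window`` x
    ``window`` grid neighbourhood are fit with least-squares planes
    a + b*x + c*y; the gradients give exx = du/dx, eyy = dv/dy and
    exy = (du/dy + dv/dx) / 2.  Points with fewer than 3x3 valid
    neighbours (or at the grid border) are masked.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    hw = window // 2
    ny, nx = field.u.shape
    exx = np.full((ny, nx), np.nan)
    eyy = np.full((ny, nx), np.nan)
    exy = np.full((ny, nx), np.nan)
    valid = field.mask

    for iy in range(hw, ny - hw):
        for ix in range(hw, nx - hw):
            sel = np.s_[iy - hw : iy + hw + 1, ix - hw : ix + hw + 1]
            m = valid[sel]
            if m.sum() < 9:
                continue
            gx, gy = np.meshgrid(field.x[ix - hw : ix + hw + 1],
                                 field.y[iy - hw : iy + hw + 1])
            a = np.column_stack([np.ones(m.sum()), gx[m], gy[m]])
            cu, *_ = np.linalg.lstsq(a, field.u[sel][m], rcond=None)
            cv, *_ = np.linalg.lstsq(a, field.v[sel][m], rcond=None)
            exx[iy, ix] = cu[1]          # du/dx
            eyy[iy, ix] = cv[2]          # dv/dy
            exy[iy, ix] = 0.5 * (cu[2] + cv[1])
    return StrainField(x=field.x, y=field.y, exx=exx, eyy=eyy, exy=exy)


def strain_concentration_index(strains: StrainField) -> float:
    """Peak-to-median ratio of exx: ~1 for homogeneous elongation fields,
    large when strain localizes at an incipient crack."""
    vals = strains.exx[strains.mask]
    if vals.size < 10:
        raise ValueError("need >= 10 unmasked strain points")
    med = float(np.median(vals))
    if med <= 0:
        raise ValueError("non-positive median strain; index undefined")
    return float(np.max(vals) / med)
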