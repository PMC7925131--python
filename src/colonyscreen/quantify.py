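"""Ratiometric quantification of two-channel colony plate scans.

Pipeline (per plate): segment the scan into one pitch-sized grid cell
per colony, extract background-subtracted GFP and RFP intensities, form
the ratio ``I = GFP/RFP``, fit the plate's titration row to the
saturating calibration curve

    I = alpha * G / (1 - beta * G)

where ``G`` is the GFP-strain fraction, invert it for every colony
(``G = I / (alpha + beta * I)``), and normalize fractions so the 1:1
parent-parent control co-cultures average 1 — the competitive fitness
scale on which 0 means fully outcompeted and 1 means parity with the
parent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares

from .layout import PlateLayout

#: factor by which the RFP intensity must exceed the background-noise
#: estimate of the summed signal before the ratio is considered stable
RFP_FLOOR_SIGMA = 5.0

#: default border-frame width for background estimation, as a fraction
#: of the grid-cell side
BORDER_FRACTION = 0.1

# mean and sd scale of a zero-mean Gaussian pixel after clipping at 0,
# used to predict the background contribution to a clipped pixel sum
_CLIP_MEAN = 1.0 / math.sqrt(2.0 * math.pi)
_CLIP_SD = math.sqrt(0.5 - 1.0 / (2.0 * math.pi))


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted parameters of the ratio-vs-fraction calibration curve."""

    alpha: float
    beta: float
    residual_norm: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta >= 1:
            raise ValueError("beta must be < 1")

    def predict(self, fractions) -> np.ndarray:
        """Predicted ratio I at GFP fraction(s) G."""
        return predict_ratio(np.asarray(fractions, dtype=float), self.alpha, self.beta)


def predict_ratio(G, alpha: float, beta: float):
    """Calibration curve I = alpha*G / (1 - beta*G)."""
    G = np.asarray(G, dtype=float)
    return alpha * G / (1.0 - beta * G)


@dataclass(frozen=True)
class Region:
    """One grid cell of a segmented plate (pixel bounds, half-open)."""

    row: int
    col: int
    y0: int
    y1: int
    x0: int
    x1: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y0, self.y1), slice(self.x0, self.x1))

    @property
    def center_px(self) -> tuple[float, float]:
        return ((self.y0 + self.y1) / 2.0, (self.x0 + self.x1) / 2.0)


@dataclass
class ColonyMeasurement:
    """Background-subtracted channel intensities of one colony."""

    position: tuple[int, int]
    gfp_intensity: float
    rfp_intensity: float
    ratio: float | None  # I = gfp/rfp; None when RFP is below the floor
    flags: tuple[str, ...] = ()
    background_gfp: float = 0.0
    background_rfp: float = 0.0


@dataclass
class FractionEstimate:
    """Estimated GFP-strain fraction of one colony."""

    position: tuple[int, int]
    G: float
    clipped: bool = False
    flags: tuple[str, ...] = ()


@dataclass
class FitnessRecord:
    """Control-normalized competitive fitness of one colony."""

    position: tuple[int, int]
    fitness: float
    strain_id: str | None = None
    medium: str | None = None
    induction: str | None = None
    parent_genotype: str | None = None
    time_hr: float | None = None
    replicate: int = 0
    flags: tuple[str, ...] = ()


def segment_plate(
    image: np.ndarray, layout: PlateLayout, scale: float
) -> list[Region]:
    """Divide a plate scan into one pitch-sized cell per layout position.

    ``scale`` is in px/mm.  Each region is a square of side ``pitch``
    centered on the nominal colony center; adjacent regions share edges
    so the grid tiles without overlap.

    Raises
    ------
    ValueError
        if any region would fall outside the image, naming the position.
    """
    side = int(round(layout.pitch * scale))
    regions = []
    for p in layout.positions:
        y0 = int(round(p.center_y * scale - side / 2))
        x0 = int(round(p.center_x * scale - side / 2))
        y1, x1 = y0 + side, x0 + side
        if y0 < 0 or x0 < 0 or y1 > image.shape[0] or x1 > image.shape[1]:
            raise ValueError(
                f"grid cell for position ({p.row},{p.col}) "
                f"[{y0}:{y1}, {x0}:{x1}] falls outside the "
                f"{image.shape[0]}x{image.shape[1]} image"
            )
        regions.append(Region(p.row, p.col, y0, y1, x0, x1))
    return regions


def _border_mask(shape: tuple[int, int], width: int) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[:width, :] = m[-width:, :] = True
    m[:, :width] = m[:, -width:] = True
    return m


def _region_signal(patch: np.ndarray, border: np.ndarray) -> tuple[float, float, float]:
    """(clipped background-subtracted sum, background median, noise sd)."""
    ring = patch[border].astype(float)
    bg = float(np.median(ring))
    sigma = 1.4826 * float(np.median(np.abs(ring - bg)))
    resid = patch.astype(float) - bg
    total = float(np.sum(np.clip(resid, 0.0, None)))
    return total, bg, sigma


def extract_intensities(
    gfp_image: np.ndarray,
    rfp_image: np.ndarray,
    regions: list[Region],
    border_fraction: float = BORDER_FRACTION,
    rfp_floor_sigma: float = RFP_FLOOR_SIGMA,
) -> list[ColonyMeasurement]:
    """Measure background-subtracted channel intensities per grid cell.

    Background per region is the median of its border-pixel frame
    (robust to the colony occupying the cell center); negative residual
    pixels are clipped to 0 before summing.  The ratio I is left
    undefined (and the colony flagged) when the RFP sum does not exceed
    the expected clipped-background sum by ``rfp_floor_sigma`` standard
    deviations — the guard against dividing by noise.
    """
    if gfp_image.shape != rfp_image.shape:
        raise ValueError(
            f"channel shapes differ: {gfp_image.shape} vs {rfp_image.shape}"
        )
    out = []
    for reg in regions:
        g_patch = gfp_image[reg.slices]
        r_patch = rfp_image[reg.slices]
        width = max(1, int(round(border_fraction * g_patch.shape[0])))
        border = _border_mask(g_patch.shape, width)
        n_px = g_patch.size
        g_sum, g_bg, g_sigma = _region_signal(g_patch, border)
        r_sum, r_bg, r_sigma = _region_signal(r_patch, border)

        # expected pixel sum of pure clipped background noise, plus margin
        r_floor = n_px * r_sigma * _CLIP_MEAN + rfp_floor_sigma * r_sigma * math.sqrt(
            n_px
        ) * _CLIP_SD
        g_floor = n_px * g_sigma * _CLIP_MEAN + rfp_floor_sigma * g_sigma * math.sqrt(
            n_px
        ) * _CLIP_SD

        flags: list[str] = []
        ratio: float | None = None
        if r_sum <= r_floor:
            flags.append("low_rfp")
            if g_sum <= g_floor:
                flags.append("background_only")
        else:
            ratio = g_sum / r_sum
        out.append(
            ColonyMeasurement(
                position=(reg.row, reg.col),
                gfp_intensity=g_sum,
                rfp_intensity=r_sum,
                ratio=ratio,
                flags=tuple(flags),
                background_gfp=g_bg,
                background_rfp=r_bg,
            )
        )
    return out


def fit_titration(fractions, ratios) -> CalibrationFit:
    """Fit the calibration curve I = alpha*G/(1 - beta*G) to a titration row.

    Nonlinear least squares with alpha > 0 and beta <= 0.999 (covering
    both the saturating beta > 0 and the linear beta ~ 0 regimes).
    Initialization: alpha0 from the point nearest G = 0.5 via
    alpha0 = I/G (exact when beta = 0), beta0 = 0.

    Raises
    ------
    ValueError
        for degenerate input (fewer than 3 distinct fractions, or a
        titration that does not span the unit interval).
    RuntimeError
        when the optimizer fails to converge, reporting the
        initialization and residual reached.
    """
    G = np.asarray(fractions, dtype=float)
    I = np.asarray(ratios, dtype=float)
    if G.shape != I.shape or G.ndim != 1:
        raise ValueError("fractions and ratios must be 1-D and the same length")
    if not np.all(np.isfinite(I)) or not np.all(np.isfinite(G)):
        raise ValueError("fractions and ratios must be finite")
    if len(np.unique(G)) < 3:
        raise ValueError("need at least 3 distinct titration fractions")
    if G.min() > 0.2 or G.max() < 0.8:
        raise ValueError(
            "titration must span the unit interval (values near 0 and near 1)"
        )

    mid = int(np.argmin(np.abs(G - 0.5)))
    alpha0 = I[mid] / G[mid] if G[mid] > 0 else max(I.max(), 1.0)
    alpha0 = max(alpha0, 1e-6)
    x0 = np.array([alpha0, 0.0])

    def residuals(params):
        a, b = params
        return a * G / (1.0 - b * G) - I

    res = least_squares(
        residuals,
        x0,
        bounds=([1e-12, -np.inf], [np.inf, 0.999]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise RuntimeError(
            f"calibration fit failed to converge from alpha0={alpha0:.4g}, "
            f"beta0=0 (residual norm {np.linalg.norm(res.fun):.4g}): {res.message}"
        )
    alpha, beta = res.x
    return CalibrationFit(
        alpha=float(alpha),
        beta=float(beta),
        residual_norm=float(np.linalg.norm(res.fun)),
        n_points=len(G),
    )


def ratio_to_fraction(
    I: float, cal: CalibrationFit, position: tuple[int, int] = (-1, -1)
) -> FractionEstimate:
    """Invert the calibration curve: G = I / (alpha + beta*I).

    Values outside [0, 1] (possible under noise) are clipped and
    flagged, never silently.
    """
    if I < 0:
        raise ValueError("ratio I must be >= 0")
    denom = cal.alpha + cal.beta * I
    if denom <= 0:
        raise ValueError(
            f"invalid calibration for ratio {I:.4g}: alpha + beta*I = {denom:.4g} <= 0"
        )
    G = I / denom
    clipped = not (0.0 <= G <= 1.0)
    return FractionEstimate(
        position=position,
        G=float(np.clip(G, 0.0, 1.0)),
        clipped=clipped,
        flags=("clipped",) if clipped else (),
    )


def compute_fitness(
    estimates: list[FractionEstimate],
    control_positions,
) -> list[FitnessRecord]:
    """Normalize GFP fractions so the plate's 1:1 controls average 1.

    fitness = G / mean(G over this plate's unflagged control colonies).
    """
    control_set = {tuple(p) for p in control_positions}
    ctrl = [
        e.G for e in estimates if e.position in control_set and not e.clipped
    ]
    if not ctrl:
        ctrl = [e.G for e in estimates if e.position in control_set]
    if not ctrl:
        raise ValueError("no valid control colonies on the plate")
    mean_ctrl = float(np.mean(ctrl))
    if mean_ctrl <= 1e-9:
        raise ValueError(f"control mean fraction {mean_ctrl:.3g} is ~0; cannot normalize")
    return [
        FitnessRecord(position=e.position, fitness=e.G / mean_ctrl, flags=e.flags)
        for e in estimates
    ]


def measure_colony_size(
    image: np.ndarray,
    region: Region,
    scale: float,
    threshold_fraction: float = 0.5,
    border_fraction: float = BORDER_FRACTION,
    min_peak_sigma: float = 5.0,
) -> float:
    """Colony diameter (mm) from the above-threshold footprint.

    The threshold sits at ``threshold_fraction`` of the background-
    subtracted peak (half-maximum by default).  The diameter is the
    equivalent-area diameter of the connected component containing the
    region center; 0 when nothing rises ``min_peak_sigma`` noise sd
    above background (a dead or absent colony).
    """
    patch = image[region.slices].astype(float)
    width = max(1, int(round(border_fraction * patch.shape[0])))
    border = _border_mask(patch.shape, width)
    ring = patch[border]
    bg = float(np.median(ring))
    sigma = 1.4826 * float(np.median(np.abs(ring - bg)))
    peak = float(patch.max()) - bg
    if peak <= min_peak_sigma * sigma or peak <= 0:
        return 0.0
    mask = patch - bg > threshold_fraction * peak
    labels, _ = ndimage.label(mask)
    cy, cx = patch.shape[0] // 2, patch.shape[1] // 2
    lab = labels[cy, cx]
    if lab == 0:
        return 0.0
    area_px = float(np.sum(labels == lab))
    return 2.0 * math.sqrt(area_px / math.pi) / scale


def quantify_plate(
    gfp_image: np.ndarray,
    rfp_image: np.ndarray,
    layout: PlateLayout,
    scale: float,
    border_fraction: float = BORDER_FRACTION,
) -> tuple[pd.DataFrame, CalibrationFit]:
    """Full per-plate pipeline: segment, extract, calibrate, map, normalize.

    Returns a per-colony table (position, role, intensities, ratio,
    fraction, fitness, flags) and the plate's calibration fit.  The
    calibration comes from this plate's own titration row; fitness is
    normalized to this plate's own 1:1 controls.
    """
    regions = segment_plate(gfp_image, layout, scale)
    measurements = extract_intensities(
        gfp_image, rfp_image, regions, border_fraction=border_fraction
    )
    by_pos = {m.position: m for m in measurements}

    tit = [
        (p.known_fraction, by_pos[(p.row, p.col)].ratio)
        for p in layout.titration_positions
        if by_pos[(p.row, p.col)].ratio is not None
    ]
    if len(tit) < 3:
        raise ValueError("fewer than 3 usable titration colonies on the plate")
    cal = fit_titration([t[0] for t in tit], [t[1] for t in tit])

    estimates = []
    for m in measurements:
        if m.ratio is None:
            estimates.append(
                FractionEstimate(position=m.position, G=0.0, clipped=False, flags=m.flags)
            )
        else:
            est = ratio_to_fraction(m.ratio, cal, position=m.position)
            est.flags = est.flags + m.flags
            estimates.append(est)

    controls = [(p.row, p.col) for p in layout.control_positions]
    usable = [e for e in estimates if "low_rfp" not in e.flags]
    fitness = compute_fitness(usable, controls) if controls else []
    fit_by_pos = {f.position: f.fitness for f in fitness}

    role_by_pos = {(p.row, p.col): p for p in layout.positions}
    rows = []
    for m, e in zip(measurements, estimates):
        p = role_by_pos[m.position]
        rows.append(
            {
                "row": m.position[0],
                "col": m.position[1],
                "role": p.role,
                "known_fraction": p.known_fraction,
                "gfp_intensity": m.gfp_intensity,
                "rfp_intensity": m.rfp_intensity,
                "ratio": m.ratio,
                "fraction": e.G if "low_rfp" not in e.flags else np.nan,
                "clipped": e.clipped,
                "fitness": fit_by_pos.get(m.position, np.nan),
                "flags": ";".join(e.flags),
            }
        )
    return pd.DataFrame(rows), cal
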