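"""Synthetic data generators for every stage of the screen pipeline.

The wet-lab screen produces two-channel (GFP/RFP) plate scans, OD600
growth curves, and per-strain fitness trajectories.  This module renders
all three with known ground truth so the quantification, kinetics and
statistics stages each have known-answer tests.

Rendering model
---------------
Each colony is a flat-top disc with a Gaussian edge falloff.  A colony
with GFP-strain fraction ``G`` and total brightness ``B`` (fluorescence-
equivalent counts) contributes integrated background-subtracted signals

    GFP = B * alpha * G          RFP = B * (1 - beta * G)

so the channel ratio reproduces the saturating calibration relationship
``I = alpha*G / (1 - beta*G)`` exactly when all noise terms are zero.
Noise is additive per-pixel Gaussian background plus an independent
per-colony, per-channel multiplicative log-normal factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .layout import PlateLayout, make_plate_layout
from .quantify import CalibrationFit

DEFAULT_SCALE_PX_PER_MM = 10.0

__all__ = [
    "NoiseModel",
    "ColonyProfile",
    "TruthTable",
    "make_truth_table",
    "render_plate_images",
    "profile_integral_mm2",
    "generate_growth_curve",
    "generate_screen_truth",
    "simulate_plate",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive background plus per-colony multiplicative noise.

    background_level : mean pixel intensity away from colonies (counts)
    background_sd    : per-pixel Gaussian sd of the background (counts)
    multiplicative_cv: coefficient of variation of the per-colony,
                       per-channel log-normal brightness factor
    """

    background_level: float = 100.0
    background_sd: float = 5.0
    multiplicative_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_sd < 0 or self.multiplicative_cv < 0:
            raise ValueError("noise dispersion parameters must be >= 0")
        if self.background_level < 0:
            raise ValueError("background level must be >= 0")

    def quiet(self) -> "NoiseModel":
        """The same model with all dispersions zeroed (background kept)."""
        return replace(self, background_sd=0.0, multiplicative_cv=0.0)


@dataclass(frozen=True)
class ColonyProfile:
    """Flat-top radial intensity profile with a Gaussian rim.

    p(r) = 1 for r <= radius, exp(-(r-radius)^2 / (2 sigma^2)) beyond.
    """

    radius_mm: float = 1.5
    edge_sigma_mm: float = 0.1

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.edge_sigma_mm < 0:
            raise ValueError("profile radius must be > 0 and edge sigma >= 0")

    def __call__(self, r: np.ndarray) -> np.ndarray:
        out = np.ones_like(r)
        rim = r > self.radius_mm
        if self.edge_sigma_mm > 0:
            out[rim] = np.exp(
                -((r[rim] - self.radius_mm) ** 2) / (2 * self.edge_sigma_mm**2)
            )
        else:
            out[rim] = 0.0
        return out

    @property
    def support_mm(self) -> float:
        """Radius beyond which the profile is negligible (< 4 sigma tail)."""
        return self.radius_mm + 4.0 * self.edge_sigma_mm


def profile_integral_mm2(profile: ColonyProfile) -> float:
    """Analytic area integral of the radial profile in mm^2.

    2*pi * int p(r) r dr  =  pi R^2 + 2 pi sigma^2 + 2 pi R sigma sqrt(pi/2)
    """
    R, s = profile.radius_mm, profile.edge_sigma_mm
    return math.pi * R**2 + 2 * math.pi * s**2 + 2 * math.pi * R * s * math.sqrt(math.pi / 2)


@dataclass(frozen=True)
class TruthTable:
    """Ground truth for every non-blank position of a rendered plate."""

    table: pd.DataFrame  # row, col, role, strain_id, true_fraction, true_biomass

    def fraction_at(self, row: int, col: int) -> float:
        m = (self.table["row"] == row) & (self.table["col"] == col)
        return float(self.table.loc[m, "true_fraction"].iloc[0])


def make_truth_table(
    layout: PlateLayout,
    seed: int = 0,
    biomass_mean: float = 1.0e6,
    biomass_cv: float = 0.2,
    sample_fraction_weights: tuple[float, float, float] = (0.3, 0.4, 0.3),
) -> TruthTable:
    """Assign ground-truth GFP fractions and brightness to a layout.

    Titration positions keep their nominal fractions; 1:1 controls are
    exactly 0.5.  Sample fractions come from a three-component mixture
    (mass near 0, near 0.5, and spread across the middle) so the full
    calibration range is exercised.  Brightness is log-normal around
    ``biomass_mean`` counts.
    """
    rng = np.random.default_rng(seed)
    lo_w, mid_w, spread_w = sample_fraction_weights
    records = []
    for i, p in enumerate(layout.positions):
        if p.role == "blank":
            continue
        if p.role == "titration":
            frac = float(p.known_fraction)
        elif p.role == "control_1to1":
            frac = 0.5
        else:
            u = rng.random()
            if u < lo_w:
                frac = float(rng.uniform(0.0, 0.1))
            elif u < lo_w + mid_w:
                frac = float(np.clip(rng.normal(0.5, 0.05), 0.0, 1.0))
            else:
                frac = float(rng.uniform(0.1, 0.9))
        sigma = math.sqrt(math.log(1 + biomass_cv**2))
        biomass = float(biomass_mean * rng.lognormal(-0.5 * sigma**2, sigma))
        records.append(
            {
                "row": p.row,
                "col": p.col,
                "role": p.role,
                "strain_id": f"{p.role}_{i:03d}",
                "true_fraction": frac,
                "true_biomass": biomass,
            }
        )
    return TruthTable(pd.DataFrame.from_records(records))


def _render_colony_patch(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    profile: ColonyProfile,
    scale: float,
    oversample: int = 4,
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Evaluate the profile on an oversampled patch around one colony.

    Returns the patch's slice into the full image and the mean profile
    value per pixel (so the pixel sum approximates the area integral in
    px^2 even for sharp edges).
    """
    cy, cx = center_px
    r_px = profile.support_mm * scale
    y0 = max(int(math.floor(cy - r_px)) - 1, 0)
    y1 = min(int(math.ceil(cy + r_px)) + 2, shape[0])
    x0 = max(int(math.floor(cx - r_px)) - 1, 0)
    x1 = min(int(math.ceil(cx + r_px)) + 2, shape[1])
    n = oversample
    # subpixel sample centers: pixel i covers [i, i+1), samples at i + (k+0.5)/n
    ys = y0 + (np.arange((y1 - y0) * n) + 0.5) / n
    xs = x0 + (np.arange((x1 - x0) * n) + 0.5) / n
    dy = (ys - cy) / scale
    dx = (xs - cx) / scale
    rr = np.sqrt(dy[:, None] ** 2 + dx[None, :] ** 2)
    fine = profile(rr)
    coarse = fine.reshape(y1 - y0, n, x1 - x0, n).mean(axis=(1, 3))
    return (slice(y0, y1), slice(x0, x1)), coarse


def render_plate_images(
    layout: PlateLayout,
    truth: TruthTable,
    cal: CalibrationFit,
    noise: NoiseModel,
    profile: ColonyProfile = ColonyProfile(),
    scale: float = DEFAULT_SCALE_PX_PER_MM,
) -> tuple[np.ndarray, np.ndarray, TruthTable]:
    """Render the GFP and RFP channel images of one plate.

    Returns two uint16 images (one per channel) plus the truth table
    augmented with each colony's integrated per-channel signal (after the
    multiplicative factor, before background and quantization), which is
    the oracle for intensity-extraction tests.
    """
    if not (cal.alpha > 0 and 0 <= cal.beta < 1):
        raise ValueError("calibration must satisfy alpha > 0 and 0 <= beta < 1")
    if profile.support_mm > layout.pitch / 2:
        raise ValueError(
            f"colony support {profile.support_mm:.2f} mm exceeds half the "
            f"pitch ({layout.pitch / 2:.2f} mm); colonies would overlap"
        )

    rng = np.random.default_rng(noise.seed)
    h = int(round(layout.n_rows * layout.pitch * scale))
    w = int(round(layout.n_cols * layout.pitch * scale))

    if noise.background_sd > 0:
        gfp = rng.normal(noise.background_level, noise.background_sd, (h, w))
        rfp = rng.normal(noise.background_level, noise.background_sd, (h, w))
    else:
        gfp = np.full((h, w), float(noise.background_level))
        rfp = np.full((h, w), float(noise.background_level))

    integral_px2 = profile_integral_mm2(profile) * scale**2
    cv = noise.multiplicative_cv
    sigma_ln = math.sqrt(math.log(1 + cv**2)) if cv > 0 else 0.0

    table = truth.table.copy()
    gfp_sig = np.zeros(len(table))
    rfp_sig = np.zeros(len(table))

    pos_by_rc = {(p.row, p.col): p for p in layout.positions}
    for i, rec in enumerate(table.itertuples(index=False)):
        p = pos_by_rc[(rec.row, rec.col)]
        G, B = rec.true_fraction, rec.true_biomass
        sig = {"gfp": B * cal.alpha * G, "rfp": B * (1 - cal.beta * G)}
        # mean-one log-normal brightness factor, independent per channel
        for chan in ("gfp", "rfp"):
            if sigma_ln > 0:
                sig[chan] *= rng.lognormal(-0.5 * sigma_ln**2, sigma_ln)
        center_px = (p.center_y * scale, p.center_x * scale)
        sl, patch = _render_colony_patch((h, w), center_px, profile, scale)
        gfp[sl] += (sig["gfp"] / integral_px2) * patch
        rfp[sl] += (sig["rfp"] / integral_px2) * patch
        gfp_sig[i], rfp_sig[i] = sig["gfp"], sig["rfp"]

    table["gfp_signal"] = gfp_sig
    table["rfp_signal"] = rfp_sig
    gfp16 = np.clip(np.rint(gfp), 0, 65535).astype(np.uint16)
    rfp16 = np.clip(np.rint(rfp), 0, 65535).astype(np.uint16)
    return gfp16, rfp16, TruthTable(table)


def simulate_plate(
    n_rows: int = 8,
    n_cols: int = 12,
    pitch: float = 9.0,
    alpha: float = 2.0,
    beta: float = 0.5,
    noise: NoiseModel | None = None,
    profile: ColonyProfile = ColonyProfile(),
    scale: float = DEFAULT_SCALE_PX_PER_MM,
    seed: int = 0,
) -> tuple[PlateLayout, TruthTable, np.ndarray, np.ndarray]:
    """One-call convenience wrapper: layout + truth + rendered channels."""
    layout = make_plate_layout(n_rows=n_rows, n_cols=n_cols, pitch=pitch)
    truth = make_truth_table(layout, seed=seed)
    cal = CalibrationFit(alpha=alpha, beta=beta)
    if noise is None:
        noise = NoiseModel(seed=seed + 1)
    else:
        noise = replace(noise, seed=seed + 1)
    gfp, rfp, truth = render_plate_images(layout, truth, cal, noise, profile, scale)
    return layout, truth, gfp, rfp


# ---------------------------------------------------------------------------
# OD600 growth curves


def generate_growth_curve(
    r_max: float,
    lag: float = 0.0,
    capacity: float = 1.0,
    blank: float = 0.05,
    noise_sd: float = 0.001,
    sample_interval: float = 7.5,
    total_duration: float = 960.0,
    seed: int = 0,
    init_od: float = 0.02,
):
    """Sample a logistic OD600 trajectory the way a plate reader would.

    OD(t) = blank + logistic(t; r_max, lag, capacity, init_od) + noise,
    read every ``sample_interval`` minutes (7.5 min by default).  Set
    ``capacity=np.inf`` for pure exponential growth.  Rates are per
    minute, durations in minutes, OD unitless.  Default noise_sd of
    0.001 OD matches the read-to-read precision of a modern microplate
    reader; the default inoculum sits at OD 0.02 above blank.
    """
    from .kinetics import GrowthCurve

    if r_max <= 0:
        raise ValueError("r_max must be positive")
    if total_duration <= 0 or sample_interval <= 0:
        raise ValueError("duration and sampling interval must be positive")
    if not np.isinf(capacity) and capacity <= blank:
        raise ValueError("capacity must exceed the blank")
    if init_od <= 0:
        raise ValueError("initial OD must be positive")

    t = np.arange(0.0, total_duration + sample_interval / 2, sample_interval)
    tt = np.maximum(t - lag, 0.0)
    if np.isinf(capacity):
        od = init_od * np.exp(r_max * tt)
    else:
        # logistic with N(lag) = init_od
        od = capacity / (1.0 + (capacity / init_od - 1.0) * np.exp(-r_max * tt))
    od = od + blank
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, od.shape)
    return GrowthCurve(times=t, od=od, blank=blank, smoothed=False, meta="synthetic")


# ---------------------------------------------------------------------------
# Whole-screen ground truth

#: default library composition: known essential genes, conditionally
#: essential genes, and no-sgRNA controls
DEFAULT_REGISTRY = {"essential": 252, "conditionally_essential": 47, "control": 3}


def default_strain_registry() -> pd.DataFrame:
    """Strain registry mirroring the screened library's composition."""
    records = []
    for cls, n in DEFAULT_REGISTRY.items():
        for i in range(n):
            records.append({"strain_id": f"{cls}_{i + 1:03d}", "strain_class": cls})
    return pd.DataFrame.from_records(records)


def generate_screen_truth(
    n_strains: int | None = None,
    fitness_effect_distribution: dict | None = None,
    mutualist_ids: set[str] | frozenset[str] = frozenset(),
    media: tuple[str, ...] = ("LB", "MSgg"),
    timepoints: tuple[float, ...] = (16.0, 24.0, 48.0),
    n_replicates: int = 3,
    n_parent_controls: int = 19,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a tidy ground-truth fitness table for a whole screen.

    Every strain gets a fitness value at each (medium, induction,
    parent_genotype, time, replicate) combination.  Controls and most
    strains sit near fitness 1; a ``low_fraction`` of non-control strains
    is planted with a strong competitive defect.  Designated mutualists
    gain a fitness advantage with the matrix-deficient parent that grows
    linearly from 16 to 48 hr, mimicking a matrix-for-nutrient mutualism;
    everyone else's trajectories are exchangeable with the controls'.

    Besides the 302-strain library registry, each screen carries
    ``n_parent_controls`` parent-GFP : parent-RFP control co-cultures
    (class ``parent_control``, fitness 1) — the plates' outer control
    column and row — which anchor control-derived thresholds.

    ``fitness_effect_distribution`` keys (all optional):
      low_fraction (0.3), low_fitness_range ((0.0, 0.5)),
      neutral_sd (0.05), replicate_sd (0.05),
      mutualist_benefit_16 (0.05), mutualist_benefit_48 (0.5).

    Columns: strain_id, strain_class, medium, induction, parent_genotype,
    time_hr, replicate, fitness, true_low, true_mutualist.
    """
    spec = {
        "low_fraction": 0.3,
        "low_fitness_range": (0.0, 0.5),
        "neutral_sd": 0.05,
        "replicate_sd": 0.05,
        "mutualist_benefit_16": 0.05,
        "mutualist_benefit_48": 0.5,
    }
    spec.update(fitness_effect_distribution or {})

    registry = default_strain_registry()
    if n_strains is not None:
        if n_strains < len(registry):
            registry = registry.iloc[:n_strains].reset_index(drop=True)
        else:
            extra = [
                {"strain_id": f"essential_x{i:03d}", "strain_class": "essential"}
                for i in range(n_strains - len(registry))
            ]
            registry = pd.concat(
                [registry, pd.DataFrame.from_records(extra)], ignore_index=True
            )

    if n_parent_controls > 0:
        pc = [
            {"strain_id": f"parent_control_{i + 1:03d}", "strain_class": "parent_control"}
            for i in range(n_parent_controls)
        ]
        registry = pd.concat([registry, pd.DataFrame.from_records(pc)], ignore_index=True)

    mutualist_ids = set(mutualist_ids)
    unknown = mutualist_ids - set(registry["strain_id"])
    if unknown:
        raise ValueError(f"mutualist ids not in the registry: {sorted(unknown)}")
    if mutualist_ids and not {16.0, 48.0} <= set(float(t) for t in timepoints):
        raise ValueError("mutualist trajectories need both 16 and 48 hr timepoints")

    rng = np.random.default_rng(seed)
    n = len(registry)
    is_control = registry["strain_class"].isin(["control", "parent_control"]).to_numpy()

    base = 1.0 + rng.normal(0.0, spec["neutral_sd"], n)
    low = (rng.random(n) < spec["low_fraction"]) & ~is_control
    lo, hi = spec["low_fitness_range"]
    base[low] = rng.uniform(lo, hi, int(low.sum()))
    base[is_control] = 1.0

    t16, t48 = 16.0, 48.0
    b16, b48 = spec["mutualist_benefit_16"], spec["mutualist_benefit_48"]

    rows = []
    for i, strain in enumerate(registry.itertuples(index=False)):
        is_mut = strain.strain_id in mutualist_ids
        for medium in media:
            for induction in ("basal", "full"):
                for parent in ("matrix_proficient", "matrix_deficient"):
                    for t in timepoints:
                        benefit = 0.0
                        if is_mut and parent == "matrix_deficient":
                            benefit = b16 + (b48 - b16) * (float(t) - t16) / (t48 - t16)
                        mean = base[i] + benefit
                        vals = mean + rng.normal(
                            0.0, spec["replicate_sd"], n_replicates
                        )
                        for rep, v in enumerate(vals):
                            rows.append(
                                (
                                    strain.strain_id,
                                    strain.strain_class,
                                    medium,
                                    induction,
                                    parent,
                                    float(t),
                                    rep,
                                    max(float(v), 0.0),
                                    bool(low[i]),
                                    is_mut,
                                )
                            )
    return pd.DataFrame(
        rows,
        columns=[
            "strain_id",
            "strain_class",
            "medium",
            "induction",
            "parent_genotype",
            "time_hr",
            "replicate",
            "fitness",
            "true_low",
            "true_mutualist",
        ],
    )
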