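"""Two-strain nutrient-competition reaction-diffusion colony model.

Two cell types are inoculated together in a disc on an agar surface,
spread diffusively in two dimensions, and compete for a single diffusing
nutrient under Monod kinetics.  In nondimensional form (nutrient scaled
by its initial level n0, cell densities by n0/b where b is the
nutrient-to-biomass conversion factor):

    dC1/dt = M1 * n/(n + kappa) * C1 + DC * lap(C1)
    dC2/dt = M2 * n/(n + kappa) * C2 + DC * lap(C2)
    dn/dt  = -(M1*C1 + M2*C2) * n/(n + kappa) + Dn * lap(n)

with kappa = K/n0.  Growth converts nutrient to biomass one-to-one in
these units, so with no-flux boundaries the domain integral of
n + C1 + C2 is conserved — the solver's principal correctness check.

Model competitive fitness is the ratio of integrated cell densities
int C2 dA / int C1 dA; with identical initial conditions and M2 < M1 it
falls from 1 as the slower strain is outcompeted where nutrient runs
low.  Defaults encode a wild-type doubling time of 40 min (M1 = 0.0175
per min) and a 20% slower knockdown (M2/M1 = 0.8).

The solver is explicit forward Euler with a 5-point Laplacian on a
square Cartesian grid and reflecting (no-flux) boundaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace, field

import numpy as np
import pandas as pd

M1_DEFAULT = 0.0175  # 1/min; 40-min doubling time
GROWTH_RATE_RATIO_DEFAULT = 0.8  # M2/M1 for a 20% growth-rate deficit
DC_DEFAULT = 0.003 / 60.0  # mm^2/min (0.003 mm^2/hr)
DN_OVER_DC_DEFAULT = 100.0
KAPPA_DEFAULT = 0.05  # K/n0
C0BAR_DEFAULT = 1.0e-3  # C0 * b / n0, per strain inside the inoculum
R0_DEFAULT = 1.0  # mm


@dataclass(frozen=True)
class RDParams:
    """Model parameters; rates in 1/min, lengths in mm, times in min."""

    M1: float = M1_DEFAULT
    M2: float = M1_DEFAULT * GROWTH_RATE_RATIO_DEFAULT
    DC: float = DC_DEFAULT
    Dn: float = DC_DEFAULT * DN_OVER_DC_DEFAULT
    kappa: float = KAPPA_DEFAULT
    c0bar: float = C0BAR_DEFAULT
    r0: float = R0_DEFAULT
    domain_radius: float = 6.0
    dx: float = 0.05
    dt: float = 0.1

    def __post_init__(self) -> None:
        problems = []
        for name in ("M1", "M2", "DC", "Dn", "kappa", "c0bar"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if self.r0 <= 0 or self.r0 >= self.domain_radius:
            problems.append("need 0 < r0 < domain_radius")
        if self.dx <= 0 or self.dt <= 0:
            problems.append("dx and dt must be positive")
        dmax = max(self.DC, self.Dn)
        if dmax > 0 and self.dt > self.dx**2 / (4.0 * dmax):
            problems.append(
                f"dt={self.dt} violates the explicit-scheme stability bound "
                f"dx^2/(4 max(DC, Dn)) = {self.dx**2 / (4 * dmax):.4g}"
            )
        if problems:
            raise ValueError("invalid RD parameters: " + "; ".join(problems))

    def with_growth_ratio(self, ratio: float) -> "RDParams":
        """Same parameters with M2 = ratio * M1."""
        return replace(self, M2=ratio * self.M1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RDParams":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RDParams":
        """Load parameters from a JSON or YAML file keyed by field name."""
        text = open(path).read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass
class RDState:
    """Discretized fields on the square grid at time t (minutes)."""

    c1bar: np.ndarray
    c2bar: np.ndarray
    nbar: np.ndarray
    t: float = 0.0
    clipped_mass: float = 0.0  # cumulative mass removed by negativity clipping

    def copy(self) -> "RDState":
        return RDState(
            self.c1bar.copy(), self.c2bar.copy(), self.nbar.copy(), self.t,
            self.clipped_mass,
        )


def _grid_radii(params: RDParams) -> np.ndarray:
    """Radial coordinate of each cell center, origin at the domain center."""
    L = 2.0 * params.domain_radius
    n = int(round(L / params.dx))
    coords = (np.arange(n) + 0.5) * params.dx - L / 2.0
    return np.sqrt(coords[:, None] ** 2 + coords[None, :] ** 2)


def init_state(params: RDParams) -> RDState:
    """Uniform nutrient (nbar = 1) and each strain at density c0bar inside
    the inoculum disc of radius r0, with the disc edge anti-aliased over
    one grid cell to reduce grid artifacts."""
    r = _grid_radii(params)
    coverage = np.clip((params.r0 - r) / params.dx + 0.5, 0.0, 1.0)
    c = params.c0bar * coverage
    return RDState(
        c1bar=c.copy(), c2bar=c.copy(), nbar=np.ones_like(c), t=0.0
    )


def _laplacian(f: np.ndarray, dx: float) -> np.ndarray:
    """5-point Laplacian with reflecting (no-flux) boundaries."""
    p = np.pad(f, 1, mode="edge")
    return (
        p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * f
    ) / dx**2


def step(state: RDState, params: RDParams) -> RDState:
    """One explicit forward-Euler update, in place, returning the state.

    Negative undershoots (possible only at extreme parameters) are
    clipped to zero and their mass accumulated in ``clipped_mass``.
    """
    c1, c2, n = state.c1bar, state.c2bar, state.nbar
    monod = n / (n + params.kappa)
    g1 = params.M1 * monod * c1
    g2 = params.M2 * monod * c2
    dt, dx = params.dt, params.dx
    c1_new = c1 + dt * (g1 + params.DC * _laplacian(c1, dx))
    c2_new = c2 + dt * (g2 + params.DC * _laplacian(c2, dx))
    n_new = n + dt * (-(g1 + g2) + params.Dn * _laplacian(n, dx))
    clipped = 0.0
    for f in (c1_new, c2_new, n_new):
        neg = f < 0
        if neg.any():
            clipped += float(-f[neg].sum()) * dx**2
            f[neg] = 0.0
    state.c1bar, state.c2bar, state.nbar = c1_new, c2_new, n_new
    state.t += dt
    state.clipped_mass += clipped
    return state


def model_competitive_fitness(state: RDState) -> float:
    """int C2 dA / int C1 dA (the model's competitive-fitness readout)."""
    denom = float(state.c1bar.sum())
    if denom <= 0:
        raise ValueError("integral of C1 is zero; fitness undefined")
    return float(state.c2bar.sum()) / denom


def model_colony_radius(
    state: RDState, params: RDParams, fraction_of_max: float = 0.1
) -> float:
    """Colony radius (mm): the largest radius at which the azimuthally
    averaged total cell density C1 + C2 still exceeds ``fraction_of_max``
    of its radial maximum.  Returns 0 for an empty field."""
    total = state.c1bar + state.c2bar
    if float(total.max()) <= 0.0:
        return 0.0
    r = _grid_radii(params)
    nbins = int(math.ceil(r.max() / params.dx)) + 1
    idx = np.minimum((r / params.dx).astype(int), nbins - 1)
    sums = np.bincount(idx.ravel(), weights=total.ravel(), minlength=nbins)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    profile = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    above = np.nonzero(profile > fraction_of_max * profile.max())[0]
    if len(above) == 0:
        return 0.0
    return float((above[-1] + 0.5) * params.dx)


def _summary(state: RDState, params: RDParams) -> dict:
    dA = params.dx**2
    return {
        "t_min": state.t,
        "fitness": model_competitive_fitness(state),
        "radius_mm": model_colony_radius(state, params),
        "c1_integral": float(state.c1bar.sum()) * dA,
        "c2_integral": float(state.c2bar.sum()) * dA,
        "n_min": float(state.nbar.min()),
        "total_mass": float(
            (state.nbar + state.c1bar + state.c2bar).sum()
        )
        * dA,
        "clipped_mass": state.clipped_mass,
    }


def run_simulation(
    params: RDParams,
    duration: float = 960.0,
    record_times=None,
    record_every: float | None = None,
    return_state: bool = False,
):
    """Integrate the model for ``duration`` minutes, recording summaries.

    ``record_times`` (minutes) or ``record_every`` selects when the
    fitness, colony radius, field integrals and nutrient minimum are
    recorded; by default only t=0 and the endpoint.  The model is fully
    deterministic.  Raises on numerical blow-up (advising a smaller dt).

    Returns a summary DataFrame, plus the final state when
    ``return_state`` is set.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_steps = int(round(duration / params.dt))
    if record_times is None:
        if record_every is not None:
            record_times = np.arange(0.0, duration + params.dt / 2, record_every)
        else:
            record_times = [0.0, duration]
    record_steps = sorted({int(round(t / params.dt)) for t in record_times})

    state = init_state(params)
    rows = []
    if 0 in record_steps:
        rows.append(_summary(state, params))
    for k in range(1, n_steps + 1):
        step(state, params)
        if k in record_steps:
            if not np.isfinite(state.nbar).all() or not np.isfinite(state.c1bar).all():
                raise RuntimeError(
                    f"solution diverged by t={state.t:.1f} min; reduce dt "
                    f"(current dt={params.dt})"
                )
            rows.append(_summary(state, params))
    if np.abs(state.c1bar).max() > 1e12:
        raise RuntimeError("solution diverged; reduce dt")
    traj = pd.DataFrame(rows)
    return (traj, state) if return_state else traj
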