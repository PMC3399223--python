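"""Chemocline geochemistry: profile interpolation, diffusive fluxes,
NOx/sulfide overlap detection, and 15N-incubation N2-production rates.

Chemical profiles in strongly stratified basins align on potential density
(sigma-theta) rather than depth, so profiles carry both ordinates: density
for alignment and reporting, depth (m) for gradients and fluxes.

Incubation rates: adding 15N-labeled nitrate to an anoxic sample lets
denitrification of the labeled pool produce 30N2 (both atoms labeled),
while anammox — pairing one labeled nitrite-derived N with one unlabeled
ammonium N — produces 29N2.  The per-mil excess of a mass over its control
converts to a concentration of labeled N2 through the natural isotopologue
ratio of the background N2 pool, and then to a rate over the incubation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86400.0
#: 15N/(14N+15N) atom fraction of atmospheric N2 (air standard).
NATURAL_15N_FRACTION = 0.003663

#: Default analyte detection limits, in µM.
DETECTION_LIMITS = {"O2": 1.0, "H2S": 3.0, "NO3": 0.05, "NO2": 0.02, "NH4": 0.1}


@dataclass(frozen=True)
class ChemProfile:
    """Depth-resolved chemistry of one station/year.

    ``samples`` must carry ``depth_m`` (strictly increasing) and
    ``sigma_theta`` (non-decreasing) columns plus one column per analyte
    (concentrations in µM; particulate Mn in any consistent unit).
    """

    station: str
    year: int
    samples: pd.DataFrame
    detection_limits: dict = field(default_factory=lambda: dict(DETECTION_LIMITS))

    def __post_init__(self) -> None:
        df = self.samples
        for col in ("depth_m", "sigma_theta"):
            if col not in df.columns:
                raise ValueError(f"profile is missing column {col!r}")
        depth = df["depth_m"].to_numpy(dtype=float)
        sigma = df["sigma_theta"].to_numpy(dtype=float)
        if len(depth) and not (np.diff(depth) > 0).all():
            raise ValueError("depth_m must be strictly increasing")
        if len(sigma) and not (np.diff(sigma) >= 0).all():
            raise ValueError("sigma_theta must be non-decreasing")

    @property
    def analytes(self) -> list[str]:
        return [c for c in self.samples.columns if c not in ("depth_m", "sigma_theta")]


def interpolate(
    profile: ChemProfile,
    analyte: str,
    grid: Sequence[float],
    ordinate: Literal["depth", "sigma_theta"] = "sigma_theta",
) -> np.ndarray:
    """Piecewise-linear interpolation of an analyte onto *grid*.

    Extrapolation is refused: every grid point must lie within the sampled
    ordinate range.
    """
    col = "depth_m" if ordinate == "depth" else "sigma_theta"
    if ordinate not in ("depth", "sigma_theta"):
        raise ValueError(f"unknown ordinate {ordinate!r}")
    if analyte not in profile.samples.columns:
        raise ValueError(f"analyte {analyte!r} not in profile")
    x = profile.samples[col].to_numpy(dtype=float)
    y = profile.samples[analyte].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 samples to interpolate")
    grid = np.asarray(grid, dtype=float)
    if grid.min() < x.min() - 1e-12 or grid.max() > x.max() + 1e-12:
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] extends outside the sampled "
            f"{ordinate} range [{x.min()}, {x.max()}]; extrapolation refused"
        )
    return np.interp(grid, x, y)


@dataclass(frozen=True)
class FluxResult:
    flux: float  # µmol m^-2 day^-1, magnitude
    direction: str  # "up" (toward shallower) or "down"
    gradient: float  # dC/dz in µM per m, signed


def diffusive_flux(
    profile: ChemProfile,
    analyte: str,
    interval: tuple[float, float],
    K: float,
) -> FluxResult:
    """Fick's-law diffusive flux over a depth interval.

    ``F = K * |dC/dz| * 86400`` with concentrations converted from µM to
    µmol m^-3 (x1000) and the gradient taken between the interpolated
    concentrations at the interval ends (depths in m).  ``K`` is the
    (turbulent) diffusion coefficient in m^2 s^-1, user-supplied per
    density layer.  Flux is directed toward decreasing concentration.
    """
    z1, z2 = interval
    if not z1 < z2:
        raise ValueError("interval must satisfy z1 < z2")
    if K <= 0:
        raise ValueError("K must be positive")
    c1, c2 = interpolate(profile, analyte, [z1, z2], ordinate="depth")
    grad = (c2 - c1) / (z2 - z1)  # µM per m, positive = increasing with depth
    flux = K * abs(grad) * 1000.0 * SECONDS_PER_DAY
    direction = "up" if grad > 0 else "down"
    return FluxResult(flux=float(flux), direction=direction, gradient=float(grad))


@dataclass(frozen=True)
class OverlapResult:
    overlap_intervals: tuple[tuple[float, float], ...]  # both above detection
    gap_interval: tuple[float, float] | None  # both below detection
    possible_overlap: bool
    grid_step: float


def _mask_intervals(grid: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    intervals = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = grid[i]
        elif not flag and start is not None:
            intervals.append((float(start), float(grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(start), float(grid[-1])))
    return intervals


def overlap_zone(
    nox: ChemProfile,
    sulfide: ChemProfile,
    nox_analytes: Sequence[str] = ("NO3", "NO2"),
    sulfide_analyte: str = "H2S",
    detection_limits: dict | None = None,
    grid_step: float = 0.005,
    max_gap: float = 0.15,
) -> OverlapResult:
    """Density interval(s) where NOx and sulfide are both above detection.

    Profiles are interpolated onto a common sigma-theta grid.  Also
    reported: the gap interval between the deepest NOx detection and the
    shallowest sulfide detection where both are below detection, and a
    ``possible_overlap`` flag set when that gap is narrower than
    ``max_gap`` density units (below-detection concentrations could then
    co-occur within the detection limits).
    """
    if nox.station != sulfide.station or nox.year != sulfide.year:
        raise ValueError("profiles must share station and year")
    limits = dict(DETECTION_LIMITS)
    limits.update(nox.detection_limits)
    if detection_limits:
        limits.update(detection_limits)
    lo = max(nox.samples["sigma_theta"].min(), sulfide.samples["sigma_theta"].min())
    hi = min(nox.samples["sigma_theta"].max(), sulfide.samples["sigma_theta"].max())
    if not lo < hi:
        raise ValueError("profiles cover disjoint sigma_theta ranges")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    nox_above = np.zeros(len(grid), dtype=bool)
    for analyte in nox_analytes:
        if analyte in nox.samples.columns:
            conc = interpolate(nox, analyte, grid)
            nox_above |= conc > limits.get(analyte, 0.0)
    s_conc = interpolate(sulfide, sulfide_analyte, grid)
    s_above = s_conc > limits.get(sulfide_analyte, 0.0)

    overlap = _mask_intervals(grid, nox_above & s_above)
    gap = None
    possible = bool(overlap)
    if not overlap and nox_above.any() and s_above.any():
        deepest_nox = grid[nox_above][-1]
        shallowest_s = grid[s_above][0]
        if shallowest_s > deepest_nox:
            gap = (float(deepest_nox), float(shallowest_s))
            possible = (shallowest_s - deepest_nox) < max_gap
    return OverlapResult(
        overlap_intervals=tuple(overlap),
        gap_interval=gap,
        possible_overlap=possible,
        grid_step=grid_step,
    )


@dataclass(frozen=True)
class IncubationResult:
    """Endpoint of one 15NO3- incubation (sample and killed control)."""

    sigma_theta: float
    depth_m: float
    spike_uM: float
    duration_days: float
    delta30_sample: float
    delta30_control: float
    delta29_sample: float
    delta29_control: float
    no2_uM: float | None = None
    nh4_uM: float | None = None

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")
        if self.spike_uM < 0:
            raise ValueError("spike must be non-negative")


@dataclass(frozen=True)
class RateConfig:
    """Constants for converting per-mil enrichments to rates.

    ``n2_background_uM``: dissolved N2 of the incubated water (µM; deep
    Black Sea waters hold roughly 500 µM).  ``natural_15n_fraction``: atom
    fraction of 15N in the unlabeled pool (air standard).
    ``labeled_fraction``: 15N fraction of the NO3- pool after spiking (27
    µM spike into <= ~3 µM ambient nitrate gives >= 0.9).  ``mode``:
    "raw_p30" reports the rate of labeled-pair production as-is;
    "pairing_corrected" divides by the squared (30N2) or single (29N2)
    labeled fraction to estimate total N2 production under random isotope
    pairing.
    """

    n2_background_uM: float = 500.0
    natural_15n_fraction: float = NATURAL_15N_FRACTION
    labeled_fraction: float = 1.0
    mode: Literal["raw_p30", "pairing_corrected"] = "raw_p30"

    def __post_init__(self) -> None:
        if not 0 <= self.natural_15n_fraction <= 1:
            raise ValueError("natural_15n_fraction must be in [0, 1]")
        if not 0 <= self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must be in [0, 1]")
        if self.n2_background_uM <= 0:
            raise ValueError("n2_background_uM must be positive")

    @property
    def r30(self) -> float:
        """Natural 30N2 abundance ratio, x^2 for atom fraction x."""
        x = self.natural_15n_fraction
        return x**2

    @property
    def r29(self) -> float:
        """Natural 29N2/28N2 abundance ratio, 2x(1-x)/(1-x)^2."""
        x = self.natural_15n_fraction
        return 2.0 * x * (1.0 - x) / (1.0 - x) ** 2


def excess_delta(sample_delta: float, control_delta: float) -> float:
    """Per-mil excess of a sample over its control; negative excess is
    floored at 0 with a warning (no consumption model)."""
    if sample_delta is None or control_delta is None or np.isnan(control_delta):
        raise ValueError("missing control delta")
    excess = sample_delta - control_delta
    if excess < 0:
        warnings.warn(
            f"negative excess ({excess:.3g} per mil) floored at 0; "
            "isotopologue consumption is not modeled"
        )
        return 0.0
    return float(excess)


def n2_production_rate(
    excess_delta30: float,
    config: RateConfig,
    duration_days: float,
) -> float:
    """Denitrification rate from excess 30N2, in nM N per day.

    excess [30N2] = (excess_delta30 / 1000) * R30 * [N2]background, with
    R30 the natural 30N2/28N2 ratio; the rate counts N atoms (2 per N2)
    over the incubation.  In "pairing_corrected" mode the labeled-pair
    rate is divided by the squared labeled fraction of the NO3- pool.
    """
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    excess30_uM = (excess_delta30 / 1000.0) * config.r30 * config.n2_background_uM
    rate = 2.0 * excess30_uM * 1000.0 / duration_days  # nM N / day
    if config.mode == "pairing_corrected":
        if config.labeled_fraction == 0:
            raise ValueError("labeled_fraction must be > 0 in pairing_corrected mode")
        rate /= config.labeled_fraction**2
    return float(rate)


@dataclass(frozen=True)
class AnammoxSignal:
    rate: float  # nM N / day
    ambiguous: bool
    note: str


def anammox_signal(
    excess_delta29: float,
    config: RateConfig,
    duration_days: float,
) -> AnammoxSignal:
    """N2 production attributed to 29N2 (single-labeled pairs), nM N/day.

    29N2 production in a 15NO3- incubation is the usual anammox signal,
    but it can equally arise from denitrification of small amounts of
    unlabeled NOx-, so the result always carries an ambiguity flag.  In
    "pairing_corrected" mode the rate is divided by the labeled fraction
    (one labeled atom per 29N2 pair).
    """
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    excess29_uM = (excess_delta29 / 1000.0) * config.r29 * config.n2_background_uM
    rate = 2.0 * excess29_uM * 1000.0 / duration_days
    if config.mode == "pairing_corrected":
        if config.labeled_fraction == 0:
            raise ValueError("labeled_fraction must be > 0 in pairing_corrected mode")
        rate /= config.labeled_fraction
    return AnammoxSignal(
        rate=float(rate),
        ambiguous=True,
        note="29N2 excess may reflect denitrification of unspiked NOx- rather than anammox",
    )


def incubation_rates(
    results: Sequence[IncubationResult],
    config: RateConfig,
) -> pd.DataFrame:
    """Rate table for a set of incubations (one row per endpoint)."""
    rows = []
    for res in results:
        e30 = excess_delta(res.delta30_sample, res.delta30_control)
        e29 = excess_delta(res.delta29_sample, res.delta29_control)
        rows.append(
            {
                "sigma_theta": res.sigma_theta,
                "depth_m": res.depth_m,
                "excess_delta30": e30,
                "excess_delta29": e29,
                "denitrification_nM_N_day": n2_production_rate(e30, config, res.duration_days),
                "anammox_signal_nM_N_day": anammox_signal(e29, config, res.duration_days).rate,
                "anammox_ambiguous": True,
            }
        )
    return pd.DataFrame(rows)
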