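"""TRFLP profile data model: reading, normalization, minor-peak filtering,
and frame-shifted binning.

A profile is the list of (fragment length, peak height) pairs one enzyme
produced for one sample.  Heights are normalized per profile; peaks under a
fraction of the profile total (0.3% by default) are dropped as noise; the
surviving mass is binned into 2-bp bins in four frames offset by 0.5 bp, so
that sub-bp electrophoresis drift cannot split one fragment across a bin
edge in every frame at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PEAK_TABLE_COLUMNS = [
    "sample_id",
    "station",
    "year",
    "sigma_theta",
    "enzyme",
    "fragment_bp",
    "height_rfu",
]


@dataclass(frozen=True)
class Peak:
    fragment_bp: float
    height_rfu: float

    def __post_init__(self) -> None:
        if not self.fragment_bp > 0:
            raise ValueError(f"fragment_bp must be positive, got {self.fragment_bp}")
        if self.height_rfu < 0:
            raise ValueError(f"height_rfu must be non-negative, got {self.height_rfu}")


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-reproducibility error of a fingerprinting run.

    ``sigma_height`` is the height sd in rfu at a profile total of
    ``reference_total`` rfu (the sd scales proportionally with the total);
    ``sigma_bp`` is the fragment-sizing sd in bp.  Defaults are the
    duplicate-profile errors of the bacterial (27F) runs: +/-46 rfu at
    18,000 rfu total and +/-0.08 bp.  The Planctomycetes (58F) runs use
    +/-83 rfu at 15,000 rfu and +/-0.06 bp.
    """

    sigma_height: float = 46.0
    reference_total: float = 18000.0
    sigma_bp: float = 0.08

    def __post_init__(self) -> None:
        if self.sigma_height < 0 or self.sigma_bp < 0 or self.reference_total <= 0:
            raise ValueError("noise parameters must be non-negative (reference_total > 0)")


PLANCTOMYCETES_NOISE = NoiseModel(sigma_height=83.0, reference_total=15000.0, sigma_bp=0.06)


@dataclass(frozen=True)
class TRFLPProfile:
    sample_id: str
    enzyme: str
    peaks: tuple[Peak, ...]
    station: str = ""
    year: int | None = None
    sigma_theta: float | None = None

    def __post_init__(self) -> None:
        peaks = tuple(sorted(self.peaks, key=lambda p: p.fragment_bp))
        object.__setattr__(self, "peaks", peaks)

    @property
    def total_height(self) -> float:
        return float(sum(p.height_rfu for p in self.peaks))

    @property
    def fragment_lengths(self) -> np.ndarray:
        return np.array([p.fragment_bp for p in self.peaks])

    @property
    def heights(self) -> np.ndarray:
        return np.array([p.height_rfu for p in self.peaks])

    def with_peaks(self, peaks: Iterable[Peak]) -> "TRFLPProfile":
        return replace(self, peaks=tuple(peaks))


@dataclass(frozen=True)
class BinnedMatrix:
    """Sample x bin relative abundances for one binning frame.

    Bins are half-open ``[edge, edge + bin_width)``; ``bins`` holds the
    ordered lower edges.  Rows sum to 1 whenever any peaks survived
    filtering.
    """

    frame_offset: float
    bin_width: float
    bins: np.ndarray
    abundance: pd.DataFrame  # index: sample_id, columns: bin lower edges

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)


def read_peak_table(path) -> list[TRFLPProfile]:
    """Read a delimited peak table into profiles grouped by (sample, enzyme).

    The table must carry the columns
    ``sample_id, station, year, sigma_theta, enzyme, fragment_bp, height_rfu``
    (tab- or comma-delimited, sniffed from the header line).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        return []
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table {path} is missing columns {missing}")
    profiles = []
    for (sample, enzyme), grp in df.groupby(["sample_id", "enzyme"], sort=True):
        peaks = []
        for idx, row in grp.iterrows():
            try:
                peaks.append(Peak(float(row["fragment_bp"]), float(row["height_rfu"])))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"unparseable peak in row {idx} of {path}: {exc}") from exc
        first = grp.iloc[0]
        profiles.append(
            TRFLPProfile(
                sample_id=str(sample),
                enzyme=str(enzyme),
                peaks=tuple(peaks),
                station=str(first["station"]),
                year=int(first["year"]),
                sigma_theta=float(first["sigma_theta"]),
            )
        )
    return profiles


def write_peak_table(profiles: Sequence[TRFLPProfile], path, sep: str = "\t") -> None:
    rows = []
    for prof in profiles:
        for peak in prof.peaks:
            rows.append(
                {
                    "sample_id": prof.sample_id,
                    "station": prof.station,
                    "year": prof.year,
                    "sigma_theta": prof.sigma_theta,
                    "enzyme": prof.enzyme,
                    "fragment_bp": peak.fragment_bp,
                    "height_rfu": peak.height_rfu,
                }
            )
    # 2 decimals: far below the +/-0.08 bp / +/-46 rfu measurement error
    pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS).to_csv(
        path, sep=sep, index=False, float_format="%.2f"
    )


def normalize(profile: TRFLPProfile) -> TRFLPProfile:
    """Divide every height by the profile total so heights sum to 1."""
    total = profile.total_height
    if total <= 0:
        raise ValueError(f"profile {profile.sample_id}/{profile.enzyme} has zero total height")
    return profile.with_peaks(Peak(p.fragment_bp, p.height_rfu / total) for p in profile.peaks)


def filter_minor_peaks(
    profile: TRFLPProfile, threshold: float = 0.003
) -> tuple[TRFLPProfile, int]:
    """Drop peaks below ``threshold`` of the profile total; re-normalize.

    Returns the filtered (normalized) profile and the number of peaks
    removed.  The threshold is a fraction of this profile's own total, so
    the operation commutes with normalization.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    total = profile.total_height
    if total <= 0:
        raise ValueError(f"profile {profile.sample_id}/{profile.enzyme} has zero total height")
    kept = [p for p in profile.peaks if p.height_rfu >= threshold * total]
    removed = len(profile.peaks) - len(kept)
    if not kept:
        return profile.with_peaks([]), removed
    return normalize(profile.with_peaks(kept)), removed


def _bin_edge(bp: float, offset: float, width: float) -> float:
    k = math.floor((bp - offset) / width)
    return offset + k * width


def bin_frames(
    profiles: Sequence[TRFLPProfile],
    bin_width: float = 2.0,
    offsets: Sequence[float] = (0.0, 0.5, 1.0, 1.5),
) -> list[BinnedMatrix]:
    """Bin a set of same-enzyme profiles into one matrix per frame.

    Each frame's bins are ``[offset + k*width, offset + (k+1)*width)``;
    peak mass (normalized height) goes to the unique bin containing its
    fragment length, boundary peaks to the upper bin.  Mass is conserved
    per sample in every frame.
    """
    if not profiles:
        raise ValueError("no profiles to bin")
    enzymes = {p.enzyme for p in profiles}
    if len(enzymes) > 1:
        raise ValueError(f"profiles must share an enzyme, got {sorted(enzymes)}")
    if any(off >= bin_width for off in offsets):
        raise ValueError("offsets must be smaller than bin_width")

    matrices = []
    sample_ids = [p.sample_id for p in profiles]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id within one enzyme's profile set")
    for offset in offsets:
        masses: dict[str, dict[float, float]] = {}
        for prof in profiles:
            total = prof.total_height
            row: dict[float, float] = {}
            if total > 0:
                for peak in prof.peaks:
                    edge = _bin_edge(peak.fragment_bp, offset, bin_width)
                    row[edge] = row.get(edge, 0.0) + peak.height_rfu / total
            masses[prof.sample_id] = row
        edges = sorted({e for row in masses.values() for e in row})
        abundance = pd.DataFrame(0.0, index=sample_ids, columns=edges)
        for sid, row in masses.items():
            for edge, mass in row.items():
                abundance.loc[sid, edge] = mass
        matrices.append(
            BinnedMatrix(
                frame_offset=float(offset),
                bin_width=float(bin_width),
                bins=np.array(edges, dtype=float),
                abundance=abundance,
            )
        )
    return matrices
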