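"""Topographic motor-map construction and metrics.

From one background-corrected amplitude per grid site, a map is built by
normalising to the hot spot (the site with the largest amplitude) and removing
sites below 25% of the peak.  On the thresholded, normalised map:

* **CoG** (centre of gravity): amplitude-weighted centroid,
  ``CoG_x = sum(z_i x_i) / sum(z_i)`` (likewise y), in grid cm.
* **CoG vector**: Euclidean norm of the CoG coordinates (distance from the
  midline/vertex origin).
* **Map volume**: sum of normalised amplitudes -- a total-excitability index.
* **Map area**: number of active (supra-threshold) sites.
* **Overlap**: Jaccard index of two muscles' active masks -- shared sites over
  the union of active sites.
* **CoG variation**: per-subject distance of the CoG from the group-mean CoG,
  separately per axis and as a vector -- the between-subject heterogeneity
  index.

Boundary convention: a site at exactly 25% of the peak is kept (only sites
strictly below threshold are removed); both the removal fraction and the
convention are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grid import GridSpec
from .mep import SiteAmplitude

__all__ = [
    "MotorMap",
    "MapMetrics",
    "CoGDeviation",
    "OverlapResult",
    "build_map",
    "map_from_site_amplitudes",
    "cog",
    "cog_vector",
    "map_volume",
    "map_area",
    "map_metrics",
    "map_overlap",
    "cog_variation",
    "average_group_map",
]


@dataclass
class MotorMap:
    """One muscle's normalised, thresholded amplitude map on the grid.

    ``z`` holds normalised amplitudes in [0, 1] (0 where inactive); the hot
    spot has z = 1 whenever any site is active.  ``raw_peak_uV`` preserves the
    pre-normalisation hot-spot amplitude.
    """

    grid: GridSpec
    z: np.ndarray  # (n_rows, n_cols)
    active_mask: np.ndarray  # bool, same shape
    raw_peak_uV: float
    subject_id: str = ""
    muscle: str = ""

    @property
    def any_active(self) -> bool:
        return bool(self.active_mask.any())


@dataclass(frozen=True)
class MapMetrics:
    """Scalar map statistics for one subject-muscle."""

    cog_x: float
    cog_y: float
    cog_vector: float
    volume: float
    area: int


@dataclass(frozen=True)
class CoGDeviation:
    """Per-subject CoG deviation from the group-mean CoG (all in cm, >= 0)."""

    subject_id: str
    muscle: str
    dev_x: float
    dev_y: float
    dev_vector: float


@dataclass(frozen=True)
class OverlapResult:
    muscle_pair: tuple[str, str]
    overlap: float


def build_map(
    amplitudes: np.ndarray,
    grid: GridSpec,
    threshold_fraction: float = 0.25,
    *,
    subject_id: str = "",
    muscle: str = "",
) -> MotorMap:
    """Normalise site amplitudes to the hot spot and apply the removal rule.

    ``amplitudes`` is a (n_rows, n_cols) array of µV.  Sites with normalised
    amplitude strictly below ``threshold_fraction`` are removed (set to 0,
    inactive).  A map with no positive amplitude is returned all-inactive.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != grid.shape:
        raise ValueError(f"expected amplitude array of shape {grid.shape}, got {amplitudes.shape}")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be non-negative")
    peak = float(amplitudes.max())
    if peak <= 0:
        return MotorMap(
            grid=grid,
            z=np.zeros(grid.shape),
            active_mask=np.zeros(grid.shape, dtype=bool),
            raw_peak_uV=0.0,
            subject_id=subject_id,
            muscle=muscle,
        )
    z = amplitudes / peak
    active = z >= threshold_fraction
    z = np.where(active, z, 0.0)
    return MotorMap(
        grid=grid, z=z, active_mask=active, raw_peak_uV=peak,
        subject_id=subject_id, muscle=muscle,
    )


def map_from_site_amplitudes(
    amplitudes: Sequence[SiteAmplitude],
    grid: GridSpec,
    threshold_fraction: float = 0.25,
) -> MotorMap:
    """Build a map from per-site amplitude records (one per grid site)."""
    if len(amplitudes) != grid.n_sites:
        raise ValueError(f"expected {grid.n_sites} site amplitudes, got {len(amplitudes)}")
    arr = np.full(grid.shape, np.nan)
    for a in amplitudes:
        col, row = a.site
        arr[row, col] = a.mean_amplitude_uV
    if np.isnan(arr).any():
        raise ValueError("duplicate or missing grid sites in amplitude list")
    ref = amplitudes[0]
    return build_map(
        arr, grid, threshold_fraction, subject_id=ref.subject_id, muscle=ref.muscle
    )


def cog(m: MotorMap) -> tuple[float, float]:
    """Amplitude-weighted centroid of the active map, in grid cm."""
    if not m.any_active:
        raise ValueError("CoG undefined: map has no active sites")
    X, Y = m.grid.meshgrid()
    w = m.z.sum()
    return float((m.z * X).sum() / w), float((m.z * Y).sum() / w)


def cog_vector(c: tuple[float, float]) -> float:
    """Euclidean norm of the CoG coordinate pair (cm from the midline/vertex origin)."""
    return float(np.hypot(c[0], c[1]))


def map_volume(m: MotorMap) -> float:
    """Sum of normalised amplitudes over the (thresholded) map."""
    return float(m.z.sum())


def map_area(m: MotorMap) -> int:
    """Number of active sites (amplitude at or above the hot-spot fraction)."""
    return int(m.active_mask.sum())


def map_metrics(m: MotorMap) -> MapMetrics:
    """All scalar metrics of one map (CoG requires at least one active site)."""
    cx, cy = cog(m)
    return MapMetrics(
        cog_x=cx, cog_y=cy, cog_vector=cog_vector((cx, cy)),
        volume=map_volume(m), area=map_area(m),
    )


def map_overlap(map_a: MotorMap, map_b: MotorMap) -> OverlapResult:
    """Jaccard overlap of two muscles' active masks.

    Shared active sites as a proportion of the union (total active across both
    muscles minus the shared area).  Defined as 0 when both maps are empty.
    """
    if map_a.grid != map_b.grid:
        raise ValueError("maps are on different grids")
    a = map_a.active_mask
    b = map_b.active_mask
    inter = int((a & b).sum())
    union = int(a.sum()) + int(b.sum()) - inter
    return OverlapResult(
        muscle_pair=(map_a.muscle, map_b.muscle),
        overlap=inter / union if union > 0 else 0.0,
    )


def cog_variation(
    cogs: Sequence[tuple[float, float]],
    subject_ids: Sequence[str] | None = None,
    muscle: str = "",
) -> tuple[list[CoGDeviation], dict[str, tuple[float, float]]]:
    """Per-subject CoG deviations from the group-mean CoG, plus group summary.

    The group mean CoG is the arithmetic mean of the coordinates; deviations
    are |x_i - mean_x|, |y_i - mean_y| and the Euclidean distance to the mean.
    Returns ``(deviations, summary)`` where summary maps ``dev_x``/``dev_y``/
    ``dev_vector`` to (mean, SD) across subjects.
    """
    arr = np.asarray(cogs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("cogs must be a sequence of (x, y) pairs")
    if arr.shape[0] < 2:
        raise ValueError("CoG variation requires at least 2 subjects")
    if subject_ids is None:
        subject_ids = [f"s{i + 1}" for i in range(arr.shape[0])]
    mean = arr.mean(axis=0)
    dx = np.abs(arr[:, 0] - mean[0])
    dy = np.abs(arr[:, 1] - mean[1])
    dv = np.hypot(arr[:, 0] - mean[0], arr[:, 1] - mean[1])
    devs = [
        CoGDeviation(subject_id=sid, muscle=muscle, dev_x=float(a), dev_y=float(b), dev_vector=float(v))
        for sid, a, b, v in zip(subject_ids, dx, dy, dv)
    ]
    summary = {
        "dev_x": (float(dx.mean()), float(dx.std(ddof=1))),
        "dev_y": (float(dy.mean()), float(dy.std(ddof=1))),
        "dev_vector": (float(dv.mean()), float(dv.std(ddof=1))),
    }
    return devs, summary


def average_group_map(maps: Sequence[MotorMap]) -> np.ndarray:
    """Per-site mean of normalised maps (the group-average map).

    The peak of the average is <= 1, with equality iff every subject shares the
    same hot-spot site; flat averages indicate high variation of peak location.
    """
    if not maps:
        raise ValueError("average_group_map requires at least one map")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid != grid:
            raise ValueError("maps are on different grids")
    return np.mean([m.z for m in maps], axis=0)
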