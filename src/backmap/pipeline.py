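"""End-to-end analysis: sweeps -> site amplitudes -> maps -> metrics -> stats.

The pipeline mirrors the mapping study's processing chain.  For each
subject-muscle: every sweep is background-corrected (MEP RMS minus pre-stimulus
RMS, detected window), amplitudes are averaged per site, the channel is
quality-checked, a normalised thresholded map is built and its metrics
computed.  Group-level CoG variation is then derived per group-muscle, map
overlaps per subject for each muscle pair, and the whole metric table can be
fed to :func:`backmap.stats.run_group_report`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec, default_grid
from .mapping import (
    MotorMap,
    average_group_map,
    build_map,
    cog,
    cog_variation,
    cog_vector,
    map_area,
    map_overlap,
    map_volume,
)
from .mep import DetectionParams, SiteAmplitude, channel_qc, sweep_array_amplitudes
from .simulate import Cohort

logger = logging.getLogger("backmap")

__all__ = ["PipelineConfig", "ChannelResult", "CohortResult", "process_channel_array", "analyze_cohort"]


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis-side settings (the acquisition side lives in SimulationConfig)."""

    grid: GridSpec = field(default_factory=default_grid)
    threshold_fraction: float = 0.25
    background_window_ms: tuple[float, float] = (-500.0, -5.0)
    detection: DetectionParams = field(default_factory=DetectionParams)
    alpha: float = 0.05
    variance_gate: Optional[str] = None  # None = Levene gate; "classic"/"welch" force
    qc_background_ceiling_uV: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        t0, t1 = self.background_window_ms
        if not t0 < t1 <= 0:
            raise ValueError("background window must be strictly pre-stimulus")


@dataclass
class ChannelResult:
    """Per-subject-muscle outcome: site amplitudes, QC verdict, map."""

    subject_id: str
    muscle: str
    amplitudes: list[SiteAmplitude]
    qc: str
    map: Optional[MotorMap]


def process_channel_array(
    arr: np.ndarray,
    fs: float,
    stim: int,
    grid: GridSpec,
    subject_id: str,
    muscle: str,
    config: PipelineConfig,
) -> ChannelResult:
    """Process all sweeps of one subject-muscle.

    ``arr`` has shape (n_sites, n_stimuli, n_samples) with sites in row-major
    (row, col) order; the heavy per-sweep work is vectorised.
    """
    n_sites, n_stim, n_samp = arr.shape
    if n_sites != grid.n_sites:
        raise ValueError(f"expected {grid.n_sites} sites, got {n_sites}")
    det = DetectionParams(
        k=config.detection.k,
        min_duration_ms=config.detection.min_duration_ms,
        latency_band_ms=config.detection.latency_band_ms,
        smooth_ms=config.detection.smooth_ms,
        background_window_ms=config.background_window_ms,
    )
    flat = arr.reshape(n_sites * n_stim, n_samp)
    amps, found = sweep_array_amplitudes(flat, fs, stim, det)
    amps = amps.reshape(n_sites, n_stim)
    found = found.reshape(n_sites, n_stim)
    sl = slice(
        stim + int(round(config.background_window_ms[0] * fs / 1000.0)),
        stim + int(round(config.background_window_ms[1] * fs / 1000.0)),
    )
    bg = np.sqrt(np.mean(flat[:, sl] ** 2, axis=1))
    site_amps = []
    for s in range(n_sites):
        row, col = divmod(s, grid.n_cols)
        used = found[s]
        site_amps.append(
            SiteAmplitude(
                subject_id=subject_id,
                muscle=muscle,
                site=(col, row),
                mean_amplitude_uV=float(amps[s, used].mean()) if used.any() else 0.0,
                n_stimuli_used=int(used.sum()),
            )
        )
    qc = channel_qc(site_amps, bg, background_ceiling_uV=config.qc_background_ceiling_uV)
    mm = None
    if qc == "usable":
        grid_amps = np.array([a.mean_amplitude_uV for a in site_amps]).reshape(grid.shape)
        mm = build_map(
            grid_amps, grid, config.threshold_fraction, subject_id=subject_id, muscle=muscle
        )
        if not mm.any_active:
            qc = "no-mep"
            mm = None
    return ChannelResult(subject_id=subject_id, muscle=muscle, amplitudes=site_amps, qc=qc, map=mm)


@dataclass
class CohortResult:
    """Analysis output for a cohort.

    ``metrics``: long DataFrame (subject_id, group, variable, value) ready for
    :func:`backmap.stats.run_group_report`; ``maps``: per (subject, muscle)
    MotorMap; ``qc``: DataFrame of channel verdicts; ``group_maps``: group ->
    muscle -> average map array.
    """

    metrics: pd.DataFrame
    maps: dict[tuple[str, str], MotorMap]
    qc: pd.DataFrame
    group_maps: dict[str, dict[str, np.ndarray]]


def analyze_cohort(
    cohort: Cohort,
    config: PipelineConfig | None = None,
    muscles: Sequence[str] | None = None,
) -> CohortResult:
    """Run the full analysis chain on a simulated (or loaded) cohort.

    Channels failing QC are dropped from downstream metrics (their subjects
    keep reduced per-muscle n, as in real recordings where channels are
    rejected).  CoG variation is computed per group-muscle over usable maps.
    """
    config = config or PipelineConfig(grid=cohort.grid)
    muscles = tuple(muscles or cohort.muscles)
    fs = cohort.config.sampling_rate
    stim = cohort.config.stimulus_index

    maps: dict[tuple[str, str], MotorMap] = {}
    qc_rows = []
    metric_rows = []
    for subject in cohort.subjects:
        for muscle in muscles:
            arr = cohort.sweep_array(subject, muscle)
            res = process_channel_array(arr, fs, stim, cohort.grid, subject.subject_id, muscle, config)
            qc_rows.append({"subject_id": subject.subject_id, "group": subject.group, "muscle": muscle, "qc": res.qc})
            if res.qc != "usable" or res.map is None:
                logger.info("dropping channel %s/%s: %s", subject.subject_id, muscle, res.qc)
                continue
            maps[(subject.subject_id, muscle)] = res.map
            cx, cy = cog(res.map)
            for variable, value in [
                (f"cog_x {muscle}", cx),
                (f"cog_y {muscle}", cy),
                (f"cog_vector {muscle}", cog_vector((cx, cy))),
                (f"volume {muscle}", map_volume(res.map)),
                (f"area {muscle}", float(map_area(res.map))),
            ]:
                metric_rows.append(
                    {"subject_id": subject.subject_id, "group": subject.group, "variable": variable, "value": value}
                )

    # per-subject overlap for each muscle pair
    for subject in cohort.subjects:
        for i, ma in enumerate(muscles):
            for mb in muscles[i + 1 :]:
                a = maps.get((subject.subject_id, ma))
                b = maps.get((subject.subject_id, mb))
                if a is None or b is None:
                    continue
                metric_rows.append(
                    {
                        "subject_id": subject.subject_id, "group": subject.group,
                        "variable": f"overlap {ma}/{mb}", "value": map_overlap(a, b).overlap,
                    }
                )

    metrics = pd.DataFrame(metric_rows)

    # CoG variation: per group-muscle deviations from the group-mean CoG
    groups = sorted({s.group for s in cohort.subjects})
    var_rows = []
    for group in groups:
        ids = [s.subject_id for s in cohort.subjects_in(group)]
        for muscle in muscles:
            pairs = [(sid, maps[(sid, muscle)]) for sid in ids if (sid, muscle) in maps]
            if len(pairs) < 2:
                continue
            cogs = [cog(m) for _, m in pairs]
            devs, _ = cog_variation(cogs, [sid for sid, _ in pairs], muscle)
            for d in devs:
                for variable, value in [
                    (f"cog_variation_x {muscle}", d.dev_x),
                    (f"cog_variation_y {muscle}", d.dev_y),
                    (f"cog_variation_vector {muscle}", d.dev_vector),
                ]:
                    var_rows.append(
                        {"subject_id": d.subject_id, "group": group, "variable": variable, "value": value}
                    )
    if var_rows:
        metrics = pd.concat([metrics, pd.DataFrame(var_rows)], ignore_index=True)

    group_maps: dict[str, dict[str, np.ndarray]] = {}
    for group in groups:
        ids = [s.subject_id for s in cohort.subjects_in(group)]
        group_maps[group] = {}
        for muscle in muscles:
            ms = [maps[(sid, muscle)] for sid in ids if (sid, muscle) in maps]
            if ms:
                group_maps[group][muscle] = average_group_map(ms)

    qc = pd.DataFrame(qc_rows)
    n_dropped = int((qc["qc"] != "usable").sum()) if len(qc) else 0
    logger.info("analyzed %d channels, dropped %d", len(qc), n_dropped)
    return CohortResult(metrics=metrics, maps=maps, qc=qc, group_maps=group_maps)
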