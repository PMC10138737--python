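"""File formats: HDF5 cohort containers, delimited-text sweeps and manifests,
report tables, YAML configuration.

Cohorts travel as one HDF5 file (groups/subjects/muscles with sweeps as
``(n_sites, n_stimuli, n_samples)`` datasets and ground truth as attributes).
Single sweeps round-trip through a plain-text format (header comments plus one
sample per line) so curated recordings can be assembled from any acquisition
system via a manifest table.  Reports are CSV with fixed formatting (2 decimals
for means/SDs/F, 3 for p and eta-squared) and deterministic ordering, so
re-running on identical input yields byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import fields
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .grid import GridSpec
from .mep import DetectionParams, EMGSweep
from .pipeline import PipelineConfig
from .simulate import Cohort, GroupProfile, SimulationConfig, default_profiles
from .stats import GroupReport

logger = logging.getLogger("backmap")

__all__ = [
    "save_cohort_hdf5",
    "load_cohort_hdf5",
    "LoadedCohort",
    "write_sweep_text",
    "read_sweep_text",
    "read_sweeps",
    "write_report",
    "load_config",
]

MANIFEST_COLUMNS = ["subject_id", "group", "muscle", "site_col", "site_row", "sweep_file"]


def save_cohort_hdf5(cohort: Cohort, path, muscles: Optional[Sequence[str]] = None) -> None:
    """Write a simulated cohort (sweeps + ground truth) to one HDF5 file."""
    muscles = tuple(muscles or cohort.muscles)
    cfg = cohort.config
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = cfg.sampling_rate
        f.attrs["stimulus_index"] = cfg.stimulus_index
        f.attrs["stimuli_per_site"] = cfg.stimuli_per_site
        f.attrs["seed"] = cfg.seed
        f.attrs["muscles"] = list(muscles)
        f.attrs["grid_x_coords"] = list(cfg.grid.x_coords)
        f.attrs["grid_y_coords"] = list(cfg.grid.y_coords)
        subs = f.create_group("subjects")
        for s in cohort.subjects:
            g = subs.create_group(s.subject_id)
            g.attrs["group"] = s.group
            g.attrs["pain_nrs"] = s.pain_nrs
            g.attrs["seed"] = s.seed
            for m in muscles:
                d = g.create_dataset(m, data=cohort.sweep_array(s, m).astype(np.float32))
                d.attrs["true_cog"] = list(s.true_cog[m])
                d.attrs["footprint_sigma"] = s.footprint_sigma[m]
                d.attrs["peak_amplitude_uV"] = s.peak_amplitude_uV[m]


class _LoadedSubject:
    __slots__ = ("subject_id", "group", "pain_nrs", "true_cog")

    def __init__(self, subject_id: str, group: str, pain_nrs: float, true_cog: dict):
        self.subject_id = subject_id
        self.group = group
        self.pain_nrs = pain_nrs
        self.true_cog = true_cog


class LoadedCohort:
    """A cohort read back from HDF5; satisfies the interface
    :func:`backmap.pipeline.analyze_cohort` expects."""

    def __init__(self, path):
        self._path = Path(path)
        with h5py.File(path, "r") as f:
            self.muscles = tuple(str(m) for m in f.attrs["muscles"])
            x = tuple(float(v) for v in f.attrs["grid_x_coords"])
            y = tuple(float(v) for v in f.attrs["grid_y_coords"])
            grid = GridSpec(n_cols=len(x), n_rows=len(y), x_coords=x, y_coords=y)
            n_stim = int(f.attrs["stimuli_per_site"])
            fs = float(f.attrs["sampling_rate"])
            stim = int(f.attrs["stimulus_index"])
            self.subjects = []
            self._truth = {}
            for sid in sorted(f["subjects"]):
                g = f["subjects"][sid]
                true_cog = {m: tuple(g[m].attrs["true_cog"]) for m in self.muscles if m in g}
                self.subjects.append(
                    _LoadedSubject(sid, str(g.attrs["group"]), float(g.attrs["pain_nrs"]), true_cog)
                )
            n_samp = f["subjects"][self.subjects[0].subject_id][self.muscles[0]].shape[-1]
        pre_ms = stim / fs * 1000.0
        post_ms = (n_samp - stim) / fs * 1000.0
        self.config = SimulationConfig(
            grid=grid, stimuli_per_site=n_stim, sampling_rate=fs,
            pre_ms=pre_ms, post_ms=post_ms,
        )
        assert self.config.stimulus_index == stim

    @property
    def grid(self) -> GridSpec:
        return self.config.grid

    def subjects_in(self, group: str):
        return [s for s in self.subjects if s.group == group]

    def sweep_array(self, subject, muscle: str) -> np.ndarray:
        with h5py.File(self._path, "r") as f:
            return f["subjects"][subject.subject_id][muscle][()].astype(float)


def write_sweep_text(sweep: EMGSweep, path) -> None:
    """Write one sweep as plain text: '#' header lines, one µV sample per line."""
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz {sweep.sampling_rate!r}\n")
        fh.write(f"# stimulus_index {sweep.stimulus_index}\n")
        fh.write(f"# channel {sweep.channel}\n")
        fh.write(f"# site_col {sweep.site[0]}\n")
        fh.write(f"# site_row {sweep.site[1]}\n")
        fh.write(f"# subject_id {sweep.subject_id}\n")
        for v in sweep.samples:
            fh.write(f"{float(v)!r}\n")


def read_sweep_text(path) -> EMGSweep:
    """Read a sweep written by :func:`write_sweep_text` (bit-exact round trip)."""
    meta: dict[str, str] = {}
    samples: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.split(maxsplit=2)
                if len(parts) >= 2:
                    meta[parts[1]] = parts[2] if len(parts) == 3 else ""
            else:
                samples.append(float(line))
    if "stimulus_index" not in meta:
        raise ValueError(f"{path}: missing stimulus marker ('# stimulus_index N')")
    return EMGSweep(
        samples=np.array(samples),
        sampling_rate=float(meta.get("sampling_rate_hz", 2000.0)),
        stimulus_index=int(meta["stimulus_index"]),
        channel=meta.get("channel", "DM"),
        site=(int(meta.get("site_col", 0)), int(meta.get("site_row", 0))),
        subject_id=meta.get("subject_id", ""),
    )


def read_sweeps(root, manifest: pd.DataFrame) -> tuple[list[EMGSweep], int]:
    """Load sweeps listed in a manifest table; returns (sweeps, n_skipped).

    Manifest columns: subject_id, group, muscle, site_col, site_row,
    sweep_file (relative to ``root``).  Rows whose file is missing are skipped
    and logged; a file without a stimulus marker raises.
    """
    missing_cols = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
    root = Path(root)
    sweeps: list[EMGSweep] = []
    skipped = 0
    for _, row in manifest.iterrows():
        p = root / str(row["sweep_file"])
        if not p.exists():
            logger.warning("manifest row skipped, file missing: %s", p)
            skipped += 1
            continue
        sw = read_sweep_text(p)
        sw.channel = str(row["muscle"])
        sw.site = (int(row["site_col"]), int(row["site_row"]))
        sw.subject_id = str(row["subject_id"])
        sweeps.append(sw)
    logger.info("read %d sweeps, skipped %d manifest rows", len(sweeps), skipped)
    return sweeps, skipped


def _fmt(df: pd.DataFrame, two_dp: Sequence[str], three_dp: Sequence[str]) -> pd.DataFrame:
    out = df.copy()
    for c in two_dp:
        if c in out.columns:
            out[c] = out[c].map(lambda v: f"{v:.2f}" if pd.notna(v) else "")
    for c in three_dp:
        if c in out.columns:
            out[c] = out[c].map(lambda v: f"{v:.3f}" if pd.notna(v) else "")
    return out


def write_report(report: GroupReport, outdir, group_maps: Optional[dict] = None) -> list[Path]:
    """Write the group-comparison report as CSV files under ``outdir``.

    Files: group_summary.csv, omnibus.csv, posthoc.csv, normality.csv,
    skipped.csv and (optionally) maps/<group>_<muscle>.csv as 8 x 5 matrices.
    Numbers carry 2 decimals (means, SDs, F) and 3 (p, eta-squared, W).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str, sort_by: list[str], two=(), three=()):
        path = outdir / name
        if len(df):
            df = df.sort_values(sort_by).reset_index(drop=True)
            df = _fmt(df, two, three)
        df.to_csv(path, index=False)
        written.append(path)

    _write(report.summary, "group_summary.csv", ["variable", "group"], two=("mean", "sd"))
    _write(
        report.omnibus, "omnibus.csv", ["variable"],
        two=("F", "df2"), three=("p", "eta_squared"),
    )
    _write(report.posthoc, "posthoc.csv", ["variable", "group_a", "group_b"], three=("p",))
    _write(report.normality, "normality.csv", ["variable", "group"], three=("W", "p"))
    pd.DataFrame(report.skipped, columns=["variable", "reason"]).to_csv(
        outdir / "skipped.csv", index=False
    )
    written.append(outdir / "skipped.csv")
    if group_maps:
        mapdir = outdir / "maps"
        mapdir.mkdir(exist_ok=True)
        for group in sorted(group_maps):
            for muscle in sorted(group_maps[group]):
                p = mapdir / f"{group}_{muscle}.csv"
                np.savetxt(p, group_maps[group][muscle], delimiter=",", fmt="%.4f")
                written.append(p)
    return written


def _dataclass_from_dict(cls, d: dict, **overrides):
    allowed = {f.name for f in fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**{**d, **overrides})


def load_config(path) -> tuple[PipelineConfig, SimulationConfig, list[GroupProfile]]:
    """Load pipeline/simulation settings and group profiles from YAML.

    Top-level keys (all optional): ``seed``, ``pipeline``, ``simulation``,
    ``groups`` (list of group-profile mappings; defaults to the built-in
    pain-mechanism profiles).  Tuple-valued fields may be given as lists.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.get("seed", 0))
    pdict = dict(raw.get("pipeline", {}))
    det = pdict.pop("detection", None)
    for key in ("background_window_ms",):
        if key in pdict:
            pdict[key] = tuple(pdict[key])
    if det is not None:
        for key in ("latency_band_ms", "background_window_ms"):
            if key in det:
                det[key] = tuple(det[key])
        pdict["detection"] = _dataclass_from_dict(DetectionParams, det)
    pipeline = _dataclass_from_dict(PipelineConfig, pdict, seed=seed)
    sdict = dict(raw.get("simulation", {}))
    sim = _dataclass_from_dict(SimulationConfig, sdict, seed=seed)
    groups_raw = raw.get("groups")
    if groups_raw:
        profiles = []
        for g in groups_raw:
            g = dict(g)
            for key in ("true_cog_mean", "cog_dispersion"):
                if key in g:
                    g[key] = tuple(g[key])
            profiles.append(_dataclass_from_dict(GroupProfile, g))
    else:
        profiles = default_profiles()
    return pipeline, sim, profiles
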