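"""Synthetic cohorts of TMS motor-map participants with known ground truth.

Each simulated participant carries, per muscle, a latent 2-D Gaussian cortical
amplitude surface: MEP amplitude at scalp site (x, y) is
``peak * exp(-((x-mu_x)^2 + (y-mu_y)^2) / (2 sigma^2))``.  Between-subject
scatter of the surface centre (the true CoG) is drawn per group from a normal
distribution truncated to the grid, so groups can differ in CoG dispersion the
way pain-mechanism subgroups do.  Raw stimulus-locked EMG sweeps are generated
from the surface: tonic background EMG (zero-mean Gaussian at a configured RMS,
emulating a sustained 10% MVC contraction) plus an MEP burst -- a damped
sinusoid of fixed duration scaled to a target RMS drawn lognormally around the
surface amplitude.  Waveform shape is irrelevant to the RMS-based metrics
downstream; the burst exists so the full sweep pipeline (background RMS,
onset/offset detection, subtraction, averaging) can be exercised end to end
with recoverable ground truth.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so identical seed + config give a bit-identical cohort and
per-subject data can be regenerated lazily without storing every sweep.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .grid import GridSpec, default_grid
from .mep import MUSCLES, EMGSweep

__all__ = [
    "GroupProfile",
    "SimulatedSubject",
    "SimulationConfig",
    "PainLink",
    "Cohort",
    "simulate_surface",
    "simulate_sweeps",
    "simulate_cohort",
    "default_profiles",
    "recovery_profiles",
]

#: Fixed per-muscle centre offsets (cm) relative to the deep multifidus (DM)
#: anchor, applied with weight (1 - overlap_coupling).  DM is the reference
#: muscle: its true CoG dispersion equals the group's generating dispersion
#: exactly.
MUSCLE_OFFSETS: dict[str, tuple[float, float]] = {
    "DM": (0.0, 0.0),
    "SM": (0.3, -0.3),
    "LES": (-0.3, 0.5),
    "TES": (0.4, 0.4),
}

#: Between-subject SD (cm) of the muscle-specific centre jitter (non-anchor
#: muscles only), likewise scaled by (1 - overlap_coupling).
MUSCLE_JITTER_SD = 0.3


@dataclass(frozen=True)
class GroupProfile:
    """Generating parameters of one participant group.

    ``true_cog_mean`` and ``cog_dispersion`` are in grid cm; ``footprint_sigma``
    is the isotropic SD of the Gaussian amplitude surface; ``overlap_coupling``
    in [0, 1] interpolates muscle centres toward a shared (DM) centre, giving
    continuous control of the expected between-muscle map overlap; pain scores
    are on the 0-10 NRS.
    """

    label: str
    true_cog_mean: tuple[float, float] = (2.0, 1.5)
    cog_dispersion: tuple[float, float] = (0.6, 0.6)
    footprint_sigma: float = 1.2
    peak_amplitude_uV: float = 100.0
    overlap_coupling: float = 0.5
    pain_mean: float = 5.0
    pain_sd: float = 1.8
    n_subjects: int = 10

    def __post_init__(self) -> None:
        if self.footprint_sigma <= 0:
            raise ValueError("footprint_sigma must be positive")
        if min(self.cog_dispersion) < 0:
            raise ValueError("cog_dispersion must be non-negative")
        if not 0 <= self.overlap_coupling <= 1:
            raise ValueError("overlap_coupling must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedSubject:
    """Ground truth for one simulated participant."""

    subject_id: str
    group: str
    true_cog: dict[str, tuple[float, float]]  # muscle -> (x, y) cm
    footprint_sigma: dict[str, float]
    peak_amplitude_uV: dict[str, float]
    pain_nrs: float
    seed: int


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition-model parameters shared by all simulated subjects.

    Defaults mirror the mapping protocol: 5 stimuli per site, 2000 Hz sampling,
    sweeps spanning 550 ms before to 120 ms after the pulse (room for the
    -500..-5 ms background window), MEP latency 20 +- 2 ms, 20 ms burst.
    ``amplitude_cv`` is the coefficient of variation of the per-stimulus MEP
    amplitude (lognormal: amplitudes are positive and right-skewed).
    """

    grid: GridSpec = field(default_factory=default_grid)
    stimuli_per_site: int = 5
    sampling_rate: float = 2000.0
    pre_ms: float = 550.0
    post_ms: float = 120.0
    background_rms_uV: float = 10.0
    mep_latency_ms: float = 20.0
    latency_jitter_ms: float = 2.0
    mep_duration_ms: float = 20.0
    amplitude_cv: float = 0.2
    mains_hz: Optional[float] = None  # set to 50.0/60.0 to add a mains component
    mains_rms_uV: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stimuli_per_site < 1:
            raise ValueError("stimuli_per_site must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be non-negative")
        if self.pre_ms < 510.0:
            raise ValueError("pre_ms must leave room for the 500 ms background window")

    @property
    def n_samples(self) -> int:
        return int(round((self.pre_ms + self.post_ms) * self.sampling_rate / 1000.0))

    @property
    def stimulus_index(self) -> int:
        return int(round(self.pre_ms * self.sampling_rate / 1000.0))


@dataclass(frozen=True)
class PainLink:
    """Optional induced monotone link between a map feature and pain NRS.

    Pain is drawn as ``pain_mean + slope * z(true CoG deviation) + noise`` and
    clipped to [0, 10], where z() standardises the subject's true distance from
    the group-mean CoG.  Used for Spearman sign-recovery tests; slope 0 gives
    the null (pain independent of the map).
    """

    slope: float = 0.0
    noise_sd: float = 0.5
    muscle: str = "DM"


def simulate_surface(
    subject: SimulatedSubject, muscle: str, grid: GridSpec
) -> np.ndarray:
    """Latent MEP amplitude surface (µV) sampled at the grid sites.

    Returns a ``(n_rows, n_cols)`` array.  In the degenerate sigma -> 0 limit
    only the site nearest the true CoG responds (at full peak amplitude).
    """
    mu_x, mu_y = subject.true_cog[muscle]
    if not grid.contains(mu_x, mu_y):
        raise ValueError(f"true CoG ({mu_x}, {mu_y}) outside grid bounds {grid.bounds}")
    sigma = subject.footprint_sigma[muscle]
    peak = subject.peak_amplitude_uV[muscle]
    X, Y = grid.meshgrid()
    d2 = (X - mu_x) ** 2 + (Y - mu_y) ** 2
    if sigma == 0.0:
        amp = np.zeros(grid.shape)
        r, c = np.unravel_index(np.argmin(d2), d2.shape)
        amp[r, c] = peak
        return amp
    return peak * np.exp(-d2 / (2.0 * sigma**2))


def _mep_waveform(n: int, fs: float) -> np.ndarray:
    """Unit-shape MEP burst: damped 60 Hz sinusoid (decay tau = 8 ms).

    60 Hz keeps each rectified lobe longer than the detector's 5 ms sustain
    requirement; the sharp onset makes detected latencies match ground truth.
    """
    t = np.arange(n) / fs
    return np.exp(-t / 0.008) * np.sin(2 * np.pi * 60.0 * t)


def _site_seed(subject_seed: int, muscle: str, site_flat: int) -> int:
    h = hashlib.blake2b(
        f"{subject_seed}:{muscle}:{site_flat}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(h, "little") % (2**31)


def _sweep_block(
    amplitude_uV: float,
    n_stimuli: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stimulus-locked sweeps for one site as a (n_stimuli, n_samples) array."""
    n = config.n_samples
    stim = config.stimulus_index
    fs = config.sampling_rate
    out = rng.normal(0.0, config.background_rms_uV, size=(n_stimuli, n))
    if config.mains_hz is not None and config.mains_rms_uV > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi, size=(n_stimuli, 1))
        out += config.mains_rms_uV * np.sqrt(2) * np.sin(2 * np.pi * config.mains_hz * t + phase)
    if amplitude_uV > 0:
        burst_n = max(2, int(round(config.mep_duration_ms * fs / 1000.0)))
        shape = _mep_waveform(burst_n, fs)
        shape = shape / np.sqrt(np.mean(shape**2))  # unit RMS
        if config.amplitude_cv > 0:
            s2 = np.log1p(config.amplitude_cv**2)
            mu = np.log(amplitude_uV) - s2 / 2.0
            target = rng.lognormal(mu, np.sqrt(s2), size=n_stimuli)
        else:
            target = np.full(n_stimuli, amplitude_uV)
        if config.latency_jitter_ms > 0:
            lat = rng.uniform(
                config.mep_latency_ms - config.latency_jitter_ms,
                config.mep_latency_ms + config.latency_jitter_ms,
                size=n_stimuli,
            )
        else:
            lat = np.full(n_stimuli, config.mep_latency_ms)
        starts = stim + np.round(lat * fs / 1000.0).astype(int)
        for i in range(n_stimuli):
            out[i, starts[i] : starts[i] + burst_n] += target[i] * shape
    return out


def simulate_sweeps(
    subject: SimulatedSubject,
    muscle: str,
    site: tuple[int, int],
    config: SimulationConfig,
) -> list[EMGSweep]:
    """EMG sweeps for the stimuli at one grid site (deterministic in the seed).

    ``site`` is (col, row).  The per-site random stream is derived from the
    subject seed, muscle and site, so repeated calls reproduce identical sweeps
    and sites can be generated independently in any order.
    """
    col, row = site
    surf = simulate_surface(subject, muscle, config.grid)
    amp = float(surf[row, col])
    rng = np.random.default_rng(
        _site_seed(subject.seed, muscle, row * config.grid.n_cols + col)
    )
    block = _sweep_block(amp, config.stimuli_per_site, config, rng)
    return [
        EMGSweep(
            samples=block[i],
            sampling_rate=config.sampling_rate,
            stimulus_index=config.stimulus_index,
            channel=muscle,
            site=(col, row),
            subject_id=subject.subject_id,
        )
        for i in range(config.stimuli_per_site)
    ]


def _truncnorm_xy(
    mean: tuple[float, float],
    sd: tuple[float, float],
    grid: GridSpec,
    rng: np.random.Generator,
    size: int,
) -> np.ndarray:
    """Draw (size, 2) centres from independent normals truncated to the grid."""
    (x_lo, x_hi), (y_lo, y_hi) = grid.bounds
    out = np.empty((size, 2))
    for j, (m, s, lo, hi) in enumerate(
        [(mean[0], sd[0], x_lo, x_hi), (mean[1], sd[1], y_lo, y_hi)]
    ):
        if s == 0:
            out[:, j] = m
        else:
            a, b = (lo - m) / s, (hi - m) / s
            out[:, j] = sps.truncnorm.rvs(a, b, loc=m, scale=s, size=size, random_state=rng)
    return out


@dataclass
class Cohort:
    """A simulated cohort: subjects with ground truth plus lazy sweep access.

    Sweeps are regenerated deterministically from per-subject seeds rather than
    stored, so arbitrarily large cohorts stay cheap to hold in memory.
    """

    subjects: list[SimulatedSubject]
    profiles: list[GroupProfile]
    config: SimulationConfig
    muscles: tuple[str, ...] = MUSCLES

    @property
    def grid(self) -> GridSpec:
        return self.config.grid

    def subjects_in(self, group: str) -> list[SimulatedSubject]:
        return [s for s in self.subjects if s.group == group]

    def surface(self, subject: SimulatedSubject, muscle: str) -> np.ndarray:
        return simulate_surface(subject, muscle, self.grid)

    def sweep_array(self, subject: SimulatedSubject, muscle: str) -> np.ndarray:
        """All sweeps for one subject-muscle as (n_sites, n_stimuli, n_samples),
        sites in row-major (row, col) order."""
        cfg = self.config
        surf = simulate_surface(subject, muscle, cfg.grid)
        n_sites = cfg.grid.n_sites
        out = np.empty((n_sites, cfg.stimuli_per_site, cfg.n_samples))
        for flat in range(n_sites):
            row, col = divmod(flat, cfg.grid.n_cols)
            rng = np.random.default_rng(_site_seed(subject.seed, muscle, flat))
            out[flat] = _sweep_block(float(surf[row, col]), cfg.stimuli_per_site, cfg, rng)
        return out

    def sweeps(self, subject: SimulatedSubject, muscle: str) -> list[EMGSweep]:
        """All sweeps for one subject-muscle as EMGSweep objects."""
        cfg = self.config
        arr = self.sweep_array(subject, muscle)
        out = []
        for flat in range(cfg.grid.n_sites):
            row, col = divmod(flat, cfg.grid.n_cols)
            for i in range(cfg.stimuli_per_site):
                out.append(
                    EMGSweep(
                        samples=arr[flat, i],
                        sampling_rate=cfg.sampling_rate,
                        stimulus_index=cfg.stimulus_index,
                        channel=muscle,
                        site=(col, row),
                        subject_id=subject.subject_id,
                    )
                )
        return out


def simulate_cohort(
    profiles: Sequence[GroupProfile],
    config: SimulationConfig,
    muscles: Sequence[str] = MUSCLES,
    pain_link: Optional[PainLink] = None,
) -> Cohort:
    """Draw a full cohort: per-subject true CoGs, footprints, pain scores.

    Per-subject true CoGs are drawn from the group mean with the group's
    ``cog_dispersion`` (truncated to the grid).  The DM centre anchors the
    subject; other muscles sit at ``DM + (1 - coupling) * (offset + jitter)``,
    so ``overlap_coupling = 1`` collapses all muscles onto a shared centre.
    """
    if not profiles:
        raise ValueError("at least one group profile required")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels: {labels}")
    for p in profiles:
        if not config.grid.contains(*p.true_cog_mean):
            raise ValueError(f"group {p.label}: true_cog_mean outside grid")

    root = np.random.SeedSequence(config.seed)
    group_seqs = root.spawn(len(profiles))
    subjects: list[SimulatedSubject] = []
    for p, seq in zip(profiles, group_seqs):
        rng = np.random.default_rng(seq)
        anchors = _truncnorm_xy(p.true_cog_mean, p.cog_dispersion, config.grid, rng, p.n_subjects)
        pains = np.clip(rng.normal(p.pain_mean, p.pain_sd, size=p.n_subjects), 0.0, 10.0)
        if pain_link is not None and pain_link.slope != 0.0:
            dev = np.hypot(
                anchors[:, 0] - anchors[:, 0].mean(), anchors[:, 1] - anchors[:, 1].mean()
            )
            z = (dev - dev.mean()) / dev.std() if dev.std() > 0 else np.zeros_like(dev)
            pains = np.clip(
                p.pain_mean
                + pain_link.slope * z
                + rng.normal(0.0, pain_link.noise_sd, size=p.n_subjects),
                0.0,
                10.0,
            )
        sub_seeds = rng.integers(0, 2**31, size=p.n_subjects)
        for i in range(p.n_subjects):
            cogs: dict[str, tuple[float, float]] = {}
            for m in muscles:
                off = MUSCLE_OFFSETS.get(m, (0.0, 0.0))
                w = 1.0 - p.overlap_coupling
                jit = rng.normal(0.0, MUSCLE_JITTER_SD, size=2) if m != "DM" else np.zeros(2)
                x = anchors[i, 0] + w * (off[0] + jit[0])
                y = anchors[i, 1] + w * (off[1] + jit[1])
                (x_lo, x_hi), (y_lo, y_hi) = config.grid.bounds
                cogs[m] = (float(np.clip(x, x_lo, x_hi)), float(np.clip(y, y_lo, y_hi)))
            subjects.append(
                SimulatedSubject(
                    subject_id=f"{p.label}-{i + 1:03d}",
                    group=p.label,
                    true_cog=cogs,
                    footprint_sigma={m: p.footprint_sigma for m in muscles},
                    peak_amplitude_uV={m: p.peak_amplitude_uV for m in muscles},
                    pain_nrs=float(pains[i]),
                    seed=int(sub_seeds[i]),
                )
            )
    return Cohort(subjects=subjects, profiles=list(profiles), config=config, muscles=tuple(muscles))


def default_profiles() -> list[GroupProfile]:
    """Default pain-mechanism group profiles on the scale of real back-muscle maps.

    CoG means, dispersions, footprints and pain levels are set inside the
    ranges observed for the four low-back-pain subgroups (CoG x ~2.1-2.6 cm,
    CoG variation ~0.3-1.6 cm, DM areas ~10-25 sites): the nociplastic (NpP)
    group gets the largest between-subject CoG dispersion, the mixed (MP)
    group the largest footprint and muscle coupling (hence overlap).
    """
    return [
        GroupProfile(
            label="NcP-FP", true_cog_mean=(2.35, 1.50), cog_dispersion=(0.66, 0.85),
            footprint_sigma=1.2, overlap_coupling=0.4, pain_mean=4.2, pain_sd=1.7,
            n_subjects=13,
        ),
        GroupProfile(
            label="NcP-AEP", true_cog_mean=(2.15, 1.00), cog_dispersion=(0.40, 0.34),
            footprint_sigma=1.2, overlap_coupling=0.5, pain_mean=5.5, pain_sd=2.7,
            n_subjects=6,
        ),
        GroupProfile(
            label="MP", true_cog_mean=(2.27, 1.17), cog_dispersion=(0.27, 0.44),
            footprint_sigma=1.7, overlap_coupling=0.8, pain_mean=5.0, pain_sd=2.2,
            n_subjects=5,
        ),
        GroupProfile(
            label="NpP", true_cog_mean=(2.12, 1.33), cog_dispersion=(0.44, 1.30),
            footprint_sigma=1.1, overlap_coupling=0.4, pain_mean=5.4, pain_sd=1.7,
            n_subjects=4,
        ),
    ]


def recovery_profiles(n_subjects: int = 50) -> list[GroupProfile]:
    """Two-group design for parameter-recovery studies: a low-dispersion
    nociceptive-like group and a nociplastic-like group with 3x the CoG
    dispersion, both centred mid-grid so truncation stays symmetric."""
    return [
        GroupProfile(
            label="NcP-like", true_cog_mean=(2.0, 1.5), cog_dispersion=(0.3, 0.3),
            footprint_sigma=1.2, overlap_coupling=0.4, n_subjects=n_subjects,
        ),
        GroupProfile(
            label="NpP-like", true_cog_mean=(2.0, 1.5), cog_dispersion=(0.9, 0.9),
            footprint_sigma=1.2, overlap_coupling=0.4, n_subjects=n_subjects,
        ),
    ]
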