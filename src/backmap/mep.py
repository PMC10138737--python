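"""Stimulus-locked EMG sweep processing.

Turns raw EMG sweeps into one background-corrected motor evoked potential (MEP)
amplitude per muscle per scalp site:

1. background RMS over a pre-stimulus window (default -500 to -5 ms),
2. MEP RMS between onset and offset (detected automatically or supplied as
   manual annotations),
3. corrected amplitude = max(MEP RMS - background RMS, 0),
4. average over the stimuli delivered at a site.

Amplitudes are in microvolts throughout.  The automatic onset/offset detector
replaces visual determination: the rectified, smoothed signal must exceed the
background mean + k standard deviations for a sustained period inside a
physiological latency band.  A sweep with no crossing carries no MEP; absence
is a value (``None``), not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "EMGSweep",
    "MEPWindow",
    "SiteAmplitude",
    "DetectionParams",
    "background_rms",
    "mep_rms",
    "corrected_amplitude",
    "detect_window",
    "detect_windows",
    "site_amplitude",
    "channel_qc",
    "sweep_array_amplitudes",
]

MUSCLES = ("DM", "SM", "LES", "TES")


@dataclass
class EMGSweep:
    """One stimulus-locked EMG trace for one muscle at one scalp site.

    ``stimulus_index`` is the sample position of the TMS pulse (t = 0);
    ``samples`` are in microvolts.
    """

    samples: np.ndarray
    sampling_rate: float = 2000.0
    stimulus_index: int = 0
    channel: str = "DM"
    site: tuple[int, int] = (0, 0)  # (col, row) zero-based grid indices
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.stimulus_index < self.samples.size:
            raise ValueError("stimulus_index outside the sweep")

    def time_to_index(self, t_ms: float) -> int:
        """Sample index of time ``t_ms`` relative to the stimulus (rounded)."""
        return self.stimulus_index + int(round(t_ms * self.sampling_rate / 1000.0))


@dataclass(frozen=True)
class MEPWindow:
    """MEP onset/offset in ms post-stimulus; ``source`` records whether the
    window came from the automatic detector or a manual annotation."""

    onset_ms: float
    offset_ms: float
    source: str = "automatic"

    def __post_init__(self) -> None:
        if not 0 < self.onset_ms < self.offset_ms:
            raise ValueError(f"invalid MEP window [{self.onset_ms}, {self.offset_ms}] ms")


@dataclass(frozen=True)
class SiteAmplitude:
    """Background-corrected MEP amplitude at one site, averaged over stimuli."""

    subject_id: str
    muscle: str
    site: tuple[int, int]
    mean_amplitude_uV: float
    n_stimuli_used: int
    qc_flag: str = "ok"


@dataclass(frozen=True)
class DetectionParams:
    """Settings of the threshold-crossing MEP detector.

    The rectified signal is smoothed with a ``smooth_ms`` moving average
    (stabilises crossing times at 2 kHz); the threshold is background mean +
    ``k`` background SD; a crossing must be sustained ``min_duration_ms``;
    the onset is searched inside ``latency_band_ms`` (paraspinal MEP
    latencies; configurable).
    """

    k: float = 3.0
    min_duration_ms: float = 5.0
    latency_band_ms: tuple[float, float] = (10.0, 40.0)
    smooth_ms: float = 2.0
    background_window_ms: tuple[float, float] = (-500.0, -5.0)


def _background_slice(n: int, stim: int, fs: float, window_ms: tuple[float, float]) -> slice:
    t0, t1 = window_ms
    if not t0 < t1 <= 0:
        raise ValueError(f"background window {window_ms} must be strictly pre-stimulus")
    i0 = stim + int(round(t0 * fs / 1000.0))
    i1 = stim + int(round(t1 * fs / 1000.0))
    if i0 < 0:
        need_ms = -t0
        have_ms = stim / fs * 1000.0
        raise ValueError(
            f"insufficient pre-stimulus signal: background window needs {need_ms:.0f} ms, "
            f"sweep provides {have_ms:.0f} ms"
        )
    return slice(i0, i1)


def _rms(x: np.ndarray, axis=None) -> np.ndarray:
    return np.sqrt(np.mean(np.square(x), axis=axis))


def background_rms(sweep: EMGSweep, window_ms: tuple[float, float] = (-500.0, -5.0)) -> float:
    """Root-mean-square of the pre-stimulus background EMG.

    The window is [-500, -5) ms relative to the TMS pulse by default.
    """
    sl = _background_slice(sweep.samples.size, sweep.stimulus_index, sweep.sampling_rate, window_ms)
    return float(_rms(sweep.samples[sl]))


def mep_rms(sweep: EMGSweep, window: MEPWindow) -> float:
    """RMS of the sweep between MEP onset and offset (inclusive)."""
    i0 = sweep.time_to_index(window.onset_ms)
    i1 = sweep.time_to_index(window.offset_ms)
    if i1 >= sweep.samples.size:
        raise ValueError("MEP window extends past the end of the sweep")
    if i1 < i0:
        raise ValueError("empty MEP window")
    return float(_rms(sweep.samples[i0 : i1 + 1]))


def corrected_amplitude(
    sweep: EMGSweep,
    window: MEPWindow,
    background_window_ms: tuple[float, float] = (-500.0, -5.0),
) -> float:
    """Background-corrected MEP amplitude: max(MEP RMS - background RMS, 0).

    Negative differences are clamped to zero -- a response below the tonic
    background is physically meaningless and would corrupt map volume sums.
    """
    return max(mep_rms(sweep, window) - background_rms(sweep, background_window_ms), 0.0)


def _detect_array(
    arr: np.ndarray,
    fs: float,
    stim: int,
    params: DetectionParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised detector core over a (n_sweeps, n_samples) array.

    Returns (onset_idx, offset_idx, found) with indices relative to the sweep
    start; this is the single detection code path (per-sweep API wraps it).
    """
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    n_sw, n_samp = arr.shape
    smooth_n = max(1, int(round(params.smooth_ms * fs / 1000.0)))
    rect = np.abs(arr)
    smooth = uniform_filter1d(rect, size=smooth_n, axis=1, mode="nearest")

    bg_sl = _background_slice(n_samp, stim, fs, params.background_window_ms)
    bg = smooth[:, bg_sl]
    thr = bg.mean(axis=1) + params.k * bg.std(axis=1)  # per sweep
    # floor the threshold just above the running-sum filter's floating residue,
    # so an exactly-silent background still separates signal from zero
    thr = np.maximum(thr, 1e-9 * smooth.max(axis=1))

    m = max(1, int(round(params.min_duration_ms * fs / 1000.0)))
    above = smooth > thr[:, None]
    # sustained[i, j] <=> above[i, j:j+m] all true
    c = np.cumsum(above, axis=1, dtype=np.int32)
    pad = np.zeros((n_sw, 1), dtype=np.int32)
    c = np.hstack([pad, c])
    winsum = c[:, m:] - c[:, :-m]  # shape (n_sw, n_samp - m + 1)
    sustained = winsum == m

    lo = stim + int(round(params.latency_band_ms[0] * fs / 1000.0))
    hi = stim + int(round(params.latency_band_ms[1] * fs / 1000.0))
    hi = min(hi, sustained.shape[1] - 1)

    onset = np.zeros(n_sw, dtype=np.int64)
    offset = np.zeros(n_sw, dtype=np.int64)
    found = np.zeros(n_sw, dtype=bool)
    if hi < lo:
        return onset, offset, found

    band = sustained[:, lo : hi + 1]
    has = band.any(axis=1)
    first = band.argmax(axis=1) + lo

    # offset: first start of a sustained below-threshold run after onset
    below = ~above
    cb = np.cumsum(below, axis=1, dtype=np.int32)
    cb = np.hstack([pad, cb])
    wb = cb[:, m:] - cb[:, :-m]
    sus_below = wb == m
    for i in np.nonzero(has)[0]:
        found[i] = True
        onset[i] = first[i]
        later = sus_below[i, first[i] + 1 :]
        j = later.argmax() if later.size else 0
        if later.size and later[j]:
            offset[i] = first[i] + 1 + j
        else:
            offset[i] = n_samp - 1  # never returns below threshold
    return onset, offset, found


def detect_window(sweep: EMGSweep, params: DetectionParams | None = None) -> Optional[MEPWindow]:
    """Detect the MEP onset/offset in one sweep; ``None`` when no MEP occurs."""
    params = params or DetectionParams()
    onset, offset, found = _detect_array(
        sweep.samples[None, :], sweep.sampling_rate, sweep.stimulus_index, params
    )
    if not found[0]:
        return None
    to_ms = 1000.0 / sweep.sampling_rate
    return MEPWindow(
        onset_ms=(onset[0] - sweep.stimulus_index) * to_ms,
        offset_ms=(offset[0] - sweep.stimulus_index) * to_ms,
        source="automatic",
    )


def detect_windows(
    sweeps: Sequence[EMGSweep], params: DetectionParams | None = None
) -> list[Optional[MEPWindow]]:
    """Per-sweep MEP windows for a list of sweeps (``None`` marks absent MEPs)."""
    return [detect_window(s, params) for s in sweeps]


def site_amplitude(
    sweeps: Sequence[EMGSweep],
    windows: Sequence[Optional[MEPWindow]],
    background_window_ms: tuple[float, float] = (-500.0, -5.0),
) -> SiteAmplitude:
    """Average the background-corrected amplitudes of the stimuli at one site.

    Only sweeps with a detected (or annotated) MEP contribute; a site where no
    stimulus evoked an MEP gets amplitude 0 with ``n_stimuli_used = 0`` so the
    map remains a full grid.
    """
    if not sweeps:
        raise ValueError("site_amplitude requires at least one sweep")
    if len(windows) != len(sweeps):
        raise ValueError("one window (or None) required per sweep")
    keys = {(s.subject_id, s.channel, s.site) for s in sweeps}
    if len(keys) > 1:
        raise ValueError(f"sweeps from mixed subject/muscle/site: {sorted(keys)}")
    amps = [
        corrected_amplitude(s, w, background_window_ms)
        for s, w in zip(sweeps, windows)
        if w is not None
    ]
    ref = sweeps[0]
    return SiteAmplitude(
        subject_id=ref.subject_id,
        muscle=ref.channel,
        site=ref.site,
        mean_amplitude_uV=float(np.mean(amps)) if amps else 0.0,
        n_stimuli_used=len(amps),
    )


def channel_qc(
    amplitudes: Sequence[SiteAmplitude],
    background_rms_values: Sequence[float],
    *,
    background_ceiling_uV: float = 30.0,
    clipped_fraction: float = 0.0,
) -> str:
    """Quality verdict for one subject-muscle channel over the full grid.

    Returns ``"no-mep"`` when no site evoked a detectable MEP, ``"poor-quality"``
    when the median background RMS exceeds the configured ceiling or more than
    half the sweeps are clipped, else ``"usable"``.  Excluded channels are
    dropped from group analyses (their per-muscle n shrinks accordingly).
    """
    if not amplitudes:
        raise ValueError("channel_qc requires site amplitudes for the attempted grid")
    if all(a.n_stimuli_used == 0 for a in amplitudes):
        return "no-mep"
    if float(np.median(background_rms_values)) > background_ceiling_uV or clipped_fraction > 0.5:
        return "poor-quality"
    return "usable"


def sweep_array_amplitudes(
    arr: np.ndarray,
    fs: float,
    stim: int,
    params: DetectionParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrected amplitude per sweep for a (n_sweeps, n_samples) array.

    Vectorised equivalent of ``detect_window`` + ``corrected_amplitude`` for
    cohort-scale processing.  Returns ``(amplitudes_uV, detected_mask)``;
    undetected sweeps get amplitude 0 and ``detected=False``.
    """
    params = params or DetectionParams()
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    onset, offset, found = _detect_array(arr, fs, stim, params)
    bg_sl = _background_slice(arr.shape[1], stim, fs, params.background_window_ms)
    bg = _rms(arr[:, bg_sl], axis=1)
    amps = np.zeros(arr.shape[0])
    for i in np.nonzero(found)[0]:
        seg = arr[i, onset[i] : offset[i] + 1]
        amps[i] = max(float(_rms(seg)) - bg[i], 0.0)
    return amps, found
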