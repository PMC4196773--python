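"""Signal conditioning for thigh-cuff manoeuvre recordings.

Raw transcranial-Doppler CBFV and Finapres-style ABP recordings (typically
200 Hz) are reduced to the uniformly sampled beat-mean series on which every
autoregulation index in this package operates:

1. zero-phase Butterworth low-pass filtering (default 8th order, 20 Hz);
2. cardiac-cycle marking at diastolic ABP minima;
3. per-beat averaging and cubic-spline resampling to a constant rate
   (default 5 Hz);
4. drop normalisation so the pre-release baseline maps to 1 and the
   post-release minimum maps to 0.

All time windows are in seconds with t = 0 at the start of the recording;
``t0`` is the cuff-release time and must be supplied explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import InsufficientDataError, InvalidParameterError, NoDropError

__all__ = [
    "RawRecording",
    "Manoeuvre",
    "NormalisedResponse",
    "lowpass_filter",
    "detect_beats",
    "beat_resample",
    "normalise_drop",
    "preprocess_recording",
]

#: Physiological inter-beat interval bounds (seconds) used to sanity-check
#: beat detection: 0.3 s (200 bpm) to 2.0 s (30 bpm).
IBI_BOUNDS = (0.3, 2.0)


@dataclass(frozen=True)
class RawRecording:
    """A raw two-channel recording: ABP (mmHg) and CBFV (cm/s).

    ``time`` must be strictly increasing and consistent with ``sample_rate``.
    """

    time: np.ndarray
    abp: np.ndarray
    cbfv: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        abp = np.asarray(self.abp, dtype=float)
        cbfv = np.asarray(self.cbfv, dtype=float)
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")
        if time.ndim != 1 or np.any(np.diff(time) <= 0):
            raise InvalidParameterError("time must be 1-D and strictly increasing")
        if abp.shape != time.shape or cbfv.shape != time.shape:
            raise InvalidParameterError("abp/cbfv must have the same length as time")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "abp", abp)
        object.__setattr__(self, "cbfv", cbfv)


@dataclass
class Manoeuvre:
    """Uniformly sampled paired ABP/CBFV series for one thigh-cuff manoeuvre.

    ``t0`` is the cuff-release time in seconds from the start of the series.
    ``meta`` carries subject/repetition labels and any ground-truth labels
    attached by the simulator.
    """

    abp: np.ndarray
    cbfv: np.ndarray
    rate: float = 5.0
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abp = np.asarray(self.abp, dtype=float)
        self.cbfv = np.asarray(self.cbfv, dtype=float)
        if self.rate <= 0:
            raise InvalidParameterError("rate must be positive")
        if self.abp.shape != self.cbfv.shape or self.abp.ndim != 1:
            raise InvalidParameterError("abp and cbfv must be 1-D of equal length")
        if not (0.0 <= self.t0 <= self.duration):
            raise InvalidParameterError(
                f"t0={self.t0} outside the recorded span [0, {self.duration:.2f}]"
            )

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.abp.size) / self.rate

    @property
    def duration(self) -> float:
        return (self.abp.size - 1) / self.rate


@dataclass
class NormalisedResponse:
    """A series rescaled to drop units: baseline -> 1, post-release minimum -> 0.

    ``values`` shares the sampling grid of the input; ``t_min`` is the time of
    the minimum located in the search window after ``t0``; ``baseline`` and
    ``drop_amplitude`` are in original units so the mapping is invertible.
    """

    values: np.ndarray
    rate: float
    t0: float
    t_min: float
    baseline: float
    drop_amplitude: float

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate


def lowpass_filter(
    values: np.ndarray, sample_rate: float, order: int = 8, cutoff: float = 20.0
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    Applied forward-backward (``filtfilt``) so beat timing is not shifted;
    the effective magnitude response is the squared one-pass response.

    Raises
    ------
    InvalidParameterError
        If ``cutoff`` is at or above the Nyquist frequency.
    """
    if cutoff >= sample_rate / 2:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz >= Nyquist {sample_rate / 2} Hz"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(values, dtype=float))


def detect_beats(
    abp: np.ndarray,
    sample_rate: float,
    refractory: float = IBI_BOUNDS[0],
    window: float = 2.0,
) -> np.ndarray:
    """Mark cardiac-cycle onsets at diastolic ABP minima.

    A sample is an onset candidate if it is a local minimum lying below a
    rolling-median threshold (median over ``window`` seconds minus a fraction
    of the local pulse amplitude); candidates closer than ``refractory``
    seconds to the previous accepted onset are discarded.

    Returns onset times in seconds; empty (with a warning) if the signal has
    no usable pulsatile component.
    """
    x = np.asarray(abp, dtype=float)
    n = x.size
    if n < 3 or np.ptp(x) == 0:
        warnings.warn("no pulsatile component detected; returning no beats")
        return np.array([])

    half = max(1, int(round(window * sample_rate / 2)))
    # rolling median and local amplitude to track slow baseline drift
    med = np.empty(n)
    amp = np.empty(n)
    for i in range(n):
        seg = x[max(0, i - half) : min(n, i + half + 1)]
        med[i] = np.median(seg)
        amp[i] = np.ptp(seg)
    thresh = med - 0.25 * amp

    # strict local minima (plateaus: keep first sample of the plateau)
    interior = np.arange(1, n - 1)
    is_min = (x[interior] < x[interior - 1]) & (x[interior] <= x[interior + 1])
    candidates = interior[is_min & (x[interior] < thresh[interior])]

    onsets: list[int] = []
    min_gap = refractory * sample_rate
    for idx in candidates:
        if onsets and idx - onsets[-1] < min_gap:
            # within the refractory period: keep the deeper minimum
            if x[idx] < x[onsets[-1]]:
                onsets[-1] = idx
            continue
        onsets.append(idx)

    if not onsets:
        warnings.warn("no beats found in ABP channel")
        return np.array([])
    times = np.asarray(onsets, dtype=float) / sample_rate
    ibi = np.diff(times)
    if ibi.size and (np.any(ibi < IBI_BOUNDS[0]) or np.any(ibi > IBI_BOUNDS[1])):
        warnings.warn(
            "inter-beat intervals outside physiological bounds "
            f"{IBI_BOUNDS}; check signal quality"
        )
    return times


def beat_resample(
    values: np.ndarray,
    sample_rate: float,
    beat_times: np.ndarray,
    out_rate: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat means resampled to a uniform rate.

    The mean of ``values`` over each cardiac cycle is placed at the cycle's
    onset time; a cubic spline through those points is evaluated on a uniform
    grid at ``out_rate`` covering the beat-marked span.

    Returns ``(grid_times, resampled_values)``.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 beats are available.
    """
    x = np.asarray(values, dtype=float)
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 3:
        raise InsufficientDataError(
            f"beat_resample needs >= 3 beats, got {beat_times.size}"
        )
    idx = np.round(beat_times * sample_rate).astype(int)
    means = np.array([x[a:b].mean() for a, b in zip(idx[:-1], idx[1:])])
    # the final onset only closes the last complete cycle; the uniform grid
    # spans the onsets that carry a cycle mean (no extrapolation)
    spline = CubicSpline(beat_times[:-1], means)
    grid = np.arange(beat_times[0], beat_times[-2] + 0.5 / out_rate, 1.0 / out_rate)
    grid = grid[grid <= beat_times[-2] + 1e-9]
    return grid, spline(grid)


def normalise_drop(
    values: np.ndarray,
    rate: float,
    t0: float,
    baseline_window: float = 4.0,
    search_window: float = 6.0,
    include_t0: bool = True,
    tolerance: float = 1e-9,
) -> NormalisedResponse:
    """Rescale a series to drop units: baseline -> 1, post-release minimum -> 0.

    baseline = mean over the ``baseline_window`` seconds immediately before
    ``t0``; the minimum is located over ``[t0, t0 + search_window]``
    (``include_t0=False`` excludes the release sample itself). Output is
    ``(x - x(t_min)) / (baseline - x(t_min))``. Ties for the minimum go to
    the earliest sample.

    Raises
    ------
    InsufficientDataError
        If the baseline or search window is not fully recorded.
    NoDropError
        If the drop amplitude is at or below ``tolerance``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    i0 = int(round(t0 * rate))
    ib = i0 - int(round(baseline_window * rate))
    if ib < 0 or i0 > n:
        raise InsufficientDataError("baseline window not fully recorded before t0")
    baseline = x[ib:i0].mean() if i0 > ib else x[i0]

    lo = i0 if include_t0 else i0 + 1
    hi = i0 + int(round(search_window * rate)) + 1
    if lo >= n:
        raise InsufficientDataError("no samples after t0")
    if hi > n:
        raise InsufficientDataError(
            f"search window extends {hi - n} samples past the recording"
        )
    seg = x[lo:hi]
    imin = lo + int(np.argmin(seg))  # argmin returns the first of tied minima
    xmin = x[imin]
    amp = baseline - xmin
    if amp <= tolerance:
        raise NoDropError(
            f"drop amplitude {amp:.3g} <= tolerance {tolerance:.3g}; no usable drop"
        )
    return NormalisedResponse(
        values=(x - xmin) / amp,
        rate=rate,
        t0=t0,
        t_min=imin / rate,
        baseline=baseline,
        drop_amplitude=amp,
    )


def preprocess_recording(
    rec: RawRecording,
    t0: float,
    out_rate: float = 5.0,
    filter_order: int = 8,
    filter_cutoff: float = 20.0,
    meta: dict | None = None,
) -> Manoeuvre:
    """Full conditioning chain: filter, beat-mark, beat-average, resample.

    Both channels are low-pass filtered; beats are marked on the (filtered)
    ABP channel and the same cycle boundaries are applied to CBFV so the two
    beat-mean series stay aligned. ``t0`` is re-expressed relative to the
    start of the resampled grid.
    """
    abp_f = lowpass_filter(rec.abp, rec.sample_rate, filter_order, filter_cutoff)
    cbfv_f = lowpass_filter(rec.cbfv, rec.sample_rate, filter_order, filter_cutoff)
    beats = detect_beats(abp_f, rec.sample_rate)
    if beats.size < 3:
        raise InsufficientDataError("fewer than 3 beats marked in the ABP channel")
    offset = rec.time[0]
    grid, abp_u = beat_resample(abp_f, rec.sample_rate, beats, out_rate)
    _, cbfv_u = beat_resample(cbfv_f, rec.sample_rate, beats, out_rate)
    return Manoeuvre(
        abp=abp_u,
        cbfv=cbfv_u,
        rate=out_rate,
        t0=t0 - offset - grid[0],
        meta=meta or {},
    )
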