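"""EEG preprocessing: band-pass filtering, baseline correction, windowing.

Raw multichannel motor-imagery EEG is band-limited to the 8-32 Hz range
covering the mu (8-13 Hz) and beta (13-30 Hz) rhythms, baseline-corrected
against the -200..0 ms pre-cue interval, and cut into overlapping 2 s
windows that slide at 40 ms over the 1-4 s post-cue imagery period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt


@dataclass
class EEGRecording:
    """A continuous multichannel recording with cue events.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    channel_names : list of str
        Ordered 10-10 electrode labels, unique.
    fs : float
        Sampling rate in Hz.
    events : list of (int, int)
        ``(onset_sample, class_label)`` pairs; labels in ``{0, 1, 2, 3}``.
    """

    samples: np.ndarray
    channel_names: list[str]
    fs: float = 250.0
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, times) matrix")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length must match samples rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        n = self.samples.shape[1]
        for onset, label in self.events:
            if not 0 <= onset < n:
                raise ValueError(f"event onset {onset} outside recording")


@dataclass
class EpochSet:
    """Labelled EEG trials or windows, shape (n_trials, n_channels, n_samples)."""

    data: np.ndarray
    labels: np.ndarray
    channel_names: list[str]
    fs: float = 250.0
    window_len_s: float | None = None
    stride_s: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must match trial count")
        if self.labels.size and not np.all((self.labels >= 0) & (self.labels <= 3)):
            raise ValueError("labels must lie in {0,1,2,3}")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def pick_channels(self, names: list[str]) -> "EpochSet":
        idx = [self.channel_names.index(n) for n in names]
        return EpochSet(self.data[:, idx, :], self.labels, list(names), self.fs,
                        self.window_len_s, self.stride_s)


def _design_bandpass(lo: float, hi: float, fs: float, order: int):
    if not (0 < lo < hi < fs / 2):
        raise ValueError(
            f"band ({lo}, {hi}) Hz must satisfy 0 < lo < hi < fs/2 = {fs / 2}")
    return butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(x, fs: float, lo: float = 8.0, hi: float = 32.0,
                    order: int = 4):
    """Zero-phase Butterworth band-pass along the last axis.

    Forward-backward application keeps window energies phase-aligned; the
    effective magnitude response is the squared single-pass response.
    """
    sos = _design_bandpass(lo, hi, fs, order)
    return sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def bandpass_recording(rec: EEGRecording, lo: float = 8.0, hi: float = 32.0,
                       order: int = 4) -> EEGRecording:
    """Band-pass an :class:`EEGRecording`, preserving metadata."""
    return EEGRecording(bandpass_filter(rec.samples, rec.fs, lo, hi, order),
                        list(rec.channel_names), rec.fs, list(rec.events))


def baseline_correct(epoch_data, fs: float, t0_ms: float = -200.0,
                     t1_ms: float = 0.0, epoch_start_ms: float = -200.0):
    """Subtract the per-channel mean over the baseline window from the epoch.

    ``epoch_start_ms`` locates the first epoch sample on the cue-relative time
    axis, so the default epoch starts exactly at the baseline onset.
    """
    epoch_data = np.asarray(epoch_data, dtype=float)
    n = epoch_data.shape[-1]
    i0 = int(round((t0_ms - epoch_start_ms) * fs / 1000.0))
    i1 = int(round((t1_ms - epoch_start_ms) * fs / 1000.0))
    if not (0 <= i0 < i1 <= n):
        raise ValueError("baseline window lies outside the epoch")
    base = epoch_data[..., i0:i1].mean(axis=-1, keepdims=True)
    return epoch_data - base


def window_segment(trial, fs: float, win_s: float = 2.0, stride_s: float = 0.04,
                   t_start_s: float = 1.0, t_end_s: float = 4.0):
    """Cut one trial into sliding windows over ``[t_start_s, t_end_s]``.

    Returns an array of shape ``(n_windows, ..., round(win_s * fs))``.  Window
    starts form the arithmetic progression ``t_start, t_start + stride, ...``
    with the last start at most ``t_end - win``; with the 2 s / 40 ms defaults
    over 1-4 s this yields 26 windows.
    """
    if win_s <= 0 or stride_s <= 0:
        raise ValueError("win_s and stride_s must be positive")
    if t_end_s - t_start_s < win_s:
        raise ValueError("analysis span shorter than one window")
    trial = np.asarray(trial, dtype=float)
    T = int(round(win_s * fs))
    n_win = int(np.floor((t_end_s - t_start_s - win_s) / stride_s + 1e-9)) + 1
    out = []
    for w in range(n_win):
        s0 = int(round((t_start_s + w * stride_s) * fs))
        if s0 + T > trial.shape[-1]:
            raise ValueError("trial too short for requested windowing")
        out.append(trial[..., s0:s0 + T])
    return np.stack(out, axis=0)


def epochs_from_recording(rec: EEGRecording, tmin_s: float = -0.2,
                          tmax_s: float = 4.0, baseline: bool = True) -> EpochSet:
    """Extract cue-aligned epochs ``[tmin, tmax)`` around each event.

    Sample coordinates are half-open; trials running past the end of the
    recording raise rather than pad.
    """
    i_lo = int(round(tmin_s * rec.fs))
    i_hi = int(round(tmax_s * rec.fs))
    data, labels = [], []
    for onset, label in rec.events:
        a, b = onset + i_lo, onset + i_hi
        if a < 0 or b > rec.samples.shape[1]:
            raise ValueError(f"epoch around event at {onset} exceeds recording")
        data.append(rec.samples[:, a:b])
        labels.append(label)
    arr = np.stack(data, axis=0) if data else np.empty((0, len(rec.channel_names), i_hi - i_lo))
    if baseline and arr.size:
        arr = baseline_correct(arr, rec.fs, epoch_start_ms=tmin_s * 1000.0)
    return EpochSet(arr, np.asarray(labels, int), list(rec.channel_names), rec.fs)


def window_epochs(epochs: EpochSet, win_s: float = 2.0, stride_s: float = 0.04,
                  t_start_s: float = 1.0, t_end_s: float = 4.0,
                  epoch_t0_s: float = -0.2,
                  every: int = 1) -> tuple[EpochSet, np.ndarray]:
    """Window every trial of an epoch set over the imagery interval.

    Times are cue-relative; ``epoch_t0_s`` is the cue-relative time of each
    trial's first sample.  ``every`` keeps one window in ``every`` (window
    subsampling for cheaper training).  Returns the per-window epoch set and
    the originating trial index of each window.
    """
    wins, labels, trial_idx = [], [], []
    for t in range(epochs.n_trials):
        w = window_segment(epochs.data[t], epochs.fs, win_s, stride_s,
                           t_start_s - epoch_t0_s, t_end_s - epoch_t0_s)
        w = w[::max(1, int(every))]
        wins.append(w)
        labels.extend([epochs.labels[t]] * len(w))
        trial_idx.extend([t] * len(w))
    data = np.concatenate(wins, axis=0)
    out = EpochSet(data, np.asarray(labels, int), list(epochs.channel_names),
                   epochs.fs, window_len_s=win_s, stride_s=stride_s)
    return out, np.asarray(trial_idx, int)
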