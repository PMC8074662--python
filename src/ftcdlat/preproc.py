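"""Raw-recording preprocessing: from bilateral CBFV traces to baseline-
corrected, heart-cycle-integrated peri-stimulus epochs.

The chain (in order) is: block-mean down-sampling to 25 Hz; epoching into
trials from -7 to 27 s peri-stimulus time; rejection of trials with multiple
out-of-range samples; manual exclusions; normalization of each channel to a
recording-wide mean of 100; heart-cycle integration (each cardiac cycle
replaced by its mean, removing pulsatile structure); baseline correction
over -5 to 2 s; and rejection of trials with values below 60 or above 140 on
the normalized scale. :func:`preprocess_recording` runs the whole chain;
:class:`FTCDPreprocessor` wraps it as a transformer.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, TransformerMixin

from .types import CBFVRecording, EpochSet

EPOCH_WINDOW = (-7.0, 27.0)
BASELINE_WINDOW = (-5.0, 2.0)
TARGET_RATE = 25.0


def downsample(recording: CBFVRecording, target_rate: float = TARGET_RATE) -> CBFVRecording:
    """Block-mean decimation to ``target_rate`` (source rate must be an
    integer multiple); markers are snapped to the nearest retained sample."""
    if recording.fs == target_rate:
        return recording
    ratio = recording.fs / target_rate
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"source rate {recording.fs} Hz is not an integer multiple of "
            f"{target_rate} Hz; resample the recording configuration first"
        )
    r = int(round(ratio))
    n = (len(recording.time) // r) * r
    left = recording.left[:n].reshape(-1, r).mean(axis=1)
    right = recording.right[:n].reshape(-1, r).mean(axis=1)
    t = recording.time[:n:r]
    markers = np.array([t[np.argmin(np.abs(t - m))] for m in recording.marker_times])
    return CBFVRecording(
        fs=target_rate,
        time=t,
        left=left,
        right=right,
        marker_times=markers,
        subject=recording.subject,
        task=recording.task,
        session=recording.session,
    )


def epoch(recording: CBFVRecording, window: tuple[float, float] = EPOCH_WINDOW) -> EpochSet:
    """Cut one epoch per marker over the closed peri-stimulus ``window``.

    At 25 Hz and the default [-7, 27] s window each epoch has 851 samples
    (both endpoints included). Epochs extending past either recording edge
    are dropped with a warning. Consecutive epochs may overlap (34 s window
    vs 33 s inter-stimulus interval): samples can belong to two trials.
    Recording-wide raw channel statistics are stored for later QC stages.
    """
    fs = recording.fs
    lo = int(round(window[0] * fs))
    hi = int(round(window[1] * fs))
    times = np.arange(lo, hi + 1) / fs
    lefts, rights, onsets = [], [], []
    n = len(recording.time)
    t0 = recording.time[0]
    for m in recording.marker_times:
        i0 = int(round((m - t0) * fs))
        a, b = i0 + lo, i0 + hi
        if a < 0 or b >= n:
            warnings.warn(
                f"dropping trial at t={m:.2f}s: epoch window extends past recording edge"
            )
            continue
        lefts.append(recording.left[a : b + 1])
        rights.append(recording.right[a : b + 1])
        onsets.append(m)
    k = len(onsets)
    stats = {
        "raw_mean_left": float(np.mean(recording.left)),
        "raw_mean_right": float(np.mean(recording.right)),
        "raw_sd_left": float(np.std(recording.left)),
        "raw_sd_right": float(np.std(recording.right)),
    }
    return EpochSet(
        times=times,
        fs=fs,
        left=np.asarray(lefts, float).reshape(k, len(times)),
        right=np.asarray(rights, float).reshape(k, len(times)),
        onsets=np.asarray(onsets, float),
        usable=np.ones(k, dtype=bool),
        reasons=[None] * k,
        channel_stats=stats,
        subject=recording.subject,
        task=recording.task,
        session=recording.session,
    )


def reject_range_artifacts(epochs: EpochSet, k_sd: float = 4.0, min_count: int = 5) -> EpochSet:
    """Flag trials with more than ``min_count`` samples (in either channel)
    outside mean +/- ``k_sd``*SD of that channel over the whole recording."""
    out = epochs.copy()
    scale = "norm" if out.normalized else "raw"
    for ch in ("left", "right"):
        mu = out.channel_stats[f"{scale}_mean_{ch}"]
        sd = out.channel_stats[f"{scale}_sd_{ch}"]
        vals = getattr(out, ch)
        bad = np.sum(np.abs(vals - mu) > k_sd * sd, axis=1)
        for i in np.nonzero(bad > min_count)[0]:
            out.flag(int(i), "range-artifact")
    return out


def apply_manual_exclusions(epochs: EpochSet, exclusions) -> EpochSet:
    """Flag listed trials. ``exclusions`` is an iterable of trial indices
    (reason 'manual') or a mapping index -> 'manual'|'no-response'."""
    out = epochs.copy()
    items = exclusions.items() if hasattr(exclusions, "items") else ((i, "manual") for i in exclusions)
    for idx, reason in items:
        if not 0 <= idx < out.n_trials:
            raise IndexError(f"trial index {idx} out of range (n={out.n_trials})")
        if reason not in ("manual", "no-response"):
            raise ValueError("manual-exclusion reason must be 'manual' or 'no-response'")
        out.flag(int(idx), reason)
    return out


def normalize(epochs: EpochSet) -> EpochSet:
    """Scale each channel by its recording-wide mean so the channel mean is
    100 (percent units). The normalization constants are recorded."""
    if epochs.normalized:
        return epochs.copy()
    out = epochs.copy()
    for ch in ("left", "right"):
        mu = out.channel_stats[f"raw_mean_{ch}"]
        if mu <= 0:
            raise ValueError(f"non-positive {ch}-channel mean; cannot normalize")
        setattr(out, ch, getattr(out, ch) * (100.0 / mu))
        out.channel_stats[f"norm_const_{ch}"] = mu
        out.channel_stats[f"norm_mean_{ch}"] = 100.0
        out.channel_stats[f"norm_sd_{ch}"] = out.channel_stats[f"raw_sd_{ch}"] * 100.0 / mu
    out.normalized = True
    return out


def detect_heartbeats(source, min_interval: float = 0.4) -> np.ndarray:
    """Detect heartbeat times as local maxima of the mean of both channels,
    separated by at least ``min_interval`` seconds.

    Accepts a recording (preferred: beats are found on the continuous trace)
    or an epoch set (beats found per trial and merged). A flat signal yields
    zero beats with a warning.
    """
    if isinstance(source, CBFVRecording):
        sig = (source.left + source.right) / 2.0
        return source.time[_peaks(sig, source.fs, min_interval)]
    if isinstance(source, EpochSet):
        beats: list[float] = []
        for i in range(source.n_trials):
            sig = (source.left[i] + source.right[i]) / 2.0
            for j in _peaks(sig, source.fs, min_interval, warn=False):
                beats.append(float(source.onsets[i] + source.times[j]))
        beats = np.array(sorted(beats))
        if len(beats) == 0:
            warnings.warn("no heartbeats detected (flat signal?)")
            return beats
        keep = np.concatenate([[True], np.diff(beats) > min_interval / 2])
        return beats[keep]
    raise TypeError("detect_heartbeats expects a CBFVRecording or EpochSet")


def _peaks(sig: np.ndarray, fs: float, min_interval: float, warn: bool = True) -> np.ndarray:
    sd = np.std(sig)
    if sd == 0:
        if warn:
            warnings.warn("no heartbeats detected: flat signal")
        return np.array([], dtype=int)
    idx, _ = find_peaks(sig, distance=max(1, int(round(min_interval * fs))), prominence=0.1 * sd)
    return idx


def heart_cycle_integrate(epochs: EpochSet, beats: np.ndarray) -> EpochSet:
    """Replace every sample within each inter-beat interval by the interval
    mean (piecewise-constant output). Samples before the first / after the
    last beat in an epoch take the nearest interval's mean. Epochs spanned
    by fewer than two beats are flagged unusable."""
    out = epochs.copy()
    beats = np.asarray(beats, float)
    for i in range(out.n_trials):
        t_abs = out.onsets[i] + out.times
        b = beats[(beats >= t_abs[0]) & (beats <= t_abs[-1])]
        if len(b) < 2:
            out.flag(i, "no-heartbeat")
            continue
        idx = np.clip(np.searchsorted(b, t_abs, side="right") - 1, 0, len(b) - 2)
        # interval means use only samples inside [b_k, b_{k+1}); edge samples
        # before the first / after the last beat take the nearest mean
        in_range = (t_abs >= b[0]) & (t_abs < b[-1])
        counts = np.bincount(idx[in_range], minlength=len(b) - 1)
        for ch in ("left", "right"):
            vals = getattr(out, ch)[i]
            sums = np.bincount(idx[in_range], weights=vals[in_range], minlength=len(b) - 1)
            with np.errstate(invalid="ignore"):
                means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            if np.any(np.isnan(means)):  # empty interval: borrow nearest mean
                good = np.nonzero(~np.isnan(means))[0]
                if len(good) == 0:
                    out.flag(i, "no-heartbeat")
                    break
                nearest = good[np.argmin(np.abs(np.arange(len(means))[:, None] - good), axis=1)]
                means = means[nearest]
            getattr(out, ch)[i] = means[idx]
    out.integrated = True
    out.beats = beats
    return out


def baseline_correct(epochs: EpochSet, baseline: tuple[float, float] = BASELINE_WINDOW) -> EpochSet:
    """Subtract each trial's per-channel mean over the baseline window, so
    corrected baselines average zero. The subtracted constants are kept so
    QC stages can shift values back to the 100-centred scale."""
    if baseline[0] < epochs.times[0] or baseline[1] > epochs.times[-1]:
        raise ValueError("baseline window lies outside the epoch window")
    out = epochs.copy()
    mask = (out.times >= baseline[0]) & (out.times <= baseline[1])
    bl = np.zeros((out.n_trials, 2))
    for c, ch in enumerate(("left", "right")):
        vals = getattr(out, ch)
        m = vals[:, mask].mean(axis=1)
        setattr(out, ch, vals - m[:, None])
        bl[:, c] = m
    out.baselined = True
    out.baseline_means = bl
    return out


def reject_extreme_trials(epochs: EpochSet, low: float = 60.0, high: float = 140.0) -> EpochSet:
    """Flag trials with any sample strictly below ``low`` or strictly above
    ``high`` on the normalized (100-centred, pre-baseline) scale."""
    if not epochs.normalized:
        raise ValueError("extreme-value rejection requires normalized epochs")
    out = epochs.copy()
    for c, ch in enumerate(("left", "right")):
        vals = getattr(out, ch)
        if out.baselined:
            vals = vals + out.baseline_means[:, c][:, None]
        bad = np.any((vals < low) | (vals > high), axis=1)
        for i in np.nonzero(bad)[0]:
            out.flag(int(i), "extreme-value")
    return out


def preprocess_recording(
    recording: CBFVRecording,
    manual_exclusions=None,
    target_rate: float = TARGET_RATE,
    window: tuple[float, float] = EPOCH_WINDOW,
    baseline: tuple[float, float] = BASELINE_WINDOW,
    k_sd: float = 4.0,
    min_count: int = 5,
    range_low: float = 60.0,
    range_high: float = 140.0,
    min_beat_interval: float = 0.4,
) -> EpochSet:
    """Run the full preprocessing chain on one raw recording."""
    rec = downsample(recording, target_rate)
    ep = epoch(rec, window)
    if ep.n_trials == 0:
        return ep
    ep = reject_range_artifacts(ep, k_sd=k_sd, min_count=min_count)
    if manual_exclusions:
        ep = apply_manual_exclusions(ep, manual_exclusions)
    ep = normalize(ep)
    beats = detect_heartbeats(rec, min_interval=min_beat_interval)
    ep = heart_cycle_integrate(ep, beats)
    ep = reject_extreme_trials(ep, low=range_low, high=range_high)
    ep = baseline_correct(ep, baseline)
    return ep


class FTCDPreprocessor(BaseEstimator, TransformerMixin):
    """Transformer wrapping :func:`preprocess_recording`.

    ``transform`` maps a recording (or list of recordings) to an
    :class:`~ftcdlat.types.EpochSet` (or list thereof). Stateless: ``fit``
    only validates parameters.
    """

    def __init__(
        self,
        target_rate: float = TARGET_RATE,
        window: tuple[float, float] = EPOCH_WINDOW,
        baseline: tuple[float, float] = BASELINE_WINDOW,
        k_sd: float = 4.0,
        min_count: int = 5,
        range_low: float = 60.0,
        range_high: float = 140.0,
        min_beat_interval: float = 0.4,
        exclusions=None,
    ):
        self.target_rate = target_rate
        self.window = window
        self.baseline = baseline
        self.k_sd = k_sd
        self.min_count = min_count
        self.range_low = range_low
        self.range_high = range_high
        self.min_beat_interval = min_beat_interval
        self.exclusions = exclusions

    def fit(self, X=None, y=None):
        if self.baseline[0] < self.window[0] or self.baseline[1] > self.window[1]:
            raise ValueError("baseline window must lie inside the epoch window")
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        if isinstance(X, CBFVRecording):
            return self._one(X)
        return [self._one(rec) for rec in X]

    def _one(self, rec: CBFVRecording) -> EpochSet:
        excl = None
        if self.exclusions:
            excl = self.exclusions.get((rec.subject, rec.task, rec.session))
        return preprocess_recording(
            rec,
            manual_exclusions=excl,
            target_rate=self.target_rate,
            window=self.window,
            baseline=self.baseline,
            k_sd=self.k_sd,
            min_count=self.min_count,
            range_low=self.range_low,
            range_high=self.range_high,
            min_beat_interval=self.min_beat_interval,
        )
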