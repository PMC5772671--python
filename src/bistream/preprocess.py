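"""Preprocessing: filtering, downsampling, trial labelling, epoching,
baseline correction and robust averaging.

The chain runs in a fixed order: band-limit (separate 5th-order Butterworth
high-pass at 0.1 Hz and low-pass at 30 Hz, both zero-phase), downsample to
300 Hz, label each 600 ms trial from the button stream, drop ambiguous and
switch-adjacent trials, epoch 0-600 ms (180 samples at 300 Hz), subtract the
baseline, and form per-condition evoked responses by iteratively reweighted
(bisquare) robust averaging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .synth import BUTTON_CODES, BUTTON_NAMES, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "EpochSet",
    "EvokedPair",
    "filter_downsample",
    "label_trials",
    "exclude_switch_adjacent",
    "epoch",
    "baseline_correct",
    "robust_average",
    "evoked_pair",
    "preprocess_recording",
]

AMBIGUOUS = "ambiguous"


@dataclass
class FilterSpec:
    highpass_hz: float = 0.1
    lowpass_hz: float = 30.0
    order: int = 5
    target_fs_hz: float = 300.0

    def __post_init__(self) -> None:
        if not (0 < self.highpass_hz < self.lowpass_hz < self.target_fs_hz / 2):
            raise ValueError("need 0 < highpass < lowpass < target_fs/2")


@dataclass
class EpochSet:
    """Epoched trials (trials x sensors x samples) with labels and retention.

    ``retained`` marks trials that survive ambiguity and switch-adjacency
    exclusion; analyses operate on the retained subset.
    """

    data: np.ndarray
    fs_hz: float
    window_ms: tuple[float, float]
    labels: np.ndarray  # per-trial state name or "ambiguous"
    retained: np.ndarray  # bool mask
    trial_onset_samples: np.ndarray
    baseline_window_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != self.data.shape[0] or len(self.retained) != self.data.shape[0]:
            raise ValueError("labels/retained must match trial count")
        if np.any(self.retained & (self.labels == AMBIGUOUS)):
            raise ValueError("retained trials must have unambiguous labels")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def select(self, condition: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(data, labels) of retained trials, optionally for one condition."""
        m = self.retained.copy()
        if condition is not None:
            m &= self.labels == condition
        return self.data[m], self.labels[m]


@dataclass
class EvokedPair:
    evoked_gallop: np.ndarray  # sensors x samples
    evoked_segregated: np.ndarray
    weights: dict = field(default_factory=dict)  # condition -> robust weights


# ---------------------------------------------------------------------------
# Filtering and downsampling
# ---------------------------------------------------------------------------

def filter_downsample(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase band-limit then downsample a Recording.

    High-pass and low-pass are applied as separate Butterworth filters of the
    configured order, forward-backward (so the effective order doubles).  If
    the source rate is an integer multiple of the target the data are
    decimated by slicing (the 30 Hz low-pass already prevents aliasing);
    otherwise ``resample_poly`` is used and a warning logged.  Event sample
    indices and the button stream are rescaled to the new rate.
    """
    if spec is None:
        spec = FilterSpec()
    if rec.fs_hz < 2 * spec.lowpass_hz:
        raise ValueError("recording rate below Nyquist for the low-pass corner")

    sos_hp = signal.butter(spec.order, spec.highpass_hz, "highpass", fs=rec.fs_hz, output="sos")
    sos_lp = signal.butter(spec.order, spec.lowpass_hz, "lowpass", fs=rec.fs_hz, output="sos")

    ratio = rec.fs_hz / spec.target_fs_hz
    integer = abs(ratio - round(ratio)) < 1e-9
    if integer:
        step = int(round(ratio))
        n_out = int(np.ceil(rec.n_samples / step))
    else:
        logger.warning(
            "fs %.6g not integer-divisible by target %.6g; polyphase resampling",
            rec.fs_hz,
            spec.target_fs_hz,
        )
        from fractions import Fraction

        frac = Fraction(spec.target_fs_hz / rec.fs_hz).limit_denominator(1000)
        up, down = frac.numerator, frac.denominator
        n_out = int(np.ceil(rec.n_samples * up / down))

    out = np.empty((rec.n_sensors, n_out))
    for ch in range(rec.n_sensors):  # channel loop keeps peak memory low
        x = signal.sosfiltfilt(sos_lp, signal.sosfiltfilt(sos_hp, rec.data[ch]))
        out[ch] = x[::step] if integer else signal.resample_poly(x, up, down)

    scale = spec.target_fs_hz / rec.fs_hz
    onsets = np.round(rec.stim_onsets * scale).astype(np.int64)
    idx = np.minimum(
        np.round(np.arange(n_out) / scale).astype(np.int64), rec.n_samples - 1
    )
    button = rec.button_stream[idx]

    meta = dict(rec.meta)
    meta["filter"] = {
        "highpass_hz": spec.highpass_hz,
        "lowpass_hz": spec.lowpass_hz,
        "order": spec.order,
        "zero_phase": True,
        "original_fs_hz": rec.fs_hz,
    }
    return Recording(
        data=out,
        fs_hz=spec.target_fs_hz,
        channel_pos=rec.channel_pos,
        stim_onsets=onsets,
        button_stream=button,
        lead_field=rec.lead_field,
        source_pos=rec.source_pos,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Labelling and exclusion
# ---------------------------------------------------------------------------

def label_trials(rec: Recording, timeline: np.ndarray | None = None) -> np.ndarray:
    """Label each trial by the single button state held throughout its
    window; any mix, "none" or "both" makes the trial ambiguous."""
    if timeline is None:
        timeline = rec.stim_onsets
    spt = int(round(0.6 * rec.fs_hz))
    labels = np.empty(len(timeline), dtype="<U16")
    for i, onset in enumerate(timeline):
        win = rec.button_stream[onset : onset + spt]
        if win.size < spt:
            labels[i] = AMBIGUOUS
            continue
        first = win[0]
        if first in (BUTTON_CODES["gallop"], BUTTON_CODES["segregated"]) and np.all(
            win == first
        ):
            labels[i] = BUTTON_NAMES[int(first)]
        else:
            labels[i] = AMBIGUOUS
    return labels


def exclude_switch_adjacent(labels: np.ndarray, n_exclude: int = 1) -> np.ndarray:
    """Retention mask dropping ambiguous trials and, at every state change
    between consecutive unambiguous trials, the ``n_exclude`` trials on each
    side of the switch."""
    labels = np.asarray(labels)
    retained = labels != AMBIGUOUS
    unamb = np.flatnonzero(retained)
    for k in range(len(unamb) - 1):
        if labels[unamb[k]] != labels[unamb[k + 1]]:
            retained[unamb[max(k - n_exclude + 1, 0) : k + 1]] = False
            retained[unamb[k + 1 : k + 1 + n_exclude]] = False
    return retained


# ---------------------------------------------------------------------------
# Epoching and baseline
# ---------------------------------------------------------------------------

def epoch(
    rec: Recording,
    timeline: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    window_ms: tuple[float, float] = (0.0, 600.0),
) -> EpochSet:
    """Cut fixed-length epochs (default 0-600 ms -> 180 samples at 300 Hz).

    Trials extending past the end of the recording are dropped (logged).
    Raises if no trial is retained.
    """
    if timeline is None:
        timeline = rec.stim_onsets
    if labels is None:
        labels = label_trials(rec, timeline)
    if mask is None:
        mask = exclude_switch_adjacent(labels)
    n_samp = int(round((window_ms[1] - window_ms[0]) * rec.fs_hz / 1000.0))
    start = timeline + int(round(window_ms[0] * rec.fs_hz / 1000.0))
    fits = start + n_samp <= rec.n_samples
    if not np.all(fits):
        logger.info("dropping %d trials extending past recording end", (~fits).sum())
    timeline, labels, mask, start = (
        timeline[fits],
        np.asarray(labels)[fits],
        np.asarray(mask)[fits],
        start[fits],
    )
    if not mask.any():
        raise ValueError("no retained trials to epoch")
    data = np.stack([rec.data[:, s : s + n_samp] for s in start])
    return EpochSet(
        data=data,
        fs_hz=rec.fs_hz,
        window_ms=tuple(window_ms),
        labels=labels,
        retained=mask,
        trial_onset_samples=timeline,
    )


def baseline_correct(
    ep: EpochSet, window_ms: tuple[float, float] | None = None
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window.

    The stimulus is continuous (no silent pre-stimulus period), so the
    default baseline is the whole epoch.
    """
    if window_ms is None:
        window_ms = ep.window_ms
    i0 = int(round((window_ms[0] - ep.window_ms[0]) * ep.fs_hz / 1000.0))
    i1 = int(round((window_ms[1] - ep.window_ms[0]) * ep.fs_hz / 1000.0))
    if not (0 <= i0 < i1 <= ep.data.shape[2]):
        raise ValueError("baseline window outside the epoch")
    data = ep.data - ep.data[:, :, i0:i1].mean(axis=2, keepdims=True)
    return replace(ep, data=data, baseline_window_ms=tuple(window_ms))


# ---------------------------------------------------------------------------
# Robust averaging
# ---------------------------------------------------------------------------

def robust_average(
    ep_or_data: EpochSet | np.ndarray,
    condition: str | None = None,
    k: float = 4.685,
    tol: float = 1e-6,
    max_iter: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively reweighted trial average (bisquare weights).

    At each iteration residuals against the current estimate are scaled by
    the across-trial MAD per channel/timepoint; weights are
    ``(1 - (r/(k*MAD))^2)^2`` for ``|r| < k*MAD`` and 0 otherwise.  Where the
    MAD vanishes (e.g. identical trials) zero residuals get weight 1 and
    non-zero residuals weight 0.  Timepoints where every weight is zero fall
    back to the across-trial median (with a warning).

    Returns (evoked sensors x samples, weights trials x sensors x samples).
    """
    if isinstance(ep_or_data, EpochSet):
        data, _ = ep_or_data.select(condition)
    else:
        data = np.asarray(ep_or_data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("robust averaging needs at least 2 trials")

    est = data.mean(axis=0)
    weights = np.ones_like(data)
    scale0 = np.abs(data).max() + 1e-300
    for _ in range(max_iter):
        r = data - est
        mad = np.median(np.abs(r), axis=0)
        tiny = mad < 1e-12 * scale0
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.abs(r) / (k * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        # degenerate scale: keep exact agreement, reject anything else
        w = np.where(tiny, (np.abs(r) <= 1e-9 * scale0).astype(float), w)
        wsum = w.sum(axis=0)
        dead = wsum == 0
        if dead.any():
            warnings.warn(
                "all-zero robust weights at some timepoints; falling back to median",
                RuntimeWarning,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            new_est = (w * data).sum(axis=0) / wsum
        if dead.any():
            med = np.median(data, axis=0)
            new_est = np.where(dead, med, new_est)
        weights = w
        if np.max(np.abs(new_est - est)) < tol * scale0:
            est = new_est
            break
        est = new_est
    return est, weights


def evoked_pair(ep: EpochSet, **kwargs) -> EvokedPair:
    """Robust-averaged evoked responses for the two percepts."""
    ev_g, w_g = robust_average(ep, "gallop", **kwargs)
    ev_s, w_s = robust_average(ep, "segregated", **kwargs)
    return EvokedPair(
        evoked_gallop=ev_g,
        evoked_segregated=ev_s,
        weights={"gallop": w_g, "segregated": w_s},
    )


def preprocess_recording(
    rec: Recording,
    spec: FilterSpec | None = None,
    n_exclude: int = 1,
    baseline_window_ms: tuple[float, float] | None = None,
) -> EpochSet:
    """Full chain: filter -> downsample -> label -> exclude -> epoch -> baseline."""
    filtered = filter_downsample(rec, spec)
    labels = label_trials(filtered)
    mask = exclude_switch_adjacent(labels, n_exclude)
    ep = epoch(filtered, filtered.stim_onsets, labels, mask)
    return baseline_correct(ep, baseline_window_ms)
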