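"""Deterministic EEG signal conditioning.

Filtering, resampling, re-referencing, cue-locked epoching, baseline
correction, band definitions, and the lateral mirroring used to fold
right-affected patients onto a common "left-affected" frame. Every
operation is pure: same input, same output, no hidden state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

from .montage import Montage

logger = logging.getLogger(__name__)

TASKS = ("fist", "elbow", "wrist")


@dataclass(frozen=True)
class Recording:
    """Continuous multi-channel EEG.

    data : (channels, samples) float array, microvolts
    fs : sampling rate in Hz
    labels : channel labels, ordered as the rows of ``data``
    events : sequence of (sample_index, task) cue markers
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    events: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        for idx, task in self.events:
            if not 0 <= idx < self.data.shape[1]:
                raise ValueError(f"event sample {idx} outside recording bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class EpochSet:
    """Cue-locked trials: (trials, channels, time), first sample at ``t0`` s."""

    data: np.ndarray
    fs: float
    t0: float
    task: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x time")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("one label per channel required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[2]) / self.fs


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, e.g. alpha = 8-13 Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)
BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


def _fir_taps(fs: float, lo: float, hi: float, pass_zero: bool) -> np.ndarray:
    # Windowed-sinc FIR; order from the Hamming transition-width heuristic
    # (3.3/Δf), with the transition band set to a quarter of the lower edge
    # but at least 1 Hz so low cut-offs stay realizable.
    trans = max(min(lo * 0.25, 2.0), 0.5 if lo < 2 else 1.0)
    numtaps = int(math.ceil(3.3 * fs / trans)) | 1  # odd length, linear phase
    numtaps = min(numtaps, int(fs * 10) | 1)
    return signal.firwin(numtaps, [lo, hi], pass_zero=pass_zero, fs=fs)


def _apply_zero_phase(rec: Recording, taps: np.ndarray) -> Recording:
    # Odd-length symmetric (linear-phase) taps applied by centred FFT
    # convolution: exact zero phase with delay compensation built in.
    out = signal.fftconvolve(rec.data, taps[None, :], mode="same")
    return replace(rec, data=out)


def bandpass_filter(rec: Recording, lo: float, hi: float) -> Recording:
    """Zero-phase FIR bandpass (default analysis band 0.1-45 Hz).

    Forward-backward application cancels the linear phase so cue-locked
    epochs are not delayed.
    """
    nyq = rec.fs / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band edges ({lo}, {hi}) must satisfy 0 < lo < hi < Nyquist ({nyq})")
    return _apply_zero_phase(rec, _fir_taps(rec.fs, lo, hi, pass_zero=False))


def notch_filter(rec: Recording, lo: float = 49.0, hi: float = 51.0) -> Recording:
    """Zero-phase FIR bandstop, default 49-51 Hz (power-line interference)."""
    nyq = rec.fs / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"stop band ({lo}, {hi}) must satisfy 0 < lo < hi < Nyquist ({nyq})")
    return _apply_zero_phase(rec, _fir_taps(rec.fs, lo, hi, pass_zero=True))


def resample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase resampling with anti-alias filtering; rescales event indices."""
    if target_fs <= 0:
        raise ValueError("target sampling rate must be positive")
    if target_fs > rec.fs:
        raise ValueError("upsampling not supported; target_fs must be <= fs")
    if target_fs == rec.fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    n_out = out.shape[1]
    scale = target_fs / rec.fs
    events = tuple(
        (min(int(round(idx * scale)), n_out - 1), task) for idx, task in rec.events
    )
    return Recording(data=out, fs=target_fs, labels=rec.labels, events=events)


def rereference_linked_ears(rec: Recording, refs: Sequence[str] = ("A1", "A2")) -> Recording:
    """Subtract the mean of the A1/A2 ear channels and drop them."""
    for r in refs:
        if r not in rec.labels:
            raise ValueError(f"reference channel {r!r} missing from recording")
    ref_idx = [rec.labels.index(r) for r in refs]
    keep = [i for i in range(rec.n_channels) if i not in ref_idx]
    ref = rec.data[ref_idx].mean(axis=0)
    out = rec.data[keep] - ref
    labels = tuple(rec.labels[i] for i in keep)
    return Recording(data=out, fs=rec.fs, labels=labels, events=rec.events)


def epoch(rec: Recording, task: str, pre_s: float = 1.0, post_s: float = 4.0) -> EpochSet:
    """Cut one [-pre_s, +post_s) epoch per cue of ``task``.

    Epochs that would run outside the recording are dropped (not padded)
    and counted in the log. The cue sample itself belongs to the action
    period, so each epoch holds exactly ``(pre_s + post_s) * fs`` samples.
    """
    n_pre = int(round(pre_s * rec.fs))
    n_post = int(round(post_s * rec.fs))
    cues = [idx for idx, t in rec.events if t == task]
    if not cues:
        logger.warning("no events of task %r; returning empty EpochSet", task)
    kept, dropped = [], 0
    for c in cues:
        if c - n_pre < 0 or c + n_post > rec.n_samples:
            dropped += 1
            continue
        kept.append(rec.data[:, c - n_pre : c + n_post])
    if dropped:
        logger.info("task %r: dropped %d out-of-bounds epochs", task, dropped)
    data = (
        np.stack(kept)
        if kept
        else np.empty((0, rec.n_channels, n_pre + n_post))
    )
    return EpochSet(data=data, fs=rec.fs, t0=-pre_s, task=task, labels=rec.labels)


def baseline_correct(ep: EpochSet) -> EpochSet:
    """Subtract each channel's mean over the pre-cue window [t0, 0) s."""
    base_mask = ep.times < 0
    if not base_mask.any():
        raise ValueError("epoch has no pre-cue baseline samples")
    base = ep.data[:, :, base_mask].mean(axis=2, keepdims=True)
    return replace(ep, data=ep.data - base)


def mirror_lateral(ep: EpochSet, montage: Montage) -> EpochSet:
    """Swap homologous left/right channels; midline channels untouched.

    Applied to right-affected patients so the whole cohort shares a
    "left-affected" laterality frame.
    """
    perm = []
    for lab in ep.labels:
        target = montage.mirror_label(lab)  # raises KeyError for unknown labels
        if target not in ep.labels:
            raise ValueError(f"homolog {target!r} of {lab!r} missing from epochs")
        perm.append(ep.labels.index(target))
    return replace(ep, data=ep.data[:, perm, :])
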