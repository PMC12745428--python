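"""Trial-averaged weighted phase lag index (wPLI) connectivity.

The wPLI between channels x and y is

    wPLI_xy = |E[Im S_xy]| / E[|Im S_xy|],

where S_xy = C_x conj(C_y) is the short-time-Fourier cross-spectrum and
the expectation pools trials (and, by default, the STFT time windows
within each trial). Because instantaneous (zero-lag) mixing of a common
source contributes only to the real part of S_xy, wPLI is insensitive to
volume conduction: it responds to consistent phase *lead or lag* only.

Spectra are computed on 0.4 s Hann windows over the post-cue action
period, zero-padded to a 1 s DFT so coefficients fall exactly on a 1 Hz
grid from 1 to 30 Hz. Band matrices average wPLI over the grid
frequencies inside each band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .preprocessing import BandDefinition, EpochSet

FREQ_GRID = np.arange(1.0, 31.0)  # 1-30 Hz in 1-Hz steps


@dataclass(frozen=True)
class SpectralTensor:
    """Complex STFT coefficients, (trials, channels, freqs, windows)."""

    coeffs: np.ndarray
    freqs: np.ndarray
    labels: tuple[str, ...]
    window_s: float

    def __post_init__(self) -> None:
        if self.coeffs.ndim != 4:
            raise ValueError("coeffs must be trials x channels x freqs x windows")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    def channel(self, label: str) -> np.ndarray:
        return self.coeffs[:, self.labels.index(label)]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric zero-diagonal matrix of band-averaged wPLI values in [0, 1]."""

    band: str
    values: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if v.shape[0] != len(self.node_labels):
            raise ValueError("one label per node required")
        if not np.allclose(v, v.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("wPLI values must lie in [0, 1]")


def stft(
    ep: EpochSet,
    window_s: float = 0.4,
    hop_s: float = 0.2,
    t_start: float = 0.0,
    t_stop: float | None = None,
    freqs: np.ndarray = FREQ_GRID,
) -> SpectralTensor:
    """Hann-tapered sliding-window DFT of the action period of each epoch.

    Only samples in [t_start, t_stop) relative to the cue enter the
    transform (default: the post-cue action period; the baseline second
    is excluded). Windows are zero-padded to ``round(fs)`` samples so the
    native DFT bins land exactly on the integer-Hz analysis grid.
    """
    n_win = int(round(window_s * ep.fs))
    hop = int(round(hop_s * ep.fs))
    if n_win < 2:
        raise ValueError("window shorter than 2 samples")
    if hop < 1:
        raise ValueError("hop must be at least one sample")
    times = ep.times
    stop = times[-1] + 1 / ep.fs if t_stop is None else t_stop
    sel = np.flatnonzero((times >= t_start) & (times < stop))
    if sel.size < n_win:
        raise ValueError("analysis segment shorter than one STFT window")
    seg = ep.data[:, :, sel]
    n_time = seg.shape[2]
    starts = np.arange(0, n_time - n_win + 1, hop)
    taper = get_window("hann", n_win, fftbins=True)
    nfft = int(round(ep.fs))
    bins = np.asarray(np.round(freqs * nfft / ep.fs), dtype=int)
    if not np.allclose(bins * ep.fs / nfft, freqs):
        raise ValueError("frequency grid not representable at this sampling rate")
    if bins[-1] > nfft // 2:
        raise ValueError("frequency grid exceeds Nyquist")
    # (trials, channels, windows, n_win) view of the tapered segments
    idx = starts[:, None] + np.arange(n_win)[None, :]
    frames = seg[:, :, idx] * taper  # trials x channels x windows x n_win
    spec = np.fft.rfft(frames, n=nfft, axis=-1)[..., bins]
    coeffs = np.moveaxis(spec, -1, 2)  # trials x channels x freqs x windows
    return SpectralTensor(coeffs=coeffs, freqs=np.asarray(freqs, float),
                          labels=ep.labels, window_s=window_s)


def cross_spectrum(s: SpectralTensor, ch_x: str, ch_y: str) -> np.ndarray:
    """S_xy = C_x conj(C_y), shape (trials, freqs, windows)."""
    return s.channel(ch_x) * np.conj(s.channel(ch_y))


def wpli(cross: np.ndarray) -> float:
    """wPLI of a set of cross-spectral observations at one frequency.

    ``cross`` holds complex cross-spectra pooled over trials and windows.
    Returns 0 when every imaginary part vanishes (declared convention:
    a purely zero-lag relationship carries no lag information).
    """
    cross = np.asarray(cross)
    if cross.size == 0:
        raise ValueError("wpli requires at least one observation")
    im = np.imag(cross).ravel()
    denom = np.abs(im).mean()
    if denom == 0:
        return 0.0
    return float(abs(im.mean()) / denom)


def _wpli_all_pairs(coeffs: np.ndarray) -> np.ndarray:
    """Vectorised wPLI for every channel pair at every frequency.

    coeffs: (trials, channels, freqs, windows) -> (channels, channels, freqs),
    pooling trials and windows in the expectation.
    """
    c = np.moveaxis(coeffs, 2, 0)  # freqs x trials x channels x windows
    # Im S_xy = Im(Cx) Re(Cy) ... use outer products per freq/trial/window
    re, im = c.real, c.imag
    # Im[Cx conj(Cy)] = im_x * re_y - re_x * im_y
    num = np.einsum("ftxw,ftyw->fxy", im, re) - np.einsum("ftxw,ftyw->fxy", re, im)
    abs_im = np.abs(
        im[:, :, :, None, :] * re[:, :, None, :, :]
        - re[:, :, :, None, :] * im[:, :, None, :, :]
    ).sum(axis=(1, 4))
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.abs(num) / abs_im
    w = np.nan_to_num(w, nan=0.0, posinf=0.0)
    return np.moveaxis(w, 0, -1)  # channels x channels x freqs


def band_frequencies(band: BandDefinition, freqs: np.ndarray = FREQ_GRID) -> np.ndarray:
    """Grid frequencies belonging to a band: half-open [lo, hi), except the
    top of the highest band (30 Hz, beta) which is included so no analysed
    frequency is orphaned."""
    mask = (freqs >= band.lo) & (freqs < band.hi)
    if band.hi == freqs[-1]:
        mask |= freqs == band.hi
    if not mask.any():
        raise ValueError(f"band {band.name} contains no grid frequencies")
    return freqs[mask]


def band_wpli(
    s: SpectralTensor,
    band: BandDefinition,
    per_window: bool = False,
) -> ConnectivityMatrix:
    """Band-averaged wPLI matrix over all channel pairs.

    ``per_window=False`` (default) pools trials and STFT windows into one
    expectation; ``per_window=True`` computes wPLI per window then averages.
    """
    fsel = np.isin(s.freqs, band_frequencies(band, s.freqs))
    coeffs = s.coeffs[:, :, fsel, :]
    if per_window:
        mats = [
            _wpli_all_pairs(coeffs[..., [w]]) for w in range(coeffs.shape[-1])
        ]
        w = np.mean(mats, axis=0)
    else:
        w = _wpli_all_pairs(coeffs)
    values = w.mean(axis=-1)  # average across band frequencies
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    values = np.clip(values, 0.0, 1.0)
    return ConnectivityMatrix(band=band.name, values=values, node_labels=s.labels)


def epochs_to_band_matrices(
    ep: EpochSet,
    bands=None,
    window_s: float = 0.4,
    hop_s: float = 0.2,
    per_window: bool = False,
) -> dict[str, ConnectivityMatrix]:
    """Convenience: STFT of the action period, then one matrix per band."""
    from .preprocessing import DEFAULT_BANDS

    bands = DEFAULT_BANDS if bands is None else bands
    s = stft(ep, window_s=window_s, hop_s=hop_s)
    return {b.name: band_wpli(s, b, per_window=per_window) for b in bands}
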