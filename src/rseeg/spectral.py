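"""Epoch-level power spectral densities and the biomarkers built on them.

The estimator is a modified periodogram: each 1-s segment is tapered with
a Kaiser window (shape 6) and transformed with a 256-point FFT, giving
1 Hz bins; segments advance by half a window (50% overlap).  The PSD of a
1-s *epoch* is the log10 of the mean of the linear PSDs of the segment
centred on it and its two half-overlapping neighbours (edge epochs average
the two available segments).

The modified-periodogram window normalisation U = sum(w^2) is applied;
every downstream measure (relative PSD, band ratios, quantile distances,
coherence) is invariant to that constant.

Bands follow the clinical convention used throughout: Delta 1-3 Hz,
Theta 3-7 Hz, Alpha 8-13 Hz (integer-Hz bins, inclusive; bin 3 belongs to
both Delta and Theta, and the 7-8 Hz gap is deliberate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import kaiser

from .montage import TEMPORAL_CHANNELS
from .session import RecordingSession

log = logging.getLogger(__name__)

#: linear powers below this (uV^2/Hz) are clamped before log10
POWER_FLOOR = 1e-12

DEFAULT_BANDS: dict[str, tuple[int, ...]] = {
    "delta": (1, 2, 3),
    "theta": (3, 4, 5, 6, 7),
    "alpha": (8, 9, 10, 11, 12, 13),
}


@dataclass
class SpectralConfig:
    fs: float = 256.0
    window_s: float = 1.0
    kaiser_beta: float = 6.0
    bin_lo: int = 1
    bin_hi: int = 40
    bands: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    alpha_peak_range: tuple[int, int] = (6, 13)
    #: "ratio_of_means" (default) or "mean_of_ratios"
    tar_mode: str = "ratio_of_means"

    @property
    def fft_n(self) -> int:
        return int(round(self.window_s * self.fs))

    @property
    def bins(self) -> np.ndarray:
        return np.arange(self.bin_lo, self.bin_hi + 1)

    def validate(self) -> None:
        if self.fft_n * 1.0 != self.window_s * self.fs:
            raise ValueError("fft_n must equal window_s x fs")
        for name, bins in self.bands.items():
            if min(bins) < self.bin_lo or max(bins) > self.bin_hi:
                raise ValueError(f"band {name} outside bin range")


@dataclass
class EpochPowerMatrix:
    """Per-epoch, per-channel, per-1-Hz-bin log10 PSD."""

    values: np.ndarray  # epochs x channels x bins, log10 uV^2/Hz
    channels: tuple[str, ...]
    config: SpectralConfig

    @property
    def linear(self) -> np.ndarray:
        return 10.0 ** self.values

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def bins(self) -> np.ndarray:
        return self.config.bins

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)


def segment_psd(x: np.ndarray, config: SpectralConfig) -> np.ndarray:
    """Modified periodograms of half-overlapping windowed segments.

    ``x``: channels x time.  Returns segments x channels x bins, linear
    scale: psd = 2|X(f)|^2 / (fs * U) with U = sum(w^2).
    """
    nwin = config.fft_n
    hop = nwin // 2
    w = kaiser(nwin, config.kaiser_beta)
    U = float(np.sum(w**2))
    segs = sliding_window_view(x, nwin, axis=-1)[..., ::hop, :]  # ch,seg,nwin
    X = np.fft.rfft(segs * w, axis=-1)
    psd = 2.0 * np.abs(X) ** 2 / (config.fs * U)
    psd = psd[..., config.bin_lo:config.bin_hi + 1]
    return np.moveaxis(psd, -2, 0)  # seg, ch, bins


def epoch_psd(
    session: RecordingSession, config: SpectralConfig | None = None
) -> EpochPowerMatrix:
    """Epoch-level log10 PSD matrix for a (filtered) session.

    Epoch k averages the linear PSDs of segments 2k-1, 2k, 2k+1 (the
    segment aligned with the epoch plus its two half-overlapping
    neighbours); the first and last epochs average the two segments that
    exist.
    """
    if config is None:
        config = SpectralConfig(fs=session.fs)
    config.validate()
    if session.duration_s < 3 * config.window_s:
        raise ValueError("session must be at least 3 windows long")
    psd = segment_psd(session.samples, config)  # seg, ch, bins
    n_seg = psd.shape[0]
    n_epochs = session.n_samples // config.fft_n
    out = np.empty((n_epochs, psd.shape[1], psd.shape[2]))
    for k in range(n_epochs):
        ids = [j for j in (2 * k - 1, 2 * k, 2 * k + 1) if 0 <= j < n_seg]
        out[k] = psd[ids].mean(axis=0)
    np.clip(out, POWER_FLOOR, None, out=out)
    if (out <= POWER_FLOOR).any():
        log.warning("power floor applied to degenerate epochs")
    return EpochPowerMatrix(
        values=np.log10(out), channels=tuple(session.montage.labels), config=config
    )


def band_power(epm: EpochPowerMatrix, band: str) -> np.ndarray:
    """Epochs x channels log10 band power (mean of linear bin powers)."""
    try:
        bins = epm.config.bands[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}") from None
    cols = [int(b) - epm.config.bin_lo for b in bins]
    return np.log10(epm.linear[..., cols].mean(axis=-1))


def relative_psd(epm: EpochPowerMatrix) -> np.ndarray:
    """Per epoch/channel, bin power over the summed 1-40 Hz power.

    Rows sum to one; scale-invariant.  Zero-total epochs yield NaN and a
    warning.
    """
    lin = epm.linear
    tot = lin.sum(axis=-1, keepdims=True)
    zero = tot <= epm.values.shape[-1] * POWER_FLOOR * (1 + 1e-9)
    if zero.any():
        log.warning("%d epoch/channel cells with no power", int(zero.sum()))
        tot = np.where(zero, np.nan, tot)
    return lin / tot


def global_psd(epm: EpochPowerMatrix) -> np.ndarray:
    """Epochs x bins: linear powers averaged across channels, then log10."""
    return np.log10(epm.linear.mean(axis=1))


def session_average_psd(epm: EpochPowerMatrix) -> np.ndarray:
    """Channels x bins mean of the stored (log-scale) epoch PSDs."""
    return epm.values.mean(axis=0)


def session_average_relative_psd(epm: EpochPowerMatrix) -> np.ndarray:
    """Channels x bins mean across epochs of the relative PSD."""
    return relative_psd(epm).mean(axis=0)


def alpha_peak_frequency(
    avg_psd: np.ndarray, config: SpectralConfig | None = None
) -> np.ndarray:
    """Per-channel alpha peak: the largest local maximum in 6-13 Hz.

    ``avg_psd`` is channels x bins (session-average).  A bin is a local
    peak if strictly greater than both integer-Hz neighbours; with several
    peaks the one with the largest power wins; with none the channel gets
    NaN.  Resolution is 1 Hz.
    """
    if config is None:
        config = SpectralConfig()
    lo, hi = config.alpha_peak_range
    avg_psd = np.atleast_2d(avg_psd)
    out = np.full(avg_psd.shape[0], np.nan)
    for c in range(avg_psd.shape[0]):
        best_p = -np.inf
        for f in range(lo, hi + 1):
            i = f - config.bin_lo
            if i - 1 < 0 or i + 1 >= avg_psd.shape[1]:
                continue
            v = avg_psd[c, i]
            if v > avg_psd[c, i - 1] and v > avg_psd[c, i + 1] and v > best_p:
                best_p, out[c] = v, float(f)
        if np.isnan(out[c]):
            log.info("no alpha peak found on channel index %d", c)
    return out


def theta_alpha_ratio(
    epm: EpochPowerMatrix, theta: str = "theta", alpha: str = "alpha"
):
    """Per-channel TAR and its mean over the temporal sites T3, T4, T5, T6.

    Default is the ratio of epoch-mean linear band powers; set
    ``config.tar_mode = "mean_of_ratios"`` for the per-epoch-ratio variant.
    Returns ``(tar_per_channel, temporal_tar)``; the temporal value is NaN
    when no temporal channel is present.
    """
    th = 10.0 ** band_power(epm, theta)
    al = 10.0 ** band_power(epm, alpha)
    if epm.config.tar_mode == "mean_of_ratios":
        tar = (th / al).mean(axis=0)
    elif epm.config.tar_mode == "ratio_of_means":
        denom = al.mean(axis=0)
        if (denom <= 0).any():
            raise ValueError("zero alpha power; TAR undefined")
        tar = th.mean(axis=0) / denom
    else:
        raise ValueError(f"unknown tar_mode {epm.config.tar_mode!r}")
    idx = [epm.channels.index(c) for c in TEMPORAL_CHANNELS if c in epm.channels]
    temporal = float(tar[idx].mean()) if idx else float("nan")
    return tar, temporal
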