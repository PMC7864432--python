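"""Magnitude-squared coherence between channel pairs, and its normalisation.

The recording is cut into 20-s epochs with 50% overlap; within each epoch
coherence is estimated with Welch's method (2-s Kaiser windows, shape 6,
50% overlap) and the per-epoch estimates are averaged arithmetically.
The native 0.5 Hz resolution is collapsed onto the integer 1-40 Hz axis
shared with the spectral stage by averaging each pair of adjacent native
bins ((f - 0.5, f) -> bin f).

Normalised coherence subtracts, per pair, the mean over bins 1-40, so a
pair's values say "more/less coherent than that pair's own average".
Pairs are classed short/long range by 2D electrode distance and
inter/intra-hemispheric by the 10-20 label parity (midline counts as
intra for either side).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import kaiser

from .montage import MontageSpec, hemisphere_of
from .preprocess import segment_epochs
from .session import RecordingSession


@dataclass
class CoherenceConfig:
    epoch_s: float = 20.0
    epoch_overlap: float = 0.5
    window_s: float = 2.0
    kaiser_beta: float = 6.0
    bin_lo: int = 1
    bin_hi: int = 40
    long_range_fraction: float = 0.4


@dataclass
class CoherenceMatrix:
    pairs: tuple[tuple[str, str], ...]
    bins: np.ndarray
    msc: np.ndarray                      # pairs x bins, in [0, 1]
    normalized: np.ndarray | None = None
    pair_class: pd.DataFrame | None = None

    def pair_index(self, a: str, b: str) -> int:
        return self.pairs.index((a, b) if (a, b) in self.pairs else (b, a))


def pairwise_coherence(
    session: RecordingSession, config: CoherenceConfig | None = None
) -> CoherenceMatrix:
    """Welch magnitude-squared coherence for every unordered channel pair."""
    if config is None:
        config = CoherenceConfig()
    if session.duration_s < 2 * config.epoch_s:
        raise ValueError("session must cover at least two coherence epochs")
    fs = session.fs
    nwin = int(round(config.window_s * fs))
    hop = nwin // 2
    w = kaiser(nwin, config.kaiser_beta)
    epochs = segment_epochs(
        session.n_samples, fs, config.epoch_s, config.epoch_overlap
    )
    x = session.samples
    n_ch = x.shape[0]
    freqs = np.fft.rfftfreq(nwin, 1.0 / fs)

    msc_sum = None
    for start, stop in epochs:
        seg = sliding_window_view(x[:, start:stop], nwin, axis=-1)[..., ::hop, :]
        F = np.fft.rfft(seg * w, axis=-1)          # ch, nseg, freq
        Sxy = np.einsum("asf,bsf->abf", F, F.conj()) / F.shape[1]
        auto = np.real(np.einsum("aaf->af", Sxy))
        denom = auto[:, None, :] * auto[None, :, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            msc = np.abs(Sxy) ** 2 / denom
        msc = np.nan_to_num(msc, nan=0.0)
        msc_sum = msc if msc_sum is None else msc_sum + msc
    msc_epoch_mean = msc_sum / len(epochs)          # ch x ch x freq

    # collapse native 0.5 Hz bins onto the integer axis: bin f = mean of
    # native bins f-0.5 and f
    native = {round(float(f) * 2): i for i, f in enumerate(freqs)}
    bins = np.arange(config.bin_lo, config.bin_hi + 1)
    cols_lo = [native[2 * f - 1] for f in bins]
    cols_hi = [native[2 * f] for f in bins]
    collapsed = 0.5 * (
        msc_epoch_mean[..., cols_lo] + msc_epoch_mean[..., cols_hi]
    )

    labels = session.montage.labels
    pairs = tuple(combinations(labels, 2))
    rows = np.array([[labels.index(a), labels.index(b)] for a, b in pairs])
    msc_pairs = collapsed[rows[:, 0], rows[:, 1], :]
    return CoherenceMatrix(
        pairs=pairs,
        bins=bins,
        msc=np.clip(msc_pairs, 0.0, 1.0),
        pair_class=classify_pairs(session.montage, config.long_range_fraction),
    )


def normalize_coherence(cm: CoherenceMatrix) -> CoherenceMatrix:
    """Subtract each pair's 1-40 Hz mean; per-pair zero mean by construction."""
    return replace(cm, normalized=cm.msc - cm.msc.mean(axis=1, keepdims=True))


def band_coherence(cm: CoherenceMatrix, band_bins) -> np.ndarray:
    """Per-pair mean of (normalised, if present) coherence over band bins."""
    values = cm.normalized if cm.normalized is not None else cm.msc
    cols = [int(b) - int(cm.bins[0]) for b in band_bins]
    return values[:, cols].mean(axis=1)


def classify_pairs(
    montage: MontageSpec, long_range_fraction: float = 0.4
) -> pd.DataFrame:
    """Range and hemisphere class for every unordered channel pair.

    Long range: 2D distance above ``long_range_fraction`` x the maximum
    inter-electrode distance.  Inter-hemispheric: members on opposite
    lateral sides; any pair touching the midline is intra-hemispheric.
    """
    dmax = montage.max_distance()
    rows = []
    for a, b in combinations(montage.labels, 2):
        d = montage.distance(a, b)
        ha, hb = hemisphere_of(a), hemisphere_of(b)
        inter = {ha, hb} == {"left", "right"}
        rows.append(
            {
                "a": a,
                "b": b,
                "distance": d,
                "range_class": "long" if d > long_range_fraction * dmax else "short",
                "hemi_class": "inter_hemispheric" if inter else "intra_hemispheric",
            }
        )
    return pd.DataFrame(rows)
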