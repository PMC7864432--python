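"""Channel screening, band-pass filtering and epoch segmentation.

The filter is a zero-phase Hamming-windowed sinc FIR band-pass (default
1-49 Hz) applied with a centred, symmetric kernel, so no group delay is
introduced.  Channel screening flags electrodes with a flat-line run
longer than 5 s or whole-session correlation below 0.4 with the signal
predicted from neighbouring electrodes; flagged channels are excluded from
downstream statistics rather than interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import signal

from .session import RecordingSession

log = logging.getLogger(__name__)

#: samples equal within this tolerance (uV) count as flat; survives the
#: quantisation round-trip through 16-bit EDF
FLAT_TOL = 1e-8


def design_bandpass(low_hz: float, high_hz: float, fs: float,
                    transition_hz: float = 1.0) -> np.ndarray:
    """Hamming-windowed sinc band-pass kernel.

    Kernel length follows the standard Hamming transition-width rule
    (3.3 / normalized transition width), forced odd for exact symmetry.
    """
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError("band must satisfy 0 < low < high < fs/2")
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    numtaps += 1 - numtaps % 2
    return signal.firwin(
        numtaps, [low_hz, high_hz], pass_zero=False, window="hamming", fs=fs
    )


def bandpass_filter(
    session: RecordingSession, low_hz: float = 1.0, high_hz: float = 49.0
) -> RecordingSession:
    """Zero-phase FIR band-pass per channel; output length = input length."""
    kernel = design_bandpass(low_hz, high_hz, session.fs)
    half = len(kernel) // 2
    padded = np.pad(session.samples, ((0, 0), (half, half)), mode="reflect")
    out = signal.fftconvolve(padded, kernel[None, :], mode="valid", axes=1)
    return replace(session, samples=out)


def _longest_flat_run(x: np.ndarray, tol: float = FLAT_TOL) -> int:
    """Longest run of consecutive samples equal within ``tol`` (in samples)."""
    flat = np.abs(np.diff(x)) <= tol
    if not flat.any():
        return 1
    # run lengths of True in `flat`; a run of r Trues = r+1 equal samples
    edges = np.diff(np.concatenate(([0], flat.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return int((stops - starts).max()) + 1


def detect_bad_channels(
    session: RecordingSession,
    flatline_s: float = 5.0,
    corr_threshold: float = 0.4,
    k_neighbors: int = 4,
) -> list[str]:
    """Channels failing the flat-line or the neighbour-correlation rule.

    Rule (a): any run of (near-)identical samples longer than ``flatline_s``.
    Rule (b): Pearson correlation with the inverse-distance-weighted average
    of the ``k_neighbors`` nearest channels below ``corr_threshold`` over the
    whole session.  With fewer than ``k_neighbors + 1`` channels rule (b) is
    skipped with a warning.
    """
    if session.duration_s < flatline_s:
        raise ValueError("session shorter than the flat-line criterion")
    labels = session.montage.labels
    bad: list[str] = []
    max_run = int(flatline_s * session.fs)
    for i, lab in enumerate(labels):
        if _longest_flat_run(session.samples[i]) > max_run:
            bad.append(lab)

    if len(labels) < k_neighbors + 1:
        log.warning(
            "only %d channels; neighbour-correlation rule skipped", len(labels)
        )
        return bad

    xy = np.array([session.montage.xy[l] for l in labels])
    x = session.samples - session.samples.mean(axis=1, keepdims=True)
    for i, lab in enumerate(labels):
        d = np.linalg.norm(xy - xy[i], axis=1)
        d[i] = np.inf
        nbr = np.argsort(d)[:k_neighbors]
        w = 1.0 / d[nbr]
        pred = w @ x[nbr]
        denom = np.linalg.norm(x[i]) * np.linalg.norm(pred)
        r = float(x[i] @ pred / denom) if denom > 0 else 0.0
        if r < corr_threshold and lab not in bad:
            bad.append(lab)
    return bad


def segment_epochs(
    n_samples: int, fs: float, epoch_s: float, overlap_fraction: float = 0.0
) -> np.ndarray:
    """Start/stop sample indices of epochs; trailing partial epoch dropped.

    Accepts either a sample count or a :class:`RecordingSession` as the
    first argument.
    """
    if isinstance(n_samples, RecordingSession):
        fs, n_samples = n_samples.fs, n_samples.n_samples
    epoch_n = epoch_s * fs
    if abs(epoch_n - round(epoch_n)) > 1e-9:
        raise ValueError("epoch_s x fs must be an integer sample count")
    epoch_n = int(round(epoch_n))
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if epoch_n > n_samples:
        raise ValueError("epoch longer than session")
    hop = int(round(epoch_n * (1.0 - overlap_fraction)))
    starts = np.arange(0, n_samples - epoch_n + 1, hop)
    return np.column_stack([starts, starts + epoch_n])
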