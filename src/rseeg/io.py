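"""Session file formats: 16-bit EDF and plain delimited matrices.

EDF files are written with a minimal built-in writer (one 1-second data
record per signal per second, physical units microvolts) and read through
MNE's EDF reader.  Delimited sessions are a text alternative: a ``# fs=``
comment line followed by a CSV with one column per channel label.
Channel-name matching is case-insensitive and accepts the modern aliases
(T7/T3, T8/T4, P7/T5, P8/T6).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import MontageSpec, canonical_label, standard_1020
from .session import RecordingSession

log = logging.getLogger(__name__)


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _phys_bound(v: float) -> float:
    """Round a physical bound to a value exactly representable in 8 chars."""
    for fmt in (".6g", ".5g", ".4g", ".3g", ".2g"):
        s = format(float(v), fmt)
        if len(s) <= 8:
            return float(s)
    return float(format(float(v), ".1g"))


def write_session_edf(session: RecordingSession, path) -> Path:
    """Write the session as 16-bit EDF (physical units uV).

    The trailing partial second, if any, is dropped; quantisation error is
    at most one least-significant bit of the 16-bit range.
    """
    path = Path(path)
    fs = session.fs
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = session.n_samples // spr
    ns = session.n_channels
    x = session.samples[:, : n_rec * spr]

    pmin = np.array([_phys_bound(row.min() - 1e-6) for row in x])
    pmax = np.array([_phys_bound(row.max() + 1e-6) for row in x])
    pmax = np.where(pmax <= pmin, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((x - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    hdr = b"".join(
        [
            _ascii("0", 8),
            _ascii(session.subject_id, 80),
            _ascii(f"group {session.group_label}", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (ns + 1), 8),
            _ascii("", 44),
            _ascii(n_rec, 8),
            _ascii("1", 8),
            _ascii(ns, 4),
        ]
    )
    labels = session.montage.labels
    sig = b"".join(
        [
            b"".join(_ascii(f"EEG {l}", 16) for l in labels),
            b"".join(_ascii("AgAgCl electrode", 80) for _ in labels),
            b"".join(_ascii("uV", 8) for _ in labels),
            b"".join(_ascii(format(v, ".6g"), 8) for v in pmin),
            b"".join(_ascii(format(v, ".6g"), 8) for v in pmax),
            b"".join(_ascii(dmin, 8) for _ in labels),
            b"".join(_ascii(dmax, 8) for _ in labels),
            b"".join(_ascii("BP 1-49Hz", 80) for _ in labels),
            b"".join(_ascii(spr, 8) for _ in labels),
            b"".join(_ascii("", 32) for _ in labels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())
    return path


def _match_channels(found: list[str], montage: MontageSpec):
    """Map montage labels to indices in ``found``; warn on extras."""
    canon = {canonical_label(f): i for i, f in enumerate(found)}
    missing = [l for l in montage.labels if l not in canon]
    if missing:
        raise ValueError(f"missing required channels: {missing}")
    extras = [f for f in found if canonical_label(f) not in montage.labels]
    if extras:
        log.warning("ignoring extra channels: %s", extras)
    return [canon[l] for l in montage.labels]


def read_session_edf(
    path, montage: MontageSpec | None = None, **session_kwargs
) -> RecordingSession:
    """Read an EDF file into a session, reordered to montage order (uV)."""
    import mne

    if montage is None:
        montage = standard_1020()
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    found = [ch.removeprefix("EEG ").strip() for ch in raw.ch_names]
    order = _match_channels(found, montage)
    data_uv = raw.get_data() * 1e6  # MNE loads EEG in volts
    return RecordingSession(
        samples=data_uv[order],
        fs=float(raw.info["sfreq"]),
        montage=montage,
        **session_kwargs,
    )


def write_session_csv(session: RecordingSession, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(session.samples.T, columns=list(session.montage.labels))
    with open(path, "w") as fh:
        fh.write(f"# fs={session.fs:g}\n")
        df.to_csv(fh, index=False)
    return path


def read_session_csv(
    path, montage: MontageSpec | None = None, fs: float | None = None,
    **session_kwargs,
) -> RecordingSession:
    """Read a delimited matrix (header = channel labels) into a session."""
    if montage is None:
        montage = standard_1020()
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "fs=" in first:
            fs = float(first.split("fs=")[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, comment="#")
    if fs is None:
        raise ValueError("sampling rate missing from file and not provided")
    order = _match_channels(list(df.columns), montage)
    return RecordingSession(
        samples=df.to_numpy(dtype=float).T[order], fs=fs, montage=montage,
        **session_kwargs,
    )


def read_session(path, montage: MontageSpec | None = None,
                 fs: float | None = None, **session_kwargs) -> RecordingSession:
    """Dispatch on extension: .edf or delimited text."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_session_edf(path, montage, **session_kwargs)
    return read_session_csv(path, montage, fs=fs, **session_kwargs)
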