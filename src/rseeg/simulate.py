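"""Synthetic resting-state EEG cohorts with controllable spectral structure.

Each simulated channel is the sum of four components, all synthesised in
the frequency domain (amplitude shaping + random phases, inverse rFFT):

* a 1/f^beta *background*, mixed from a small set of shared cortical
  sources plus a private source.  The shared/private balance is set by
  ``spatial_mixing`` and the per-source channel gains decay with scalp
  distance, which gives non-degenerate, distance-decaying inter-channel
  coherence;
* a shared narrow-band *alpha* oscillation centred on ``alpha_peak_hz``,
  weighted toward posterior channels through the montage's
  ``alpha_weight`` (the posterior dominant rhythm);
* white measurement noise of ``channel_noise_sd`` microvolts.

After background and alpha are summed, each channel's 3-7 Hz content is
split off with an FFT band mask and rescaled: its linear power is
multiplied by ``theta_sustained_gain`` on every epoch, and additionally by
``theta_burst_gain`` on 1-s epochs drawn Bernoulli(theta_burst_prob),
restricted to ``burst_channel_mask``.  Sustained elevation emulates the
established diffuse slowing of dementia; sparse conspicuous bursts emulate
abnormality present in only a small fraction of the recording, the regime
the tail-sensitive distribution statistic is designed for.

Burst epochs are aligned to the 1-s grid used by the spectral stage, so
"epoch-sparse abnormality" is exactly controllable.  Everything is a pure
function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import MontageSpec, standard_1020
from .session import RecordingSession

#: scalp anchor points of the shared background sources (unit-disc coords)
_SOURCE_XY = np.array(
    [(-0.5, 0.6), (0.5, 0.6), (-0.6, -0.1), (0.6, -0.1), (-0.4, -0.7), (0.4, -0.7)]
)
_SOURCE_DECAY = 0.8  # spatial gain length scale, head radii


@dataclass
class GroupSpectralProfile:
    """Spectral recipe for one participant group."""

    group_label: str = "custom"
    background_exponent: float = 1.0
    alpha_peak_hz: float = 10.0
    alpha_amplitude: float = 6.0  # uV RMS at a unit alpha-weight channel
    theta_sustained_gain: float = 1.0
    theta_burst_prob: float = 0.0
    theta_burst_gain: float = 1.0
    burst_channel_mask: tuple[str, ...] | None = None  # None = all channels
    channel_noise_sd: float = 1.0
    spatial_mixing: float = 0.5
    background_rms: float = 7.0  # uV RMS of the 1/f background per channel
    #: between-subject coefficient of variation of the component amplitudes
    #: (alpha, theta, background draw independent lognormal multipliers per
    #: subject); resting EEG amplitudes vary this much across individuals
    subject_cv: float = 0.25
    age_range: tuple[int, int] = (60, 90)

    def validate(self) -> None:
        if not 0.0 <= self.theta_burst_prob <= 1.0:
            raise ValueError("theta_burst_prob must be in [0, 1]")
        if not 0.0 <= self.spatial_mixing <= 1.0:
            raise ValueError("spatial_mixing must be in [0, 1]")
        if self.theta_sustained_gain <= 0 or self.theta_burst_gain <= 0:
            raise ValueError("theta gains must be positive")
        if not 6.0 <= self.alpha_peak_hz <= 13.0:
            raise ValueError("alpha_peak_hz must lie in the 6-13 Hz search range")
        if self.alpha_amplitude < 0 or self.channel_noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")


def healthy_profile(group_label: str = "HC3", alpha_peak_hz: float = 9.0) -> GroupSpectralProfile:
    """Age-matched control recipe: clean alpha, no theta elevation."""
    return GroupSpectralProfile(group_label=group_label, alpha_peak_hz=alpha_peak_hz)


def mci_like_profile(
    group_label: str = "MCI",
    theta_burst_prob: float = 0.08,
    theta_burst_gain: float = 4.0,
    burst_channel_mask: tuple[str, ...] = ("T3", "T4", "T5", "T6"),
) -> GroupSpectralProfile:
    """Sparse temporal theta bursts, alpha preserved.

    Defaults encode abnormality in roughly 1 epoch in 12, confined to
    temporal sites, with a four-fold linear-power elevation while it lasts.
    """
    return GroupSpectralProfile(
        group_label=group_label,
        alpha_peak_hz=9.0,
        theta_burst_prob=theta_burst_prob,
        theta_burst_gain=theta_burst_gain,
        burst_channel_mask=burst_channel_mask,
    )


def ad_like_profile(
    group_label: str = "AD",
    theta_sustained_gain: float = 1.5,
    alpha_amplitude: float = 5.0,
    alpha_peak_hz: float = 8.0,
) -> GroupSpectralProfile:
    """Sustained diffuse theta elevation with reduced, slowed alpha."""
    return GroupSpectralProfile(
        group_label=group_label,
        alpha_peak_hz=alpha_peak_hz,
        alpha_amplitude=alpha_amplitude,
        theta_sustained_gain=theta_sustained_gain,
    )


@dataclass
class CohortConfig:
    """Fully deterministic description of a simulated cohort."""

    profiles: list[GroupSpectralProfile]
    n_subjects_per_group: int = 10
    duration_s: float = 300.0
    fs: float = 256.0
    montage: MontageSpec = field(default_factory=standard_1020)
    seed: int = 0

    def validate(self) -> None:
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s x fs must be an integer sample count")
        for p in self.profiles:
            p.validate()


def _shaped_noise(rng, amp: np.ndarray, n: int, shape=()) -> np.ndarray:
    """Unit-RMS time series with spectral amplitude profile ``amp``.

    ``amp`` is defined on the rFFT frequency grid of an n-sample signal.
    Random phases; leading-dim broadcastable ``shape``.
    """
    nf = len(amp)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=shape + (nf,))
    spec = amp * np.exp(1j * phases)
    spec[..., 0] = 0.0  # no DC
    x = np.fft.irfft(spec, n=n, axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _background_amp(freqs: np.ndarray, exponent: float) -> np.ndarray:
    """Amplitude profile whose PSD falls off as f^-exponent above 1 Hz."""
    amp = np.zeros_like(freqs)
    above = freqs >= 1.0
    amp[above] = freqs[above] ** (-exponent / 2.0)
    # flat plateau below 1 Hz (removed anyway by the 1 Hz high-pass)
    amp[~above & (freqs > 0)] = 1.0
    return amp


def _bump_amp(freqs: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((freqs - center) / sigma) ** 2)


def _band_amp(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    return ((freqs >= low) & (freqs <= high)).astype(float)


def generate_subject(
    profile: GroupSpectralProfile,
    montage: MontageSpec | None = None,
    duration_s: float = 300.0,
    fs: float = 256.0,
    seed: int = 0,
    subject_id: str = "S000",
) -> RecordingSession:
    """Simulate one eyes-closed resting-state session.

    Returns a :class:`RecordingSession` of ``duration_s * fs`` samples per
    channel.  The same ``(profile, seed)`` yields bit-identical output.
    """
    profile.validate()
    if montage is None:
        montage = standard_1020()
    if duration_s < 30:
        raise ValueError("duration_s must be at least 30 s")
    mask = profile.burst_channel_mask
    if mask is not None:
        unknown = [c for c in mask if c not in montage.labels]
        if unknown:
            raise ValueError(f"burst_channel_mask has unknown channels: {unknown}")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    n_ch = len(montage.labels)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    # subject-level amplitude multipliers (unit mean, CV = subject_cv)
    if profile.subject_cv > 0:
        sig = np.sqrt(np.log1p(profile.subject_cv**2))
        m_bg, m_alpha, m_theta = np.exp(
            rng.normal(-0.5 * sig**2, sig, size=3)
        )
    else:
        m_bg = m_alpha = m_theta = 1.0

    # -- shared-source 1/f background ------------------------------------
    bg_amp = _background_amp(freqs, profile.background_exponent)
    sources = _shaped_noise(rng, bg_amp, n, shape=(len(_SOURCE_XY),))
    xy = np.array([montage.xy[l] for l in montage.labels])
    dists = np.linalg.norm(xy[:, None, :] - _SOURCE_XY[None, :, :], axis=-1)
    gains = np.exp(-dists / _SOURCE_DECAY)
    gains /= np.sqrt((gains**2).sum(axis=1, keepdims=True))  # unit total power
    shared = gains @ sources
    private = _shaped_noise(rng, bg_amp, n, shape=(n_ch,))
    m = profile.spatial_mixing
    background = m_bg * profile.background_rms * (
        np.sqrt(m) * shared + np.sqrt(1 - m) * private
    )

    # -- posterior-dominant alpha (one shared oscillator) -----------------
    alpha_src = _shaped_noise(rng, _bump_amp(freqs, profile.alpha_peak_hz, 0.5), n)
    w_alpha = np.array([montage.alpha_weight.get(l, 0.0) for l in montage.labels])
    alpha = m_alpha * profile.alpha_amplitude * w_alpha[:, None] * alpha_src[None, :]

    # -- theta gains: split off the 3-7 Hz content and rescale it ---------
    # The gains act multiplicatively on each channel's *total* theta-band
    # linear power: sustained everywhere, burst gain additionally on
    # Bernoulli-drawn 1-s epochs of the masked channels (time-domain
    # envelope on the band-passed component, so bursts stay epoch-aligned).
    base = background + alpha
    band_mask = _band_amp(freqs, 3.0, 7.0)
    theta_part = np.fft.irfft(np.fft.rfft(base, axis=-1) * band_mask, n=n, axis=-1)
    rest = base - theta_part

    n_epochs = n // int(round(fs))
    burst_epochs = rng.random(n_epochs) < profile.theta_burst_prob
    env = np.full(
        (n_ch, 1), np.sqrt(m_theta * profile.theta_sustained_gain)
    ) * np.ones((1, n))
    if burst_epochs.any() and profile.theta_burst_gain != 1.0:
        spf = int(round(fs))
        rows = (
            [montage.index(c) for c in mask] if mask is not None else range(n_ch)
        )
        for k in np.flatnonzero(burst_epochs):
            for r in rows:
                env[r, k * spf:(k + 1) * spf] *= np.sqrt(profile.theta_burst_gain)

    noise = profile.channel_noise_sd * rng.standard_normal((n_ch, n))

    samples = rest + env * theta_part + noise
    return RecordingSession(
        samples=samples,
        fs=fs,
        montage=montage,
        subject_id=subject_id,
        group_label=profile.group_label,
        metadata={
            "seed": seed,
            "burst_epochs": np.flatnonzero(burst_epochs).tolist(),
        },
    )


def _subject_seed(cohort_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=cohort_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(config: CohortConfig):
    """Simulate ``n_subjects_per_group`` sessions per profile.

    Returns ``(sessions, metadata)`` where ``metadata`` is a DataFrame with
    subject_id, group, age and the per-subject seed.  Per-subject seeds are
    derived deterministically from ``config.seed``.
    """
    config.validate()
    sessions: list[RecordingSession] = []
    rows = []
    idx = 0
    for profile in config.profiles:
        for _ in range(config.n_subjects_per_group):
            seed = _subject_seed(config.seed, idx)
            sid = f"S{idx:03d}"
            sess = generate_subject(
                profile,
                montage=config.montage,
                duration_s=config.duration_s,
                fs=config.fs,
                seed=seed,
                subject_id=sid,
            )
            age_rng = np.random.default_rng(seed + 1)
            lo, hi = profile.age_range
            age = int(age_rng.integers(lo, hi + 1))
            sess.metadata["age"] = age
            sessions.append(sess)
            rows.append(
                {
                    "subject_id": sid,
                    "group": profile.group_label,
                    "age": age,
                    "seed": seed,
                }
            )
            idx += 1
    return sessions, pd.DataFrame(rows)


def inject_artifacts(
    session: RecordingSession,
    flatline_channels,
    flatline_span_s: float,
    start_s: float = 0.0,
    seed: int = 0,
) -> RecordingSession:
    """Return a copy with a constant-valued segment on the named channels.

    Emulates an electrode dropping out; used to exercise the bad-channel
    detector.  ``seed`` varies the held value slightly per channel.
    """
    out = session.copy()
    span = int(round(flatline_span_s * session.fs))
    start = int(round(start_s * session.fs))
    if start + span > session.n_samples:
        raise ValueError("flatline span exceeds session duration")
    rng = np.random.default_rng(seed)
    for label in flatline_channels:
        if label not in session.montage.labels:
            raise ValueError(f"unknown channel {label!r}")
        row = out.samples[session.montage.index(label)]
        row[start:start + span] = rng.uniform(-1.0, 1.0)
    return out
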