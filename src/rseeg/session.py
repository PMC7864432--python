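"""In-memory container for one subject's multichannel recording."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import MontageSpec


@dataclass
class RecordingSession:
    """One resting-state recording: channels x time samples in microvolts.

    ``samples`` has one row per montage label, in montage order.  ``fs`` is
    the sampling rate in Hz.  ``metadata`` may carry age and clinical scores
    (MMSE, DRS) used only for correlation analyses.
    """

    samples: np.ndarray
    fs: float
    montage: MontageSpec
    subject_id: str = "S000"
    group_label: str = "custom"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if self.samples.shape[0] != len(self.montage.labels):
            raise ValueError(
                f"{self.samples.shape[0]} rows for "
                f"{len(self.montage.labels)} montage labels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.montage.index(label)]

    def drop_channels(self, labels) -> "RecordingSession":
        """Session restricted to channels not in ``labels``."""
        keep = [l for l in self.montage.labels if l not in set(labels)]
        idx = [self.montage.index(l) for l in keep]
        return replace(
            self, samples=self.samples[idx], montage=self.montage.subset(keep)
        )

    def copy(self) -> "RecordingSession":
        return replace(self, samples=self.samples.copy())
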