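"""Electrode montage registry for the 10-20 system.

The bundled montage is a 20-channel 10-20 layout (the 19 classical sites
plus Oz) with approximate 2D head-plane coordinates on the unit disc,
hemisphere and lobe assignments, and a posterior-dominance weight used by
the simulator to shape the alpha rhythm topography.

Naming follows the older clinical convention (T3/T4/T5/T6); the modern
equivalents (T7/T8/P7/P8) are accepted as aliases when reading files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


#: modern-name aliases accepted on input (case-insensitive), both directions
CHANNEL_ALIASES = {
    "T7": "T3",
    "T8": "T4",
    "P7": "T5",
    "P8": "T6",
}

# label -> (x, y, region, alpha_weight); hemisphere follows from the label
_STANDARD_1020 = {
    "Fp1": (-0.31, 0.95, "frontal", 0.15),
    "Fp2": (0.31, 0.95, "frontal", 0.15),
    "F7": (-0.809, 0.5878, "frontal", 0.20),
    "F3": (-0.40, 0.50, "frontal", 0.20),
    "Fz": (0.00, 0.50, "frontal", 0.20),
    "F4": (0.40, 0.50, "frontal", 0.20),
    "F8": (0.809, 0.5878, "frontal", 0.20),
    "T3": (-1.00, 0.00, "temporal", 0.40),
    "C3": (-0.50, 0.00, "central", 0.40),
    "Cz": (0.00, 0.00, "central", 0.40),
    "C4": (0.50, 0.00, "central", 0.40),
    "T4": (1.00, 0.00, "temporal", 0.40),
    "T5": (-0.809, -0.5878, "temporal", 0.70),
    "P3": (-0.40, -0.50, "parietal", 0.70),
    "Pz": (0.00, -0.50, "parietal", 0.70),
    "P4": (0.40, -0.50, "parietal", 0.70),
    "T6": (0.809, -0.5878, "temporal", 0.70),
    "O1": (-0.31, -0.95, "occipital", 1.00),
    "Oz": (0.00, -1.00, "occipital", 1.00),
    "O2": (0.31, -0.95, "occipital", 1.00),
}

#: temporal sites averaged for "temporal" biomarker summaries
TEMPORAL_CHANNELS = ("T3", "T4", "T5", "T6")


def hemisphere_of(label: str) -> str:
    """Hemisphere from the 10-20 label: odd = left, even = right, z = midline."""
    tail = label.rstrip()[-1]
    if tail in ("z", "Z"):
        return "midline"
    if not tail.isdigit():
        raise ValueError(f"cannot infer hemisphere from label {label!r}")
    return "left" if int(tail) % 2 == 1 else "right"


@dataclass(frozen=True)
class MontageSpec:
    """Ordered channel layout with 2D coordinates on the unit head disc."""

    labels: tuple[str, ...]
    xy: dict[str, tuple[float, float]]
    region: dict[str, str]
    alpha_weight: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        for lab in self.labels:
            x, y = self.xy[lab]
            if math.hypot(x, y) > 1.0 + 1e-9:
                raise ValueError(f"channel {lab} lies outside the unit disc")

    @property
    def hemisphere(self) -> dict[str, str]:
        return {lab: hemisphere_of(lab) for lab in self.labels}

    def distance(self, a: str, b: str) -> float:
        (xa, ya), (xb, yb) = self.xy[a], self.xy[b]
        return math.hypot(xa - xb, ya - yb)

    def max_distance(self) -> float:
        return max(
            self.distance(a, b)
            for i, a in enumerate(self.labels)
            for b in self.labels[i + 1:]
        )

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels) -> "MontageSpec":
        labels = tuple(labels)
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise ValueError(f"unknown channels: {missing}")
        return MontageSpec(
            labels=labels,
            xy={l: self.xy[l] for l in labels},
            region={l: self.region[l] for l in labels},
            alpha_weight={l: self.alpha_weight.get(l, 0.0) for l in labels},
        )

    def regions(self) -> dict[str, tuple[str, ...]]:
        """Lateralised region groupings (e.g. ``temporal_left``).

        Midline channels belong to no lateralised region; regions with no
        member channel are omitted.
        """
        out: dict[str, list[str]] = {}
        for lab in self.labels:
            hemi = hemisphere_of(lab)
            if hemi == "midline":
                continue
            out.setdefault(f"{self.region[lab]}_{hemi}", []).append(lab)
        return {k: tuple(v) for k, v in sorted(out.items())}


def canonical_label(raw: str) -> str:
    """Map a raw channel name to the montage convention (T7 -> T3 etc.)."""
    by_lower = {l.lower(): l for l in _STANDARD_1020}
    by_lower.update({k.lower(): v for k, v in CHANNEL_ALIASES.items()})
    return by_lower.get(raw.strip().lower(), raw.strip())


def standard_1020(labels=None) -> MontageSpec:
    """The bundled 20-channel 10-20 montage (or an ordered subset of it)."""
    labels = tuple(labels) if labels is not None else tuple(_STANDARD_1020)
    unknown = [l for l in labels if l not in _STANDARD_1020]
    if unknown:
        raise ValueError(f"unknown 10-20 labels: {unknown}")
    return MontageSpec(
        labels=labels,
        xy={l: _STANDARD_1020[l][:2] for l in labels},
        region={l: _STANDARD_1020[l][2] for l in labels},
        alpha_weight={l: _STANDARD_1020[l][3] for l in labels},
    )
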