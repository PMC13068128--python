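"""Sleep-stage label schemes and the hypnogram container.

Stages follow the AASM five-class scoring convention (Wake, N1, N2, N3, REM)
on a fixed 30 s epoch grid.  A merged three-class scheme (Wake, NREM, REM)
aggregates N1/N2/N3 into NREM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

EPOCH_LEN_S = 30.0

AASM5 = ("W", "N1", "N2", "N3", "R")
MERGED3 = ("W", "NREM", "R")

#: total, surjective map from the five-class to the three-class scheme
AASM5_TO_MERGED3 = {"W": "W", "N1": "NREM", "N2": "NREM", "N3": "NREM", "R": "R"}


@dataclass(frozen=True)
class LabelScheme:
    """A named set of sleep-stage classes in canonical order."""

    name: str
    classes: tuple[str, ...]

    def index(self, label: str) -> int:
        return self.classes.index(label)


SCHEME_AASM5 = LabelScheme("aasm5", AASM5)
SCHEME_MERGED3 = LabelScheme("merged3", MERGED3)

_SCHEMES = {s.name: s for s in (SCHEME_AASM5, SCHEME_MERGED3)}


def get_scheme(name: str | LabelScheme) -> LabelScheme:
    if isinstance(name, LabelScheme):
        return name
    try:
        return _SCHEMES[name]
    except KeyError:
        raise ValueError(f"unknown label scheme {name!r}; choose from {sorted(_SCHEMES)}")


@dataclass
class Hypnogram:
    """Per-epoch sleep stage labels on a 30 s grid."""

    stages: np.ndarray  # array of label strings
    scheme: LabelScheme = field(default_factory=lambda: SCHEME_AASM5)
    epoch_len_s: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        if self.stages.ndim != 1 or len(self.stages) < 1:
            raise ValueError("hypnogram must be a non-empty 1-d label sequence")
        bad = set(self.stages) - set(self.scheme.classes)
        if bad:
            raise ValueError(f"labels {sorted(bad)} not in scheme {self.scheme.name}")
        if self.epoch_len_s != EPOCH_LEN_S:
            raise ValueError("epoch length is fixed at 30 s")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return len(self.stages) * self.epoch_len_s

    @property
    def onsets_s(self) -> np.ndarray:
        return np.arange(len(self.stages)) * self.epoch_len_s

    def stage_at(self, t_s: float) -> str:
        """Stage label covering absolute time ``t_s`` (clipped to the night)."""
        i = int(np.clip(t_s // self.epoch_len_s, 0, len(self.stages) - 1))
        return self.stages[i]

    def stage_indices(self) -> np.ndarray:
        """Integer-encoded stages in scheme class order."""
        lut = {c: i for i, c in enumerate(self.scheme.classes)}
        return np.array([lut[s] for s in self.stages], dtype=np.int64)

    def total_sleep_time_min(self) -> float:
        """Total sleep time: non-Wake epochs times 0.5 min."""
        return float(np.sum(self.stages != "W")) * self.epoch_len_s / 60.0


def map_labels(hypnogram: Hypnogram, scheme: str | LabelScheme = SCHEME_MERGED3) -> Hypnogram:
    """Relabel a five-class hypnogram into the target scheme.

    The only non-identity mapping is aasm5 -> merged3, which sends N1, N2 and
    N3 to NREM and keeps Wake and REM.
    """
    scheme = get_scheme(scheme)
    if hypnogram.scheme.name == scheme.name:
        return Hypnogram(hypnogram.stages.copy(), scheme)
    if hypnogram.scheme.name != "aasm5" or scheme.name != "merged3":
        raise ValueError(
            f"no mapping from {hypnogram.scheme.name} to {scheme.name}"
        )
    mapped = np.array([AASM5_TO_MERGED3[s] for s in hypnogram.stages], dtype=object)
    return Hypnogram(mapped, scheme)


def map_label_array(labels: Sequence[str]) -> np.ndarray:
    """Vector form of the aasm5 -> merged3 mapping for raw label arrays."""
    return np.array([AASM5_TO_MERGED3[s] for s in labels], dtype=object)
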