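"""Per-patient visual-acuity profiles and the standard distance subsets.

Visual acuity (VA) is expressed in Letters on a 0-100 scale (higher is
better); test distances are in centimetres. The nine-distance grid and the
reduced four/five/six-distance subsets are the standard measurement designs
for visual-curve assessment of presbyopia corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

from .errors import MissingDistanceError

#: The full nine-distance measurement grid (cm).
DISTANCES_9: Tuple[float, ...] = (25.0, 28.0, 33.0, 40.0, 50.0, 66.0, 100.0, 200.0, 300.0)

#: Boundary between near and distance vision (cm): near is <= 50 cm.
NEAR_SPLIT_CM: float = 50.0


@dataclass(frozen=True)
class DistanceSubset:
    """A named subset of the measurement grid used for curve fitting.

    Every subset contains both 25 and 300 cm so that all curves share the
    same integration domain. ``DCT`` denotes the conventional defocus-curve
    comparator: all nine points joined by straight lines instead of a
    fitted polynomial.
    """

    subset_id: str
    distances_cm: Tuple[float, ...]

    def __post_init__(self) -> None:
        d = self.distances_cm
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError(f"subset {self.subset_id}: distances must be strictly increasing")
        if 25.0 not in d or 300.0 not in d:
            raise ValueError(f"subset {self.subset_id}: must contain 25 and 300 cm")


SUBSETS = {
    "S4": DistanceSubset("S4", (25.0, 33.0, 66.0, 300.0)),
    "S5": DistanceSubset("S5", (25.0, 33.0, 50.0, 100.0, 300.0)),
    "S6": DistanceSubset("S6", (25.0, 28.0, 33.0, 50.0, 100.0, 300.0)),
    "S9": DistanceSubset("S9", DISTANCES_9),
    "DCT": DistanceSubset("DCT", DISTANCES_9),
}

#: Subsets fitted with a polynomial (all but the piecewise-linear comparator).
POLY_SUBSETS = ("S4", "S5", "S6", "S9")
ALL_SUBSETS = POLY_SUBSETS + ("DCT",)


@dataclass(frozen=True)
class VAProfile:
    """One patient's visual acuities (Letters) at a set of distances (cm)."""

    patient_id: str
    distances_cm: Tuple[float, ...]
    va_letters: Tuple[float, ...]

    def __post_init__(self) -> None:
        d, v = self.distances_cm, self.va_letters
        if len(d) != len(v):
            raise ValueError("distances and VA values must have equal length")
        if len(d) < 2:
            raise ValueError("a VA profile needs at least 2 points")
        if any(x <= 0 for x in d):
            raise ValueError("distances must be positive")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("distances must be strictly increasing (no duplicates)")
        if any(not (0.0 <= x <= 100.0) for x in v):
            raise ValueError("VA must lie within [0, 100] Letters")

    @classmethod
    def from_pairs(cls, patient_id: str, points: Iterable[Tuple[float, float]]) -> "VAProfile":
        pts = sorted((float(d), float(v)) for d, v in points)
        d = tuple(p[0] for p in pts)
        v = tuple(p[1] for p in pts)
        return cls(patient_id, d, v)

    @property
    def points(self) -> Tuple[Tuple[float, float], ...]:
        return tuple(zip(self.distances_cm, self.va_letters))

    def restrict(self, distances: Sequence[float]) -> "VAProfile":
        """Return the sub-profile at the given distances.

        Raises :class:`MissingDistanceError` naming the first absent distance.
        """
        have = dict(zip(self.distances_cm, self.va_letters))
        vals = []
        for d in distances:
            if d not in have:
                raise MissingDistanceError(
                    f"patient {self.patient_id}: no VA measurement at {d:g} cm"
                )
            vals.append((d, have[d]))
        return VAProfile.from_pairs(self.patient_id, vals)

    def va_at(self, distance_cm: float) -> float:
        """Measured VA at an exact grid distance."""
        have = dict(zip(self.distances_cm, self.va_letters))
        if distance_cm not in have:
            raise MissingDistanceError(
                f"patient {self.patient_id}: no VA measurement at {distance_cm:g} cm"
            )
        return have[distance_cm]

    def as_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.distances_cm, float), np.asarray(self.va_letters, float)
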