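"""Helical-symmetry initialization arithmetic for filament reconstruction.

A twisted filament appears, in projection, to rotate through 180 degrees
over one crossover distance.  With an axial rise of delta Angstrom per
rung, the per-rung twist magnitude is therefore

    |twist| = 180 * rise / crossover   (degrees per rung)

which is the value used to seed 3D reconstruction before refinement.
Amyloid filaments are left-handed by convention here, so the default
signed twist is negative; right-handed filaments get a positive sign.
Cross-beta stacking fixes the rise near 4.75 A per rung.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

__all__ = ["HelicalParams", "twist_from_crossover", "rungs_per_crossover", "RungCount"]

DEFAULT_RISE = 4.75  # Angstrom per rung, cross-beta stacking distance

_CONSISTENCY_RTOL = 1e-9


@dataclass(frozen=True)
class HelicalParams:
    """Rise (A/rung), signed twist (deg/rung; negative = left-handed) and
    crossover distance (A) — mutually constrained by |twist| = 180*rise/crossover."""

    rise: float
    twist: float
    crossover: float

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.crossover <= 0:
            raise ValueError("crossover distance must be positive")
        expected = 180.0 * self.rise / self.crossover
        if abs(abs(self.twist) - expected) > _CONSISTENCY_RTOL * max(expected, 1.0):
            raise ValueError(
                f"inconsistent parameters: |twist| {abs(self.twist)} != "
                f"180*rise/crossover = {expected}"
            )

    @classmethod
    def from_crossover(
        cls, rise: float, crossover: float, handedness: str = "left"
    ) -> "HelicalParams":
        twist = twist_from_crossover(rise, crossover, handedness)
        return cls(rise=rise, twist=twist, crossover=crossover)

    @property
    def handedness(self) -> str:
        return "left" if self.twist < 0 else "right"


def twist_from_crossover(rise: float, crossover: float, handedness: str = "left") -> float:
    """Signed per-rung twist (degrees) from an observed crossover distance.

    Raises if the crossover is shorter than the rise: a half-turn within a
    single rung is unphysical for a filament.
    """
    if rise <= 0:
        raise ValueError("rise must be positive")
    if crossover < rise:
        raise ValueError(
            f"crossover ({crossover} A) shorter than rise ({rise} A) is unphysical"
        )
    if handedness not in ("left", "right"):
        raise ValueError(f"handedness must be 'left' or 'right', got {handedness!r}")
    magnitude = 180.0 * rise / crossover
    return -magnitude if handedness == "left" else magnitude


class RungCount(NamedTuple):
    exact: float
    nearest: int


def rungs_per_crossover(params: HelicalParams) -> RungCount:
    """Number of rungs in one crossover (crossover/rise), exact and rounded."""
    exact = params.crossover / params.rise
    return RungCount(exact=exact, nearest=round(exact))
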