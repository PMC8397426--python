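"""ICC stability bands and assembly of the stable metabolome.

Bins are classed by their intraclass correlation: excellent (>= 0.75), good
(0.51-0.74), fair (0.40-0.50), poor (< 0.40). Bins with ICC >= 0.51 are
"stable" and are carried forward collectively as the stable metabolome.

The printed band edges leave [0.74, 0.75) formally unassigned; the bands are
implemented as the partition poor [0, 0.40), fair [0.40, 0.51),
good [0.51, 0.75), excellent [0.75, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = ["StabilityBand", "StableSet", "BANDS", "classify_icc", "select_stable"]


@dataclass(frozen=True)
class StabilityBand:
    label: str
    lo: float  # inclusive
    hi: float  # exclusive, except the top band which closes at 1


BANDS = (
    StabilityBand("poor", 0.0, 0.40),
    StabilityBand("fair", 0.40, 0.51),
    StabilityBand("good", 0.51, 0.75),
    StabilityBand("excellent", 0.75, 1.0),
)

STABLE_CUTOFF = 0.51


@dataclass(frozen=True)
class StableSet:
    """Bins with ICC >= cutoff, sorted by descending ICC (ties: ppm ascending)."""

    bins: tuple[str, ...]
    icc: tuple[float, ...]
    n_total: int
    cutoff: float = STABLE_CUTOFF

    @property
    def fraction_of_profile(self) -> float:
        """Percent of analyzed bins that are stable."""
        return 100.0 * len(self.bins) / self.n_total

    def __len__(self) -> int:
        return len(self.bins)


def classify_icc(icc: float) -> str:
    """Band label for one ICC value; raises outside [0, 1]."""
    if not 0.0 <= icc <= 1.0:
        raise ValueError(f"ICC must lie in [0, 1], got {icc}")
    for band in BANDS:
        if band.lo <= icc < band.hi:
            return band.label
    return BANDS[-1].label  # icc == 1.0


def select_stable(icc_map: Mapping[str, float], cutoff: float = STABLE_CUTOFF) -> StableSet:
    """Assemble the stable set from a bin -> ICC mapping."""
    if len(icc_map) == 0:
        raise ValueError("empty ICC map")
    items = [(b, v) for b, v in icc_map.items() if v >= cutoff]
    items.sort(key=lambda bv: (-bv[1], bv[0]))
    return StableSet(
        bins=tuple(b for b, _ in items),
        icc=tuple(v for _, v in items),
        n_total=len(icc_map),
        cutoff=cutoff,
    )
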