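"""Subject-level lesion and ventricle load metrics.

Lesion (WMH) and ventricle volumes are expressed as percentages of
intracranial volume (ICV), and subjects are classified into lower / higher
WMH-load classes with the quantitative thresholds 0.5% and 1% of ICV
(closed on both sides: exactly 0.5% is "lower", exactly 1% is "higher";
values in between are "intermediate" and excluded from the matched-subgroup
contrast).
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "SubjectRecord",
    "percent_of_icv",
    "classify_wmh_load",
    "mask_volume_ml",
    "LOWER_THRESHOLD_PCT",
    "HIGHER_THRESHOLD_PCT",
]

LOWER_THRESHOLD_PCT = 0.5
HIGHER_THRESHOLD_PCT = 1.0


@dataclasses.dataclass
class SubjectRecord:
    """One subject's covariates, load metrics and per-tract DTI summaries."""

    id: str
    group: str                      # "control" | "prodromal_ad"
    age: float
    sex: str                        # "M" | "F"
    cvd: bool
    mmse: float
    icv: float                      # ml
    ventricle_volume: float         # ml
    wmh_volume: float               # ml
    tract_metrics: Dict[str, Tuple[float, float]] = dataclasses.field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.icv <= 0:
            raise ValueError("icv must be positive")
        if not 0 <= self.wmh_volume < self.icv:
            raise ValueError("wmh_volume must lie in [0, icv)")

    @property
    def vv_pct(self) -> float:
        return percent_of_icv(self.ventricle_volume, self.icv)

    @property
    def wmh_pct(self) -> float:
        return percent_of_icv(self.wmh_volume, self.icv)


def percent_of_icv(volume_ml: float, icv_ml: float) -> float:
    """Volume as a percentage of intracranial volume."""
    if icv_ml <= 0:
        raise ValueError("intracranial volume must be positive")
    return 100.0 * volume_ml / icv_ml


def classify_wmh_load(wmh_pct: float) -> str:
    """'lower' (<= 0.5% ICV), 'higher' (>= 1% ICV) or 'intermediate'."""
    if wmh_pct < 0:
        raise ValueError("WMH load cannot be negative")
    if wmh_pct <= LOWER_THRESHOLD_PCT:
        return "lower"
    if wmh_pct >= HIGHER_THRESHOLD_PCT:
        return "higher"
    return "intermediate"


def mask_volume_ml(mask: np.ndarray, voxel_size_mm) -> float:
    """Volume of a binary mask in ml (voxel count x voxel volume)."""
    voxel_size_mm = np.atleast_1d(np.asarray(voxel_size_mm, dtype=float))
    if voxel_size_mm.size == 1:
        voxel_size_mm = np.repeat(voxel_size_mm, 3)
    vol_mm3 = float(np.asarray(mask).astype(bool).sum()) * float(
        np.prod(voxel_size_mm)
    )
    return vol_mm3 / 1000.0
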