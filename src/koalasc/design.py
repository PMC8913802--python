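"""Study-design statistics: harvest intensity, naive occupancy, BACIPS test.

The BACIPS (Before-After-Control-Impact Paired Series) analysis treats the
control-minus-harvested density difference of each site pair at one time as
a replicate observation and tests whether that difference changed from the
before to the after period. With the paired form, the statistic is a paired
t on the per-pair change in differences, df = pairs - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NightlyCounts

__all__ = [
    "HarvestRecord",
    "PairedDesign",
    "BacipsResult",
    "harvest_intensity",
    "harvest_table",
    "naive_occupancy",
    "bacips_test",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (report-table rule)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass(frozen=True)
class HarvestRecord:
    """One forest's harvest: net area (ha) and total timber volume (m^3)."""

    forest: str
    years: tuple[int, ...]
    area_ha: float
    volume_m3: float

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError("harvest area must be positive")
        if self.volume_m3 < 0:
            raise ValueError("harvest volume must be non-negative")


@dataclass(frozen=True)
class PairedDesign:
    """Control/treatment site pairs with densities in both periods.

    ``density`` maps (site label, period) -> males per ha, period in
    {"before", "after"}; every pair must have all four densities.
    """

    pairs: tuple[tuple[str, str], ...]  # (control, treatment)
    density: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if len(self.pairs) < 2:
            raise ValueError("BACIPS needs at least 2 site pairs")
        for control, treatment in self.pairs:
            for site in (control, treatment):
                for period in ("before", "after"):
                    if (site, period) not in self.density:
                        raise ValueError(f"missing density for ({site}, {period})")
                    if self.density[(site, period)] < 0:
                        raise ValueError("densities must be non-negative")

    def differences(self, period: str) -> np.ndarray:
        """Per-pair control-minus-treatment density difference in one period."""
        return np.array(
            [
                self.density[(c, period)] - self.density[(t, period)]
                for c, t in self.pairs
            ]
        )


@dataclass(frozen=True)
class BacipsResult:
    mean_difference: float  # mean per-pair change in (control - harvested)
    t: float
    p: float
    df: int
    method: str


def harvest_intensity(record: HarvestRecord) -> float:
    """Timber volume removed per hectare of net harvest area (m^3/ha), unrounded."""
    return record.volume_m3 / record.area_ha


def harvest_table(records: list[HarvestRecord]) -> pd.DataFrame:
    """Report table with both unrounded and printed (integer) intensities."""
    rows = []
    for r in records:
        intensity = harvest_intensity(r)
        rows.append(
            {
                "forest": r.forest,
                "years": ", ".join(str(y) for y in r.years),
                "area_ha": r.area_ha,
                "volume_m3": r.volume_m3,
                "intensity_m3_per_ha": intensity,
                "intensity_reported": round_half_up(intensity),
            }
        )
    return pd.DataFrame(rows)


def naive_occupancy(counts: NightlyCounts) -> float:
    """Percentage of working detectors with at least one detection.

    Detectors with every night masked (failed units) are excluded from the
    denominator. Uncorrected for detection probability.
    """
    working = counts.effective_nights() > 0
    if not working.any():
        raise ValueError("all detectors are masked; occupancy undefined")
    detected = counts.detector_totals() > 0
    return 100.0 * detected[working].sum() / working.sum()


def bacips_test(design: PairedDesign, method: str = "paired") -> BacipsResult:
    """Test for a harvest effect on density under the BACIPS design.

    ``paired`` (default): paired t on per-pair after-minus-before change in
    the control-minus-harvested difference, df = pairs - 1. ``two_sample``:
    Welch-free two-sample t comparing the before and after difference
    series. Identical differences in every pair give zero variance and an
    undefined statistic, reported as NaN.
    """
    d_before = design.differences("before")
    d_after = design.differences("after")
    deltas = d_after - d_before
    if method == "paired":
        df = len(deltas) - 1
        if np.allclose(deltas, deltas[0]):
            if np.allclose(deltas, 0.0):
                return BacipsResult(0.0, 0.0, 1.0, df, method)
            return BacipsResult(float(deltas.mean()), np.nan, np.nan, df, method)
        t, p = stats.ttest_1samp(deltas, 0.0)
    elif method == "two_sample":
        df = 2 * len(deltas) - 2
        if np.allclose(d_after, d_after[0]) and np.allclose(d_before, d_before[0]):
            if np.allclose(d_after.mean(), d_before.mean()):
                return BacipsResult(0.0, 0.0, 1.0, df, method)
            return BacipsResult(float(deltas.mean()), np.nan, np.nan, df, method)
        t, p = stats.ttest_ind(d_after, d_before, equal_var=True)
    else:
        raise ValueError("method must be 'paired' or 'two_sample'")
    return BacipsResult(float(deltas.mean()), float(t), float(p), int(df), method)
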