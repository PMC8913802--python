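"""Core data containers shared across the survey-simulation and model stages.

Coordinates are planar metres (x east, y north); no CRS handling is done
anywhere in the package. Counts are nightly detector counts: the number of
10-minute periods in a night with at least one validated bellow, one column
per survey night (sampling occasion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DetectorArray", "NightlyCounts"]


@dataclass(frozen=True)
class DetectorArray:
    """Locations of the J acoustic detectors of one survey array.

    Parameters
    ----------
    detector_ids : list of str
        Unique labels, one per detector.
    x, y : ndarray of float
        Planar coordinates in metres (x east, y north).
    """

    detector_ids: list[str]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if len(self.detector_ids) < 2:
            raise ValueError("a detector array needs at least 2 detectors")
        if len(set(self.detector_ids)) != len(self.detector_ids):
            raise ValueError("detector_ids must be unique")
        if not (x.shape == y.shape == (len(self.detector_ids),)):
            raise ValueError("x, y must match detector_ids in length")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("detector coordinates must be finite")

    @property
    def n_detectors(self) -> int:
        return len(self.detector_ids)

    def coords(self) -> np.ndarray:
        """(J, 2) coordinate matrix."""
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"detector_id": self.detector_ids, "x": self.x, "y": self.y}
        )


@dataclass
class NightlyCounts:
    """J x K matrix of nightly detector counts with a missingness mask.

    ``counts[j, k]`` is the count for detector j on night k; ``missing[j, k]``
    is True where the detector recorded nothing that night (sensor failure).
    Masked cells carry count 0 internally and are excluded from all
    likelihood and summary computations.
    """

    detector_ids: list[str]
    counts: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a J x K matrix")
        if counts.shape[0] != len(self.detector_ids):
            raise ValueError("counts rows must match detector_ids")
        if np.any(counts < 0):
            raise ValueError("negative counts are invalid")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        self.counts = counts.astype(np.int64)
        if self.missing is None:
            self.missing = np.zeros(counts.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != counts.shape:
                raise ValueError("missing mask must match counts shape")
        # masked cells never carry information
        self.counts = np.where(self.missing, 0, self.counts)

    @property
    def n_detectors(self) -> int:
        return self.counts.shape[0]

    @property
    def n_nights(self) -> int:
        return self.counts.shape[1]

    def detector_totals(self) -> np.ndarray:
        """Total count per detector over its unmasked nights."""
        return np.where(self.missing, 0, self.counts).sum(axis=1)

    def effective_nights(self) -> np.ndarray:
        """Number of unmasked nights per detector."""
        return (~self.missing).sum(axis=1)

    def mask_detectors(self, detector_ids: list[str]) -> "NightlyCounts":
        """Return a copy with the given detectors fully masked (failed units)."""
        unknown = set(detector_ids) - set(self.detector_ids)
        if unknown:
            raise ValueError(f"unknown detector ids: {sorted(unknown)}")
        missing = self.missing.copy()
        idx = [self.detector_ids.index(d) for d in detector_ids]
        missing[idx, :] = True
        return NightlyCounts(list(self.detector_ids), self.counts.copy(), missing)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (detector_id, night, count), masked cells omitted."""
        j, k = np.nonzero(~self.missing)
        return pd.DataFrame(
            {
                "detector_id": [self.detector_ids[i] for i in j],
                "night": k + 1,
                "count": self.counts[j, k],
            }
        )
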