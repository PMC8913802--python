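"""CSV/YAML interchange for arrays, counts, designs, draws and run configs.

Counts travel as long-format CSV (detector_id, night, count) with missing
detector-nights omitted from the table and declared in a sidecar mask CSV
(detector_id, night) — no sentinel values. Coordinates are planar metres.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .containers import DetectorArray, NightlyCounts
from .design import HarvestRecord, PairedDesign

__all__ = [
    "read_detectors", "write_detectors",
    "read_counts", "write_counts",
    "read_design", "write_design",
    "read_harvest",
    "RunConfig",
]


class ParseError(ValueError):
    """Malformed input file; message names the file and offending row."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


def write_detectors(array: DetectorArray, path) -> None:
    array.to_frame().to_csv(path, index=False)


def read_detectors(path) -> DetectorArray:
    df = pd.read_csv(path)
    _require_columns(df, ["detector_id", "x", "y"], path)
    ids = df["detector_id"].astype(str).tolist()
    dupes = df["detector_id"][df["detector_id"].duplicated()].tolist()
    if dupes:
        raise ParseError(f"{path}: duplicate detector ids {sorted(set(map(str, dupes)))}")
    try:
        return DetectorArray(ids, df["x"].to_numpy(float), df["y"].to_numpy(float))
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e


def write_counts(counts: NightlyCounts, path, mask_path=None) -> None:
    counts.to_long_frame().to_csv(path, index=False)
    if mask_path is not None:
        j, k = np.nonzero(counts.missing)
        pd.DataFrame(
            {
                "detector_id": [counts.detector_ids[i] for i in j],
                "night": k + 1,
            }
        ).to_csv(mask_path, index=False)


def read_counts(
    path,
    mask_path=None,
    array: Optional[DetectorArray] = None,
    n_nights: Optional[int] = None,
) -> NightlyCounts:
    """Read long-format counts plus an optional missingness sidecar.

    With ``array`` given, rows are aligned to its detector order and unknown
    detector ids are rejected; otherwise detector order follows first
    appearance. ``n_nights`` defaults to the largest night index seen.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["detector_id", "night", "count"], path)
    df["detector_id"] = df["detector_id"].astype(str)
    for i, _det, night, cnt in df[["detector_id", "night", "count"]].itertuples():
        if cnt < 0 or cnt != int(cnt):
            raise ParseError(f"{path}: row {i + 2}: invalid count {cnt!r}")
        if night < 1 or night != int(night):
            raise ParseError(f"{path}: row {i + 2}: invalid night {night!r}")
    mask_df = None
    if mask_path is not None:
        mask_df = pd.read_csv(mask_path)
        _require_columns(mask_df, ["detector_id", "night"], mask_path)
        mask_df["detector_id"] = mask_df["detector_id"].astype(str)
    if array is not None:
        ids = list(array.detector_ids)
        unknown = set(df["detector_id"]) - set(ids)
        if unknown:
            raise ParseError(f"{path}: unknown detector ids {sorted(unknown)}")
    else:
        ids = list(dict.fromkeys(df["detector_id"]))
        if mask_df is not None:
            for d in mask_df["detector_id"]:
                if d not in ids:
                    ids.append(d)
    nights = [int(df["night"].max())] if len(df) else [1]
    if mask_df is not None and len(mask_df):
        nights.append(int(mask_df["night"].max()))
    K = n_nights or max(nights)
    J = len(ids)
    index = {d: i for i, d in enumerate(ids)}
    counts = np.zeros((J, K), dtype=np.int64)
    seen = np.zeros((J, K), dtype=bool)
    for i, det, night, cnt in df[["detector_id", "night", "count"]].itertuples():
        j, k = index[det], int(night) - 1
        if k >= K:
            raise ParseError(f"{path}: row {i + 2}: night {night} > {K}")
        if seen[j, k]:
            raise ParseError(
                f"{path}: row {i + 2}: duplicate cell ({det}, night {night})"
            )
        seen[j, k] = True
        counts[j, k] = int(cnt)
    # cells absent from the table and not declared missing default to 0? No:
    # missingness is declared explicitly; undeclared absent cells are zeros.
    missing = np.zeros((J, K), dtype=bool)
    if mask_df is not None:
        for row in mask_df.itertuples():
            if row.detector_id not in index:
                raise ParseError(
                    f"{mask_path}: row {row.Index + 2}: unknown detector id "
                    f"{row.detector_id!r}"
                )
            k = int(row.night) - 1
            if not 0 <= k < K:
                raise ParseError(
                    f"{mask_path}: row {row.Index + 2}: night {row.night} out of range"
                )
            if seen[index[row.detector_id], k]:
                raise ParseError(
                    f"{mask_path}: row {row.Index + 2}: cell both observed and masked"
                )
            missing[index[row.detector_id], k] = True
    return NightlyCounts(ids, counts, missing)


def write_design(design: PairedDesign, path) -> None:
    rows = []
    for c, t in design.pairs:
        rows.append(
            {
                "control": c,
                "treatment": t,
                "control_before": design.density[(c, "before")],
                "control_after": design.density[(c, "after")],
                "treatment_before": design.density[(t, "before")],
                "treatment_after": design.density[(t, "after")],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_design(path) -> PairedDesign:
    df = pd.read_csv(path)
    cols = [
        "control", "treatment",
        "control_before", "control_after",
        "treatment_before", "treatment_after",
    ]
    _require_columns(df, cols, path)
    pairs = []
    density: dict[tuple[str, str], float] = {}
    for row in df.itertuples():
        c, t = str(row.control), str(row.treatment)
        pairs.append((c, t))
        density[(c, "before")] = float(row.control_before)
        density[(c, "after")] = float(row.control_after)
        density[(t, "before")] = float(row.treatment_before)
        density[(t, "after")] = float(row.treatment_after)
    try:
        return PairedDesign(tuple(pairs), density)
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e


def read_harvest(path) -> list[HarvestRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["forest", "years", "area_ha", "volume_m3"], path)
    records = []
    for row in df.itertuples():
        years = tuple(int(y) for y in str(row.years).split(";"))
        try:
            records.append(
                HarvestRecord(str(row.forest), years, float(row.area_ha),
                              float(row.volume_m3))
            )
        except ValueError as e:
            raise ParseError(f"{path}: row {row.Index + 2}: {e}") from e
    return records


@dataclass
class RunConfig:
    """One reproducible pipeline run: inputs, priors, chain settings, outputs."""

    detectors: Optional[str] = None
    counts: Optional[str] = None
    mask: Optional[str] = None
    categories: Optional[str] = None
    harvest: Optional[str] = None
    design: Optional[str] = None
    buffer_m: float = 750.0
    pixel_size_m: float = 100.0
    prior: dict = field(default_factory=lambda: {"label": "strong",
                                                 "homerange_mean": 40.0,
                                                 "cv": 0.2})
    mcmc: dict = field(default_factory=dict)
    seed: int = 1
    out_dir: str = "results"
    verbosity: int = 1

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            if str(path).endswith((".yaml", ".yml")):
                raw = yaml.safe_load(fh)
            else:
                raw = json.load(fh)
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            if str(path).endswith((".yaml", ".yml")):
                yaml.safe_dump(asdict(self), fh, sort_keys=False)
            else:
                json.dump(asdict(self), fh, indent=2)

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
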