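"""Published survey records from the NSW north-coast koala harvesting study.

Small printed tables transcribed as package constants so the design
statistics can be recomputed from their raw inputs: harvesting details for
the three selectively harvested BACIPS treatment forests and the three
previously heavily harvested forests, and per-array sensor counts with
naive-occupancy percentages before and after the 2020 harvest.

A note on totals: the study text reports 153 pre-harvest sensors while the
per-array sensor counts sum to 152; both conventions appear in print and the
discrepancy is left as-is here.
"""

from __future__ import annotations

import pandas as pd

from .design import HarvestRecord

__all__ = [
    "HARVEST_RECORDS",
    "OCCUPANCY_TABLE",
    "BACIPS_PAIRS",
    "occupancy_frame",
]

HARVEST_RECORDS: list[HarvestRecord] = [
    HarvestRecord("Cowarra", (2020,), 264, 6_177),
    HarvestRecord("Kalateenee", (2020,), 289, 4_771),
    HarvestRecord("Lower Bucca", (2020,), 304, 15_480),
    HarvestRecord("Comboyne", (2009, 2011, 2016), 296, 61_209),
    HarvestRecord("Cairncross", (2012, 2013), 466, 18_370),
    HarvestRecord("Kiwarrak", (2011,), 169, 9_093),
]

# array, sensors, role, % detectors with koalas pre-harvest (2019),
# post-harvest (2020), and 5-10 years post-harvest surveys (None = not surveyed)
OCCUPANCY_TABLE: list[tuple[str, int, str, float | None, float | None, float | None]] = [
    ("Ulidarra NP", 25, "control", 100, 96, None),
    ("Lower Bucca SF", 26, "treatment", 100, 92, None),
    ("Bago Bluff NP", 25, "control", 96, 71, None),
    ("Cowarra SF", 26, "treatment", 92, 85, None),
    ("Kumbatine NP", 25, "control", 100, 100, None),
    ("Kalateenee SF", 25, "treatment", 96, 100, None),
    ("Kiwarrak SF", 26, "older_harvest", None, None, 100),
    ("Comboyne SF", 26, "older_harvest", None, None, 100),
    ("Cairncross SF", 25, "older_harvest", None, None, 100),
]

# control / treatment pairing of the BACIPS arrays
BACIPS_PAIRS: list[tuple[str, str]] = [
    ("Ulidarra NP", "Lower Bucca SF"),
    ("Bago Bluff NP", "Cowarra SF"),
    ("Kumbatine NP", "Kalateenee SF"),
]


def occupancy_frame() -> pd.DataFrame:
    return pd.DataFrame(
        OCCUPANCY_TABLE,
        columns=[
            "array", "n_sensors", "role",
            "occupancy_pre", "occupancy_post", "occupancy_older",
        ],
    )
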