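"""Reference per-vertebra morphometry dataset.

Published microCT (39 μm) trabecular morphometry of 15 metastatic
(lytic / blastic / mixed) and 9 control human vertebral bodies, one row
per specimen: BV/TV [%], St.Th. and St.Sp. mean ± SD [μm], St.N.
[1/mm].  Bundled so group summaries, rank tests and correlations can be
reproduced from printed values without the (non-deposited) scans.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_COLUMNS = ["specimen", "group", "lesion", "bvtv_percent",
            "st_th_um", "st_th_sd_um", "st_sp_um", "st_sp_sd_um", "st_n_per_mm"]

_METASTATIC = [
    (1, "lytic", 11.3, 166, 79, 841, 339, 0.68),
    (2, "lytic", 9.6, 182, 109, 1022, 337, 0.53),
    (3, "lytic", 8.4, 161, 88, 1004, 353, 0.52),
    (4, "lytic", 11.6, 155, 70, 856, 406, 0.75),
    (5, "lytic", 7.5, 175, 101, 1279, 849, 0.43),
    (6, "lytic", 14.1, 191, 94, 1036, 706, 0.74),
    (7, "blastic", 72.6, 198, 80, 1298, 75, 3.66),
    (8, "blastic", 27.7, 398, 223, 880, 400, 0.69),
    (9, "blastic", 45.4, 250, 121, 372, 231, 1.81),
    (10, "blastic", 54.4, 306, 174, 356, 339, 1.78),
    (11, "blastic", 23.3, 189, 108, 600, 419, 1.23),
    (12, "mixed", 19.6, 251, 142, 1030, 660, 0.78),
    (13, "mixed", 52.2, 328, 163, 610, 421, 1.59),
    (14, "mixed", 16.6, 211, 107, 1029, 491, 0.79),
    (15, "mixed", 51.0, 276, 122, 360, 227, 1.85),
]

_CONTROL = [
    (16, "control", 7.4, 160, 85, 1078, 369, 0.46),
    (17, "control", 8.0, 156, 78, 1039, 366, 0.05),
    (18, "control", 8.0, 157, 66, 1182, 368, 0.51),
    (19, "control", 8.6, 159, 74, 1094, 340, 0.54),
    (20, "control", 12.3, 154, 67, 782, 242, 0.80),
    (21, "control", 10.1, 163, 84, 961, 593, 0.62),
    (22, "control", 9.3, 158, 70, 1037, 425, 0.59),
    (23, "control", 9.1, 177, 101, 1126, 464, 0.52),
    (24, "control", 14.5, 167, 63, 830, 298, 0.87),
]


def reference_morphometry() -> pd.DataFrame:
    """The bundled reference dataset, one row per vertebral body."""
    rows = [
        (sid, "metastatic", lesion, bvtv, th, th_sd, sp, sp_sd, stn)
        for sid, lesion, bvtv, th, th_sd, sp, sp_sd, stn in _METASTATIC
    ] + [
        (sid, "control", lesion, bvtv, th, th_sd, sp, sp_sd, stn)
        for sid, lesion, bvtv, th, th_sd, sp, sp_sd, stn in _CONTROL
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def group_summary(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean ± sample SD of each morphometric parameter per group."""
    if df is None:
        df = reference_morphometry()
    params = ["bvtv_percent", "st_th_um", "st_sp_um", "st_n_per_mm"]
    out = []
    for group, sub in df.groupby("group", sort=False):
        row = {"group": group, "n": len(sub)}
        for p in params:
            row[f"{p}_mean"] = float(sub[p].mean())
            row[f"{p}_sd"] = float(sub[p].std(ddof=1))
        out.append(row)
    return pd.DataFrame(out)
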