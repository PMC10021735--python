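"""Published district-level figures for Maluku Province, Indonesia.

These are the province's key public-health characteristics by district
(2020 census populations, Ministry of Health facility registries, and
district mean travel distances by route type) used as the worked example
for the aggregation layer: province-level route-type means, the "all
routes" summary, access percentages and staffing-weight arithmetic can all
be recomputed from them.

Mean-distance cells that do not exist (Ambon has no naval-class
residences) are ``NaN``.  All distances are km; populations are persons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["load_maluku_districts", "MALUKU_DISTRICTS"]

_COLUMNS = [
    "district",
    "puskesmas",
    "hospitals",
    "physicians",
    "nurses",
    "midwives",
    "population",
    "pop_puskesmas_land",
    "pop_hospital_land",
    "pop_puskesmas_naval",
    "pop_hospital_naval",
    "mean_puskesmas_land_km",
    "mean_hospital_land_km",
    "mean_puskesmas_naval_km",
    "mean_hospital_naval_km",
]

nan = float("nan")

MALUKU_DISTRICTS = [
    # district, pusk, hosp, phys, nurse, midw, pop, p-land, h-land, p-nav, h-nav, d, f, d_nav, f_nav
    ("Ambon",                22, 9, 125, 899, 253, 347_288, 347_288, 347_288,      0,      0,  2.98,   5.96,   nan,    nan),
    ("Aru Islands",          27, 1,  12, 257,  59, 102_237,  63_342,  37_212, 38_895, 65_025,  2.88,   4.87, 16.31,  99.10),
    ("Buru",                 10, 1,  14, 298, 112, 135_238, 115_982, 115_982, 19_256, 19_256, 22.30,  63.39, 26.04,  56.20),
    ("Central Maluku",       33, 4,  69, 592, 407, 425_631, 411_834, 386_641, 13_797, 38_990, 11.80,  85.71, 32.18,  73.83),
    ("East Ceram",           19, 1,  24, 404, 149, 137_972, 125_378,  94_118, 12_594, 43_854,  7.69, 254.18, 15.36, 107.33),
    ("South Buru",           12, 1,   5, 179,  83,  75_410,  71_800,  55_085,  3_610, 20_325, 12.13,  92.43, 19.19,  60.13),
    ("Southeast Maluku",     18, 3,  31, 336, 115, 121_511, 112_533, 102_988,  8_978, 18_523,  5.61,  22.37, 12.12,  25.46),
    ("Southwest Maluku",     21, 1,  14, 242,  80,  81_928,  39_934,  18_505, 41_994, 63_423,  5.89,   2.53, 19.39, 178.58),
    ("Tual",                 15, 1,  22, 249, 105,  88_280,  84_242,  75_011,  4_038, 13_269,  1.60,   7.76, 11.02,  64.78),
    ("West Ceram",           17, 1,  16, 349, 193, 209_856, 179_359, 173_637, 30_497, 36_219, 12.11,  44.31, 15.92,  25.94),
    ("West Southeast Maluku",13, 3,  38, 243,  44, 123_572, 107_273,  89_060, 16_299, 34_512, 12.75,  34.56, 16.76,  39.50),
]


def load_maluku_districts() -> pd.DataFrame:
    """The 11 Maluku districts as a DataFrame (one row per district)."""
    df = pd.DataFrame(MALUKU_DISTRICTS, columns=_COLUMNS)
    return df.astype({c: np.float64 for c in _COLUMNS[11:]})
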