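"""Reference constants from the Hefei (Anhui, China) 2021 farmland case study.

These are the published calibration values and results tables for the Hefei
valuation: the 16 indicator weights of the comprehensive farmland quality
index, the fuzzy-membership function parameters for the ten numeric
indicators, the Delphi score scales for the six conceptual indicators, the
five-grade quality-index intervals, the per-region per-grade farmland areas,
the grade standard yields, and the per-grade economic values. They serve as
calibrated defaults for the pipeline and as an internal-consistency fixture:
the printed marginals can be re-derived from the printed cells, which
:func:`terravalue.valuation.consistency_check` verifies.

All values are reproduced verbatim as printed; where two printed numbers for
the same quantity disagree (see comments), both are kept and the choice of
canonical value is documented in the methods note.
"""

from __future__ import annotations

import pandas as pd

#: Indicator identifiers in canonical order. I1..I16 cover terrain (I1, I2),
#: soil physics (I3..I7), soil chemistry (I8..I12), location (I13, I14) and
#: ecology (I15, I16).
INDICATOR_IDS = tuple(f"I{i}" for i in range(1, 17))

INDICATOR_NAMES = {
    "I1": "topographic area",
    "I2": "slope",
    "I3": "cultivated-layer texture",
    "I4": "soil bulk density",
    "I5": "soil gravel volume",
    "I6": "effective water content",
    "I7": "farmland fragmentation",
    "I8": "soil pH",
    "I9": "soil organic matter",
    "I10": "cation exchange capacity",
    "I11": "organic carbon",
    "I12": "total nitrogen",
    "I13": "distance from the water system",
    "I14": "distance from settlements",
    "I15": "soil water conservation",
    "I16": "soil retention capacity",
}

#: AHP-derived weights C_i of the 16 indicators.  The printed column sums to
#: 0.9999 (not exactly 1); the values are kept verbatim.
INDICATOR_WEIGHTS = {
    "I1": 0.1191,
    "I2": 0.2381,
    "I3": 0.0632,
    "I4": 0.0309,
    "I5": 0.0188,
    "I6": 0.0442,
    "I7": 0.0173,
    "I8": 0.0434,
    "I9": 0.0819,
    "I10": 0.0434,
    "I11": 0.0756,
    "I12": 0.0264,
    "I13": 0.0426,
    "I14": 0.0426,
    "I15": 0.0562,
    "I16": 0.0562,
}

#: Fuzzy-membership function parameters for the ten numeric indicators:
#: (kind, a, b, c, u_lo, u_hi).  kind is "decreasing" or "peak"
#: (Y = 1 / (1 + a (u - c)^2)) or "linear" (Y = a u + b); u is clamped to
#: [u_lo, u_hi] before evaluation and Y to [0, 1] after.
#: Two printed oddities are kept as printed and flagged in the methods note:
#: the pH row is labelled peak-type but has c = 0 (monotone decreasing over
#: [5.4, 7.2]); the effective-water linear row never exceeds Y ~ 0.055 over
#: its own bounds.
MEMBERSHIP_PARAMS = {
    "I2": ("decreasing", 0.0157, None, 0.0, 0.0, 28.0476),
    "I7": ("decreasing", 0.0282, None, 0.2393, 0.0, 16.9944),
    "I5": ("decreasing", 0.0055, None, 1.2537, 5.66, 19.3860),
    "I4": ("peak", 57.0546, None, 1.2597, 1.21, 1.5),
    "I8": ("peak", 0.0034, None, 0.0, 5.4, 7.2),
    "I9": ("linear", 0.0417, -0.343143, None, 8.9648, 32.2732),
    "I10": ("linear", 0.0120, -1.735604, None, 138.7333, 228.4375),
    "I11": ("linear", 0.0482, 0.0, None, 0.0, 22.4),
    "I12": ("linear", 1.1069, -0.72424, None, 0.72, 1.81),
    "I6": ("linear", 0.0015, 0.0, None, 27.2, 36.8200),
}

#: Delphi score scales for the six conceptual indicators: ordered
#: category -> membership score.  Categories occupy consecutive columns of
#: the 1.0, 0.9, 0.8, ... score scale starting at 1.0 (best first).
CONCEPTUAL_CATEGORIES = {
    "I1": (
        "Impact Plains",
        "Alluvial fan plains",
        "Lacustrine plains",
        "Flood plains",
        "Storm the mesa",
        "Flood mesas",
        "Small undulating mountainous terrain",
    ),
    "I3": (
        "Tsubado",
        "Clay loam soil",
        "Silty loam",
        "Sandy loam",
        "Clay",
        "Heavy clay",
        "Loamy sandy soil",
        "Sandy soil",
    ),
    "I13": ("Closer", "Close", "Moderate", "Far", "Farther"),
    "I14": ("Closer", "Close", "Moderate", "Far", "Farther"),
    "I15": ("Stronger", "Strong ability", "Moderate", "Weak", "Weaker"),
    "I16": ("Stronger", "Strong ability", "Moderate", "Weak", "Weaker"),
}

#: Indicators scored through conceptual scales rather than numeric functions.
CONCEPTUAL_IDS = tuple(CONCEPTUAL_CATEGORIES)

#: Canonical five-grade quality-index intervals (grade I best), as published
#: with the grade-area results: {grade: (lower, upper)}.
GRADE_INTERVALS = {
    1: (0.6477, 0.7499),
    2: (0.6078, 0.6477),
    3: (0.5773, 0.6078),
    4: (0.5327, 0.5773),
    5: (0.3962, 0.5327),
}

#: Alternative interval set printed in the study's methods text; kept as a
#: named fixture because the two printed sets conflict.  The canonical set
#: above accompanies the published area results.
GRADE_INTERVALS_ALT = {
    1: (0.6477, 0.7499),
    2: (0.5738, 0.6477),
    3: (0.4991, 0.5738),
    4: (0.4186, 0.4991),
    5: (0.2840, 0.4186),
}

#: Farmland area (hm^2) per administrative region and quality grade.
#: Columns are grades 1 (best) to 5.
GRADE_AREAS_HM2 = {
    "Baohe": (45.41, 323.23, 653.02, 340.55, 2306.83),
    "Chaohu": (2493.1, 4134.98, 15500.8, 18479.64, 29128.09),
    "Feidong": (3685.99, 19874.53, 12608.84, 17571.45, 58758.1),
    "Feixi": (62.51, 1880.58, 13654.03, 18285.95, 42121.82),
    "Lujiang": (1589.93, 8896.8, 16834.84, 50363.67, 24121.19),
    "Luyang": (98.61, 870.89, 800.67, 367.54, 511.37),
    "Shushan": (26.49, 627.8, 3853.98, 16257.79, 941.65),
    "Yaohai": (7.27, 232.07, 1245.03, 1721.62, 825.23),
    "Changfeng": (16682.9, 12809.54, 26331.97, 32225.8, 1319.2),
}

#: Printed marginal totals of the regional area table (re-derivable from the
#: cells to print rounding; the consistency checks verify this).
PRINTED_REGION_TOTALS_HM2 = {
    "Baohe": 3669.04,
    "Chaohu": 69736.6,
    "Feidong": 112499.0,
    "Feixi": 76004.9,
    "Lujiang": 101806.0,
    "Luyang": 2649.08,
    "Shushan": 21707.7,
    "Yaohai": 4031.21,
    "Changfeng": 89369.4,
}

#: Printed per-grade area totals (hm^2), grades 1..5.  Note the grade-interval
#: table elsewhere prints 24692.89 for grade I; the regional table's 24692.2
#: is used here because it carries the regional breakdown.
PRINTED_GRADE_TOTALS_HM2 = (24692.2, 49650.41, 91483.2, 155614.0, 160033.49)

PRINTED_TOTAL_AREA_HM2 = 481473.0

#: Grade standard yields MPP_j (t/hm^2), grades 1..5, from the corrected
#: production-potential surface of the case study (not desk-reproducible
#: without the original rasters; shipped for valuation examples and tests).
GRADE_STANDARD_YIELDS_T_PER_HM2 = (10.28, 9.94, 9.31, 8.91, 7.95)

#: Published range of the climatic production potential surface (t/hm^2).
CLIMATIC_POTENTIAL_RANGE_T_PER_HM2 = (15.11, 16.69)
#: Published range of the quality-corrected production potential (t/hm^2).
MODIFIED_POTENTIAL_RANGE_T_PER_HM2 = (5.82, 12.52)

#: Rice economics (yuan per tonne), two-season averages for 2021.
RICE_PRICE_YUAN_PER_T = 2640.0
RICE_COST_YUAN_PER_T = 1760.0

#: Published per-grade unit economic values (yuan/hm^2), grades 1..5.  These
#: are NOT reproduced by MPP_j * (price - cost) with the values above
#: (10.28 * 880 = 9046.4, not 3291.13); the implied effective margin is about
#: 320.15 yuan/t.  They are consistent with the published totals below, which
#: is what the consistency checks assert.
UNIT_VALUES_YUAN_PER_HM2 = (3291.13, 3181.62, 2983.61, 2851.69, 2544.27)

#: Published per-grade total economic values (yuan), grades 1..5.
GRADE_TOTAL_VALUES_YUAN = (
    81265207.27,
    157968737.46,
    272950190.35,
    443762887.66,
    407168407.60,
)

PRINTED_TOTAL_VALUE_YUAN = 1363115430.35


def grade_area_table() -> pd.DataFrame:
    """Regional grade-area table as a DataFrame (regions x grades 1..5)."""
    return pd.DataFrame.from_dict(
        GRADE_AREAS_HM2, orient="index", columns=[1, 2, 3, 4, 5]
    ).rename_axis(index="region_id", columns="grade")


def indicator_value_ranges() -> dict[str, tuple[float, float]]:
    """Calibrated value bounds [u_lo, u_hi] of the ten numeric indicators."""
    return {
        iid: (p[4], p[5]) for iid, p in MEMBERSHIP_PARAMS.items()
    }
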