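"""Economic valuation of graded farmland and reference-table verification.

Per-grade unit values follow the soil-potential valuation identity

    V_j     = MPP_j * (p - c)          yuan/hm^2
    V_total = sum_j V_j * S_j          yuan

with p the crop market price and c the production cost (yuan per tonne,
two-season averages for a double-cropping system) and S_j the grade areas.
A single-year discount PV = V_1 / (1 + r) is provided for sensitivity
analysis.

The published Hefei unit values are not reproduced by the literal margin
identity with the published yields and prices (10.28 * 880 = 9046.4, not
3291.13); the module therefore also supports an externally supplied
effective margin and a totals-division mode
(:func:`derive_unit_values_from_totals`), and the consistency checks assert
only the internally consistent aggregation identities of the published
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from . import hefei2021


@dataclass(frozen=True)
class EconomicParams:
    """Crop economics: price and production cost in yuan per tonne, plus an
    optional discount rate for single-year present values."""

    price: float
    production_cost: float
    discount_rate: float | None = None

    def __post_init__(self) -> None:
        if self.price < 0 or self.production_cost < 0:
            raise ValueError("price and production cost must be non-negative")
        if self.discount_rate is not None and not (0 <= self.discount_rate < 1):
            raise ValueError("discount rate must lie in [0, 1)")

    @property
    def margin(self) -> float:
        return self.price - self.production_cost

    @classmethod
    def from_seasons(
        cls,
        seasons: Sequence[tuple[float, float]],
        discount_rate: float | None = None,
    ) -> "EconomicParams":
        """Average per-season (price, cost) pairs arithmetically, e.g. the
        two cropping seasons of a double-cropping rice system."""
        if not seasons:
            raise ValueError("at least one season required")
        p = float(np.mean([s[0] for s in seasons]))
        c = float(np.mean([s[1] for s in seasons]))
        return cls(p, c, discount_rate)


def hefei_params(discount_rate: float | None = None) -> EconomicParams:
    """The 2021 Hefei rice economics (2640 / 1760 yuan per tonne)."""
    return EconomicParams(
        hefei2021.RICE_PRICE_YUAN_PER_T,
        hefei2021.RICE_COST_YUAN_PER_T,
        discount_rate,
    )


@dataclass
class ValuationReport:
    """Per-grade and per-region economic values with shares and totals."""

    unit_values: pd.Series          # grade -> yuan/hm^2
    grade_values: pd.Series         # grade -> yuan
    region_values: pd.Series | None  # region -> yuan (None without regions)
    total_value: float              # yuan
    area_shares_pct: pd.Series      # grade -> % of total area
    value_shares_pct: pd.Series     # grade -> % of total value
    present_value: float | None = None
    notes: dict = field(default_factory=dict)


def unit_value(mpp_j, params: EconomicParams):
    """Per-hectare economic value V_j = MPP_j * (p - c) (yuan/hm^2).

    Accepts a scalar or a per-grade Series of standard yields.  A negative
    margin is allowed but warned about.
    """
    if params.margin < 0:
        warnings.warn("production cost exceeds price: negative margin",
                      stacklevel=2)
    out = np.asarray(mpp_j, dtype=float) * params.margin
    if isinstance(mpp_j, pd.Series):
        return pd.Series(out, index=mpp_j.index, name="V_j")
    return float(out) if out.ndim == 0 else out


def total_value(
    unit_values: pd.Series, areas: pd.DataFrame | pd.Series
) -> ValuationReport:
    """Aggregate per-grade unit values over grade areas into a full report.

    ``areas`` is a region x grade table (hm^2) or a per-grade Series; every
    grade carrying area must have a unit value.  Shares are exact
    percentages (display rounding is left to the caller).
    """
    if isinstance(areas, pd.Series):
        area_table = areas.to_frame().T
        area_table.index = ["all"]
        region_values = None
    else:
        area_table = areas
        region_values = "pending"
    grade_areas = area_table.sum(axis=0)
    active = grade_areas[grade_areas > 0].index
    missing = [g for g in active if g not in unit_values.index]
    if missing:
        raise KeyError(f"no unit value for grade(s) {missing}")
    uv = unit_values.reindex(grade_areas.index).fillna(0.0)
    grade_values = uv * grade_areas
    grade_values.name = "value_yuan"
    total = float(grade_values.sum())
    if region_values is not None:
        region_values = (area_table * uv).sum(axis=1)
        region_values.name = "value_yuan"
    total_area = float(grade_areas.sum())
    area_shares = 100.0 * grade_areas / total_area if total_area > 0 else (
        grade_areas * np.nan
    )
    value_shares = 100.0 * grade_values / total if total != 0 else (
        grade_values * np.nan
    )
    return ValuationReport(
        unit_values=uv,
        grade_values=grade_values,
        region_values=region_values,
        total_value=total,
        area_shares_pct=area_shares.rename("area_share_pct"),
        value_shares_pct=value_shares.rename("value_share_pct"),
    )


def value_shares(report: ValuationReport, decimals: int | None = None) -> pd.Series:
    """Per-grade percentage shares of the total value, optionally rounded for
    display."""
    if report.total_value <= 0:
        raise ValueError("total value must be positive to compute shares")
    s = report.value_shares_pct
    return s.round(decimals) if decimals is not None else s


def derive_unit_values_from_totals(totals: pd.Series, areas: pd.Series) -> pd.Series:
    """Per-grade unit values (yuan/hm^2) as totals / areas — the algebraic
    inverse of :func:`total_value` on exact inputs."""
    totals, areas = totals.align(areas, join="inner")
    if (areas <= 0).any():
        bad = areas.index[areas <= 0].tolist()
        raise ValueError(f"non-positive area for grade(s) {bad}")
    out = totals / areas
    out.name = "V_j"
    return out


def present_value(v1: float, r: float) -> float:
    """Single-year discount PV = V_1 / (1 + r)."""
    if r <= -1:
        raise ValueError("discount rate must exceed -1")
    return v1 / (1.0 + r)


# ---------------------------------------------------------------------------
# Reference-table consistency checks
# ---------------------------------------------------------------------------

def _check(name: str, ok: bool, computed, expected, tolerance) -> dict:
    return {
        "check": name,
        "passed": bool(ok),
        "computed": computed,
        "expected": expected,
        "tolerance": tolerance,
    }


def consistency_check() -> list[dict]:
    """Verify the embedded Hefei reference tables against their own printed
    marginals and stated proportions.

    Returns one record per check (name, passed, computed, expected,
    tolerance); failures are reported, never raised.
    """
    checks: list[dict] = []
    areas = hefei2021.grade_area_table()

    # regional area table: row sums vs printed region totals (print rounding)
    row_sums = areas.sum(axis=1)
    for region, printed in hefei2021.PRINTED_REGION_TOTALS_HM2.items():
        got = float(row_sums[region])
        checks.append(_check(
            f"region total {region} (hm2)", abs(got - printed) <= 0.5,
            got, printed, 0.5,
        ))
    # column sums vs printed grade totals and grand total
    col_sums = areas.sum(axis=0)
    for g, printed in enumerate(hefei2021.PRINTED_GRADE_TOTALS_HM2, start=1):
        got = float(col_sums[g])
        checks.append(_check(
            f"grade {g} area total (hm2)", abs(got - printed) <= 0.5,
            got, printed, 0.5,
        ))
    grand = float(areas.to_numpy().sum())
    checks.append(_check(
        "total farmland area (hm2)",
        abs(grand - hefei2021.PRINTED_TOTAL_AREA_HM2) <= 0.5,
        grand, hefei2021.PRINTED_TOTAL_AREA_HM2, 0.5,
    ))

    # value table: per-grade totals sum to the printed grand total
    vt = float(np.sum(hefei2021.GRADE_TOTAL_VALUES_YUAN))
    checks.append(_check(
        "total economic value (yuan)",
        abs(vt - hefei2021.PRINTED_TOTAL_VALUE_YUAN) <= 0.01,
        vt, hefei2021.PRINTED_TOTAL_VALUE_YUAN, 0.01,
    ))
    # unit values x grade areas reproduce the grand total (printed rounding)
    uv = pd.Series(hefei2021.UNIT_VALUES_YUAN_PER_HM2, index=[1, 2, 3, 4, 5])
    recomputed = float((uv * col_sums).sum())
    rel = abs(recomputed - hefei2021.PRINTED_TOTAL_VALUE_YUAN) / (
        hefei2021.PRINTED_TOTAL_VALUE_YUAN
    )
    checks.append(_check(
        "unit values x areas vs total value (relative)",
        rel <= 1e-5, recomputed, hefei2021.PRINTED_TOTAL_VALUE_YUAN, 1e-5,
    ))

    # stated proportions: grade-area shares after integer rounding
    for g, pct in ((1, 5), (2, 10), (3, 19), (4, 32), (5, 33)):
        got = round(100.0 * float(col_sums[g]) / grand)
        checks.append(_check(
            f"grade {g} area share (%)", got == pct, got, pct, "integer rounding",
        ))
    # regional dominant-grade shares
    for region, g, pct in (
        ("Baohe", 5, 63), ("Chaohu", 5, 42), ("Feidong", 5, 52),
        ("Feixi", 5, 55), ("Lujiang", 4, 49), ("Luyang", 2, 33),
        ("Shushan", 4, 75), ("Yaohai", 4, 43), ("Changfeng", 4, 36),
    ):
        got = round(100.0 * float(areas.loc[region, g]) / float(row_sums[region]))
        checks.append(_check(
            f"{region} dominant grade {g} share (%)", got == pct, got, pct,
            "integer rounding",
        ))
    # value shares: second grade to one decimal, fifth after integer rounding
    gv = pd.Series(hefei2021.GRADE_TOTAL_VALUES_YUAN, index=[1, 2, 3, 4, 5])
    second = round(100.0 * float(gv[2]) / hefei2021.PRINTED_TOTAL_VALUE_YUAN, 1)
    checks.append(_check(
        "grade 2 value share (%)", second == 11.6, second, 11.6, "1 decimal",
    ))
    fifth = round(100.0 * float(gv[5]) / hefei2021.PRINTED_TOTAL_VALUE_YUAN)
    checks.append(_check(
        "grade 5 value share (%)", fifth == 30, fifth, 30, "integer rounding",
    ))
    return checks
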