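"""Climatic and quality-corrected production potential.

The Thornthwaite Memorial model estimates the climate-limited net primary
productivity of a site from annual mean temperature T (degC) and annual
precipitation R (mm):

    L     = 0.05 T^3 + 25 T + 300                 annual maximum
                                                  evapotranspiration (mm)
    V     = 1.05 R / sqrt(1 + (1.05 R / L)^2)     annual actual
                                                  evapotranspiration (mm)
    NPP_T = 3000 (1 - exp(-0.0009695 (V - 20)))   climatic production
                                                  potential (g/m^2)

NPP_T is floored at 0 for V < 20 mm (the closed form goes negative there)
and converted to field units by 1 g/m^2 = 0.01 t/hm^2.  The climatic
potential is then attenuated by the quality index, MPP = IFI * NPP_T,
and grade standard yields MPP_j are area-weighted means of MPP over the
units of each grade.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Conversion factor: 1 g/m^2 = 0.01 t/hm^2.
G_PER_M2_TO_T_PER_HM2 = 0.01

_NPP_RATE = 0.0009695
_NPP_CEILING_G_PER_M2 = 3000.0


def max_evapotranspiration(T):
    """Annual maximum evapotranspiration L (mm) from mean temperature (degC):
    L = 0.05 T^3 + 25 T + 300."""
    T = np.asarray(T, dtype=float)
    L = 0.05 * T ** 3 + 25.0 * T + 300.0
    return float(L) if L.ndim == 0 else L


def actual_evapotranspiration(R, L):
    """Annual actual evapotranspiration V (mm):
    V = 1.05 R / sqrt(1 + (1.05 R / L)^2).

    V rises with precipitation supply but saturates at the thermal demand L.
    """
    R = np.asarray(R, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("maximum evapotranspiration L must be positive")
    if np.any(R < 0):
        raise ValueError("precipitation R must be non-negative")
    x = 1.05 * R
    V = x / np.sqrt(1.0 + (x / L) ** 2)
    return float(V) if V.ndim == 0 else V


def climatic_npp(V):
    """Climatic production potential NPP_T (g/m^2) from actual
    evapotranspiration V (mm), floored at 0 for V < 20 mm."""
    V = np.asarray(V, dtype=float)
    npp = _NPP_CEILING_G_PER_M2 * (1.0 - np.exp(-_NPP_RATE * (V - 20.0)))
    npp = np.maximum(npp, 0.0)
    return float(npp) if npp.ndim == 0 else npp


def npp_to_t_per_hm2(npp):
    """Convert NPP from g/m^2 to t/hm^2 (factor 0.01)."""
    npp = np.asarray(npp, dtype=float)
    if np.any(npp < 0):
        raise ValueError("NPP must be non-negative")
    out = npp * G_PER_M2_TO_T_PER_HM2
    return float(out) if out.ndim == 0 else out


def climatic_potential_t_per_hm2(T, R):
    """Convenience chain: T, R -> NPP_T in t/hm^2."""
    return npp_to_t_per_hm2(
        climatic_npp(actual_evapotranspiration(R, max_evapotranspiration(T)))
    )


def modified_potential(ifi, npp_t):
    """Quality-corrected production potential MPP = IFI * NPP_T (t/hm^2).

    Accepts matching scalars, arrays or aligned Series; IFI must lie in
    [0, 1].
    """
    ifi_arr = np.asarray(ifi, dtype=float)
    npp_arr = np.asarray(npp_t, dtype=float)
    finite = np.isfinite(ifi_arr)
    if np.any((ifi_arr[finite] < 0) | (ifi_arr[finite] > 1)):
        raise ValueError("IFI must lie in [0, 1]")
    if ifi_arr.shape != npp_arr.shape and ifi_arr.ndim and npp_arr.ndim:
        raise ValueError(
            f"shape mismatch: IFI {ifi_arr.shape} vs NPP {npp_arr.shape}"
        )
    out = ifi_arr * npp_arr
    if isinstance(ifi, pd.Series):
        return pd.Series(out, index=ifi.index, name="MPP")
    return float(out) if out.ndim == 0 else out


def grade_standard_yield(
    mpp: pd.Series,
    grades: pd.Series,
    areas: pd.Series,
    area_weighted: bool = True,
) -> pd.Series:
    """Grade standard yields MPP_j (t/hm^2): mean MPP over units per grade.

    Area-weighted by default (matching zonal statistics over unit polygons);
    ``area_weighted=False`` gives the unweighted unit mean.  Grades with no
    units are absent from the result (flagged by omission, never reported as
    zero).  Indexed like ``mpp``/``grades``/``areas`` by unit_id.
    """
    df = pd.DataFrame({"mpp": mpp, "grade": grades, "area": areas}).dropna(
        subset=["mpp", "grade"]
    )
    if df.empty:
        raise ValueError("no graded units with production potential")
    df["grade"] = df["grade"].astype(int)
    if area_weighted:
        g = df.groupby("grade").apply(
            lambda d: float(np.average(d["mpp"], weights=d["area"])),
            include_groups=False,
        )
    else:
        g = df.groupby("grade")["mpp"].mean()
    g.name = "MPP_j"
    return g.sort_index()
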