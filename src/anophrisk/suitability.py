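"""Sub-model 1: probability of Anopheles presence per cell, species and month.

Four scores combine multiplicatively:

* Y1[species] — land-use suitability, the sp_i-weighted mean of expert
  weights a_i rescaled by 1/10 to [0, 1];
* Y2[month]   — piecewise-linear temperature response (0 below 15 C, plateau
  on 28-33 C, 0 at and above 36 C);
* Y3a[month]  — piecewise-linear rainfall response (0 below 40 mm/month,
  peak at 400 mm, 0 at and above 800 mm);
* Y3[month]   — Y3a modulated by the cell's normalised topographic wetness
  index, expressing that suitable rain only matters where terrain lets
  water accumulate;
* Y4[month, species] = Y1[species] * Y2[month] * Y3[month], aggregated over
  months (mean or max) and averaged over species for the headline surface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SPECIES, ModelParams, WeightTable

__all__ = ["y1_landuse", "y2_temperature", "y3_rainfall", "y4_presence",
           "combine_twi", "suitability_columns"]


def combine_twi(base: np.ndarray, twi_norm: np.ndarray,
                params: ModelParams) -> np.ndarray:
    """Modulate a [0,1] score by the normalised wetness index.

    ``"multiply"`` (default): score * twi_norm — full range, zero where no
    water accumulates.  ``"modulate"``: score * (0.5 + 0.5 * twi_norm) — a
    gentler alternative that never halves more than the dry extreme.
    """
    if params.twi_combiner == "multiply":
        return base * twi_norm
    return base * (0.5 + 0.5 * twi_norm)


def y1_landuse(sp: pd.DataFrame, weights: WeightTable,
               species: str) -> np.ndarray:
    """Land-use presence score Y1 = (1/10) sum_i a_i sp_i for one species.

    ``sp`` holds per-cell proportions in columns named ``sp_<code>``.
    """
    total = np.zeros(len(sp))
    for col in sp.columns:
        code = int(col.removeprefix("sp_"))
        a = weights.suitability(code, species)
        total = total + a * sp[col].to_numpy(float)
    return total / 10.0


def y2_temperature(T, params: ModelParams) -> np.ndarray:
    """Temperature response Y2: trapezoid over (u1, u2, u3, u4) deg C."""
    t = np.asarray(T, dtype=float)
    u1, u2, u3, u4 = params.temp_breaks
    y = np.zeros_like(t)
    rise = (t >= u1) & (t < u2)
    y[rise] = (t[rise] - u1) / (u2 - u1)
    y[(t >= u2) & (t < u3)] = 1.0
    fall = (t >= u3) & (t < u4)
    y[fall] = (u4 - t[fall]) / (u4 - u3)
    y[np.isnan(t)] = np.nan
    return y


def y3_rainfall(R, twi_norm, params: ModelParams
                ) -> tuple[np.ndarray, np.ndarray]:
    """Rainfall response Y3a (triangle over v1, v2, v3 mm/month) and Y3.

    Y3 folds in the cell's capacity to accumulate the water: Y3a combined
    with the normalised wetness index (see :func:`combine_twi`).
    """
    r = np.asarray(R, dtype=float)
    v1, v2, v3 = params.rain_breaks
    y3a = np.zeros_like(r)
    rise = (r >= v1) & (r < v2)
    y3a[rise] = (r[rise] - v1) / (v2 - v1)
    fall = (r >= v2) & (r < v3)
    y3a[fall] = (v3 - r[fall]) / (v3 - v2)
    y3a[np.isnan(r)] = np.nan
    y3 = combine_twi(y3a, np.asarray(twi_norm, dtype=float), params)
    return y3a, y3


def y4_presence(Y1: dict[str, np.ndarray], Y2: np.ndarray, Y3: np.ndarray,
                params: ModelParams
                ) -> tuple[dict[tuple[int, str], np.ndarray], np.ndarray]:
    """Presence probability Y4[month, species] = Y1[s] * Y2[m] * Y3[m].

    ``Y2`` and ``Y3`` are (12, n_cells) arrays.  Returns the per-month,
    per-species surfaces and the headline aggregate: months reduced by
    ``params.month_aggregate`` (mean or max, ignoring missing months), then
    averaged over the three species.
    """
    if Y2.shape != Y3.shape or Y2.shape[0] != 12:
        raise ValueError("Y2 and Y3 must be (12, n_cells) arrays")
    per = {}
    agg_by_species = []
    monthly_presence = Y2 * Y3  # (12, n)
    for s in SPECIES:
        y4_ms = Y1[s][None, :] * monthly_presence
        for m in range(12):
            per[(m + 1, s)] = y4_ms[m]
        with np.errstate(invalid="ignore"):
            if params.month_aggregate == "mean":
                agg = np.nanmean(y4_ms, axis=0)
            else:
                agg = np.nanmax(y4_ms, axis=0)
        agg_by_species.append(agg)
    y4_agg = np.nanmean(np.stack(agg_by_species), axis=0)
    return per, y4_agg


def suitability_columns(sp: pd.DataFrame, T_months: np.ndarray,
                        R_months: np.ndarray, twi_norm: np.ndarray,
                        weights: WeightTable, params: ModelParams
                        ) -> pd.DataFrame:
    """All sub-model-1 columns for a cell table.

    ``T_months``/``R_months`` are (12, n_cells).  Output columns:
    ``Y1_<species>``, ``Y2_<mm>``, ``Y3a_<mm>``, ``Y3_<mm>``,
    ``Y4_<mm>_<species>`` and the aggregate ``Y4``.
    """
    out = {}
    Y1 = {s: y1_landuse(sp, weights, s) for s in SPECIES}
    for s in SPECIES:
        out[f"Y1_{s}"] = Y1[s]
    Y2 = np.stack([y2_temperature(T_months[m], params) for m in range(12)])
    Y3a = np.empty_like(Y2)
    Y3 = np.empty_like(Y2)
    for m in range(12):
        Y3a[m], Y3[m] = y3_rainfall(R_months[m], twi_norm, params)
        out[f"Y2_{m + 1:02d}"] = Y2[m]
        out[f"Y3a_{m + 1:02d}"] = Y3a[m]
        out[f"Y3_{m + 1:02d}"] = Y3[m]
    per, y4_agg = y4_presence(Y1, Y2, Y3, params)
    for (m, s), v in per.items():
        out[f"Y4_{m:02d}_{s}"] = v
    out["Y4"] = y4_agg
    return pd.DataFrame(out, index=sp.index)
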