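"""Sub-model 2: probability of insecticide use (selection pressure) per cell.

Two pressure sources combine:

* Y5a — agricultural intensity, the sp_i-weighted mean of (b_i - 1)/4 where
  b_i is the 1-4 expert insecticide score per land-use class (so a pure
  b=1 landscape scores 0 and a pure b=4 landscape 0.75);
* Y5  — Y5a modulated by the normalised wetness index: leached pesticides
  accumulate downstream, so wet-receiving cells carry more pressure;
* Y6  — ITN-derived pressure from per-person net density D, rising linearly
  from 0 at D=0.05 to 1 at D=0.5;
* Y7 = 0.9 Y5 + 0.1 Y6 — agricultural pressure dominates because field
  pesticide volumes dwarf bed-net insecticide loads.  The structural ceiling
  is therefore 0.9*0.75 + 0.1 = 0.775.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ModelParams, WeightTable
from .suitability import combine_twi

__all__ = ["y5_landuse", "y6_itn", "y7_combine", "insecticide_columns"]


def y5_landuse(sp: pd.DataFrame, weights: WeightTable, twi_norm,
               params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Agricultural insecticide scores (Y5a, Y5).

    Y5a = (1/4) sum_i (b_i - 1) sp_i; Y5 folds in downstream accumulation
    via the normalised wetness index.
    """
    total = np.zeros(len(sp))
    for col in sp.columns:
        code = int(col.removeprefix("sp_"))
        b = weights.insecticide(code)
        total = total + (b - 1.0) * sp[col].to_numpy(float)
    y5a = total / 4.0
    y5 = combine_twi(y5a, np.asarray(twi_norm, dtype=float), params)
    return y5a, y5


def y6_itn(D, params: ModelParams) -> np.ndarray:
    """ITN resistance pressure Y6 from per-person net density D.

    Zero below ``itn_zero`` (0.05 nets/person), linear to 1 at ``itn_full``
    (0.5), saturated above.
    """
    d = np.asarray(D, dtype=float)
    lo, hi = params.itn_zero, params.itn_full
    y = np.zeros_like(d)
    mid = (d >= lo) & (d < hi)
    y[mid] = (d[mid] - lo) / (hi - lo)
    y[d >= hi] = 1.0
    y[np.isnan(d)] = np.nan
    return y


def y7_combine(Y5, Y6, params: ModelParams) -> np.ndarray:
    """Overall insecticide-use probability Y7 = w_agri*Y5 + w_itn*Y6."""
    w5, w6 = params.y7_weights
    return w5 * np.asarray(Y5, float) + w6 * np.asarray(Y6, float)


def insecticide_columns(sp: pd.DataFrame, twi_norm: np.ndarray, D: np.ndarray,
                        weights: WeightTable, params: ModelParams
                        ) -> pd.DataFrame:
    """Columns Y5a, Y5, Y6, Y7 for a cell table."""
    y5a, y5 = y5_landuse(sp, weights, twi_norm, params)
    y6 = y6_itn(D, params)
    return pd.DataFrame({
        "Y5a": y5a, "Y5": y5, "Y6": y6,
        "Y7": y7_combine(y5, y6, params),
    }, index=sp.index)
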