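"""Sub-model 3: vulnerability of the human population per cell.

Vulnerability is threat-independent susceptibility:

* Y8a = (2/pi) arctan(P / 5000)  — population-density component (P persons
  in the cell; saturating, ~0.705 at P = 10,000);
* Y8b = (2/pi) arctan(P' / 1000) — poverty component (P' persons below the
  poverty line), on a sharper scale because poor households are more
  exposed;
* Y8  = (Y8a + 3 Y8b) / 4 — poverty carries triple weight;
* Y9  — bed-net protection factor, 1 below D = 0.05 nets/person falling
  linearly to a floor of 0.25 at D >= 0.5 (net ownership never protects
  everyone, so the factor is bounded away from zero);
* Y10 = Y8 * Y9.

The same per-person ITN density D raises resistance pressure in sub-model 2
and lowers vulnerability here — the intended duality of net distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ModelParams

__all__ = ["y8_population", "y9_protection", "y10_vulnerability",
           "vulnerability_columns"]


def y8_population(P, P_poor, params: ModelParams
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Population and poverty vulnerability (Y8a, Y8b, Y8)."""
    p = np.asarray(P, dtype=float)
    pp = np.asarray(P_poor, dtype=float)
    y8a = (2.0 / np.pi) * np.arctan(p / params.pop_scale)
    y8b = (2.0 / np.pi) * np.arctan(pp / params.poverty_scale)
    w_a, w_b = params.y8_weights
    y8 = (w_a * y8a + w_b * y8b) / (w_a + w_b)
    return y8a, y8b, y8


def y9_protection(D, params: ModelParams) -> np.ndarray:
    """Bed-net protection factor Y9 (1 = unprotected, floor = 0.25).

    Falls linearly from 1 at D = itn_zero to the floor at D = itn_full; the
    slope (D - itn_zero)/0.6 makes the function exactly continuous at the
    floor: 1 - 0.45/0.6 = 0.25.
    """
    d = np.asarray(D, dtype=float)
    lo, hi = params.itn_zero, params.itn_full
    span = (hi - lo) / (1.0 - params.y9_floor)
    y = np.ones_like(d)
    mid = (d >= lo) & (d < hi)
    y[mid] = 1.0 - (d[mid] - lo) / span
    y[d >= hi] = params.y9_floor
    y[np.isnan(d)] = np.nan
    return y


def y10_vulnerability(Y8, Y9) -> np.ndarray:
    """Final vulnerability Y10 = Y8 * Y9."""
    return np.asarray(Y8, float) * np.asarray(Y9, float)


def vulnerability_columns(P: np.ndarray, P_poor: np.ndarray, D: np.ndarray,
                          params: ModelParams) -> pd.DataFrame:
    """Columns Y8a, Y8b, Y8, Y9, Y10 for a cell table."""
    y8a, y8b, y8 = y8_population(P, P_poor, params)
    y9 = y9_protection(D, params)
    return pd.DataFrame({
        "Y8a": y8a, "Y8b": y8b, "Y8": y8,
        "Y9": y9, "Y10": y10_vulnerability(y8, y9),
    })
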