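"""Model constants and the expert land-use weight table.

Every numeric constant of the model lives here as validated, file-backed
configuration: the expert suitability weights ``a_i`` (0-10, one per vector
species and land-use class) and insecticide-intensity scores ``b_i`` (1-4)
ship as a versioned CSV inside the package, and the piecewise-response
breakpoints, mixing weights and scaling constants are fields of
:class:`ModelParams` with the published defaults.  The model math elsewhere
never hard-codes a number.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "SPECIES",
    "LandUseWeight",
    "WeightTable",
    "ModelParams",
    "load_weight_table",
    "write_weight_table",
    "default_weight_table",
    "load_params",
]

logger = logging.getLogger(__name__)

#: The three primary malaria vector species complexes modeled.
SPECIES = ("dirus", "maculatus", "minimus")

_WEIGHT_COLUMNS = ["code", "label", "a_dirus", "a_maculatus", "a_minimus",
                   "b_insecticide"]


@dataclass(frozen=True)
class LandUseWeight:
    """Expert scores for one land-use class.

    ``a_*`` are suitability weights (0 = hostile, 10 = highly favorable)
    for Anopheles dirus s.l., An. maculatus s.l. and An. minimus s.l.;
    ``b_insecticide`` scores agricultural insecticide intensity (1 = lowest,
    4 = highest).
    """

    code: int
    label: str
    a_dirus: int
    a_maculatus: int
    a_minimus: int
    b_insecticide: int

    def __post_init__(self) -> None:
        for sp in SPECIES:
            a = getattr(self, f"a_{sp}")
            if not 0 <= a <= 10:
                raise ValueError(
                    f"code {self.code}: suitability weight a_{sp}={a} outside [0, 10]")
        if not 1 <= self.b_insecticide <= 4:
            raise ValueError(
                f"code {self.code}: insecticide score b={self.b_insecticide} "
                "outside [1, 4]")

    def a(self, species: str) -> int:
        if species not in SPECIES:
            raise KeyError(f"unknown species {species!r}; expected one of {SPECIES}")
        return getattr(self, f"a_{species}")


class WeightTable:
    """Mapping land-use code -> :class:`LandUseWeight`.

    Parameters
    ----------
    weights : iterable of LandUseWeight
    unknown_policy : {"zero", "error"}
        What to do when scoring a land-use code absent from the table.
        ``"zero"`` (default) treats it as uninhabitable and insecticide-free
        (a=0, b=1) with a logged warning; ``"error"`` raises.
    """

    def __init__(self, weights, unknown_policy: str = "zero") -> None:
        if unknown_policy not in {"zero", "error"}:
            raise ValueError("unknown_policy must be 'zero' or 'error'")
        self.unknown_policy = unknown_policy
        self._by_code: dict[int, LandUseWeight] = {}
        for w in weights:
            if w.code in self._by_code:
                raise ValueError(f"duplicate code {w.code}")
            self._by_code[w.code] = w
        self._warned: set[int] = set()

    # -- mapping protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self._by_code)

    def __contains__(self, code: int) -> bool:
        return int(code) in self._by_code

    def __getitem__(self, code: int) -> LandUseWeight:
        return self._by_code[int(code)]

    @property
    def codes(self) -> list[int]:
        return sorted(self._by_code)

    def _handle_unknown(self, code: int) -> None:
        if self.unknown_policy == "error":
            raise KeyError(f"unknown land-use code {code}")
        if code not in self._warned:
            logger.warning(
                "unknown land-use code %s: scored as a=0 (no suitability), "
                "b=1 (lowest insecticide use)", code)
            self._warned.add(code)

    def suitability(self, code: int, species: str) -> float:
        """Suitability weight a_i for a species, honouring the unknown policy."""
        code = int(code)
        if code not in self._by_code:
            self._handle_unknown(code)
            return 0.0
        return float(self._by_code[code].a(species))

    def insecticide(self, code: int) -> float:
        """Insecticide-intensity score b_i, honouring the unknown policy."""
        code = int(code)
        if code not in self._by_code:
            self._handle_unknown(code)
            return 1.0
        return float(self._by_code[code].b_insecticide)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "code": w.code, "label": w.label, "a_dirus": w.a_dirus,
                "a_maculatus": w.a_maculatus, "a_minimus": w.a_minimus,
                "b_insecticide": w.b_insecticide,
            }
            for w in self._by_code.values()
        ]
        return pd.DataFrame(rows, columns=_WEIGHT_COLUMNS).sort_values(
            "code").reset_index(drop=True)


def load_weight_table(path: str | Path | None = None,
                      unknown_policy: str = "zero") -> WeightTable:
    """Load a land-use weight table from CSV (default: the shipped table).

    The CSV must have columns ``code,label,a_dirus,a_maculatus,a_minimus,
    b_insecticide``.  Duplicate codes and out-of-range weights are hard
    errors naming the offending row.
    """
    if path is None:
        ref = importlib.resources.files("anophrisk.data") / "landuse_weights.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = set(_WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    dup = df["code"][df["code"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate code {int(dup.iloc[0])}")
    weights = []
    for idx, row in df.iterrows():
        try:
            weights.append(LandUseWeight(
                code=int(row["code"]), label=str(row["label"]),
                a_dirus=int(row["a_dirus"]), a_maculatus=int(row["a_maculatus"]),
                a_minimus=int(row["a_minimus"]),
                b_insecticide=int(row["b_insecticide"])))
        except ValueError as exc:
            raise ValueError(f"row {idx + 2}: {exc}") from exc  # +2: header + 1-based
    return WeightTable(weights, unknown_policy=unknown_policy)


def default_weight_table(unknown_policy: str = "zero") -> WeightTable:
    """The shipped expert weight table for the Lao land-use classification."""
    return load_weight_table(None, unknown_policy=unknown_policy)


def write_weight_table(table: WeightTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ModelParams:
    """All scalar constants of the risk model, with published defaults.

    Temperature response (Y2): zero below ``u1``, linear rise to 1 at ``u2``,
    plateau to ``u3``, linear fall to zero at ``u4`` (deg C).  Rainfall
    response (Y3a): zero below ``v1`` mm/month, peak 1 at ``v2``, zero at
    ``v3``.  ITN (insecticide-treated net) density responses use the same
    per-person breakpoints ``itn_zero``/``itn_full`` for resistance pressure
    (Y6, rising) and protection (Y9, falling to the ``y9_floor``).
    """

    temp_breaks: tuple[float, float, float, float] = (15.0, 28.0, 33.0, 36.0)
    rain_breaks: tuple[float, float, float] = (40.0, 400.0, 800.0)
    itn_zero: float = 0.05
    itn_full: float = 0.5
    y9_floor: float = 0.25
    pop_scale: float = 5000.0      # persons; arctan scale of Y8a
    poverty_scale: float = 1000.0  # persons below poverty line; scale of Y8b
    y7_weights: tuple[float, float] = (0.9, 0.1)   # agricultural vs ITN pressure
    y8_weights: tuple[float, float] = (1.0, 3.0)   # density vs poverty in Y8
    month_aggregate: str = "mean"  # {"mean", "max"} over months for Y4
    twi_combiner: str = "multiply"  # {"multiply", "modulate"} for Y3 and Y5

    def __post_init__(self) -> None:
        u1, u2, u3, u4 = self.temp_breaks
        if not (u1 < u2 < u3 < u4):
            raise ValueError(f"temperature breakpoints must increase: {self.temp_breaks}")
        v1, v2, v3 = self.rain_breaks
        if not (v1 < v2 < v3):
            raise ValueError(f"rainfall breakpoints must increase: {self.rain_breaks}")
        if not self.itn_zero < self.itn_full:
            raise ValueError("itn_zero must be < itn_full")
        if not 0 < self.y9_floor < 1:
            raise ValueError("y9_floor must be in (0, 1)")
        if abs(sum(self.y7_weights) - 1.0) > 1e-12:
            raise ValueError("y7_weights must sum to 1")
        if self.pop_scale <= 0 or self.poverty_scale <= 0:
            raise ValueError("population scales must be positive")
        if self.month_aggregate not in {"mean", "max"}:
            raise ValueError("month_aggregate must be 'mean' or 'max'")
        if self.twi_combiner not in {"multiply", "modulate"}:
            raise ValueError("twi_combiner must be 'multiply' or 'modulate'")


_TUPLE_FIELDS = {"temp_breaks": 4, "rain_breaks": 3, "y7_weights": 2,
                 "y8_weights": 2}


def load_params(path: str | Path | None = None, **overrides) -> ModelParams:
    """Load :class:`ModelParams` from a flat-key YAML file (all keys optional).

    An absent path returns the published defaults.  Keyword overrides are
    applied after the file.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("params file must map keys to values")
        values.update(loaded)
    values.update(overrides)
    unknown = set(values) - set(ModelParams.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    for key, n in _TUPLE_FIELDS.items():
        if key in values:
            t = tuple(float(x) for x in values[key])
            if len(t) != n:
                raise ValueError(f"{key} must have {n} entries")
            values[key] = t
    return ModelParams(**values)
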