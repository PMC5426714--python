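"""Sub-model math: piecewise responses, weighted scores, products."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from anophrisk.config import SPECIES, ModelParams
from anophrisk.insecticide import y5_landuse, y6_itn, y7_combine
from anophrisk.suitability import (y1_landuse, y2_temperature, y3_rainfall,
                                   y4_presence)
from anophrisk.vulnerability import (y8_population, y9_protection,
                                     y10_vulnerability)


def sp_frame(props: dict[int, float], n: int = 1) -> pd.DataFrame:
    return pd.DataFrame({f"sp_{c}": [v] * n for c, v in props.items()})


class TestY1Landuse:
    def test_pure_evergreen_forest_dirus(self, weights, params):
        assert y1_landuse(sp_frame({11: 1.0}), weights, "dirus")[0] == 1.0

    def test_pure_urban_all_species_zero(self, weights, params):
        for s in SPECIES:
            assert y1_landuse(sp_frame({54: 1.0}), weights, s)[0] == 0.0

    def test_forest_paddy_mix(self, weights, params):
        sp = sp_frame({11: 0.5, 41: 0.5})
        assert y1_landuse(sp, weights, "dirus")[0] == pytest.approx(0.6)

    def test_bounded_in_unit_interval(self, weights):
        for s in SPECIES:
            for codes in ({547: 1.0}, {11: 0.3, 41: 0.3, 54: 0.4}):
                v = y1_landuse(sp_frame(codes), weights, s)[0]
                assert 0.0 <= v <= 1.0


class TestY2Temperature:
    @pytest.mark.parametrize("T,expected", [
        (14.0, 0.0),    # below activity threshold
        (15.0, 0.0),    # rise starts at u1
        (21.5, 0.5),    # midway up: (21.5-15)/13
        (28.0, 1.0),    # optimum plateau start
        (30.0, 1.0),
        (34.5, 0.5),    # midway down: (36-34.5)/3
        (36.0, 0.0),    # lethal heat
        (40.0, 0.0),
    ])
    def test_printed_formula(self, params, T, expected):
        assert y2_temperature(T, params) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("b", [15.0, 28.0, 33.0, 36.0])
    def test_continuity_at_breakpoints(self, params, b):
        eps = 1e-9
        left = y2_temperature(b - eps, params)
        right = y2_temperature(b + eps, params)
        at = y2_temperature(b, params)
        assert abs(left - at) < 1e-8 and abs(right - at) < 1e-8

    @given(st.floats(min_value=-10, max_value=50),
           st.floats(min_value=0, max_value=5))
    def test_monotone_on_rise_and_fall(self, t, dt):
        p = ModelParams()
        lo = y2_temperature(t, p)
        hi = y2_temperature(t + dt, p)
        if t >= p.temp_breaks[0] and t + dt <= p.temp_breaks[1]:
            assert hi >= lo - 1e-12
        if t >= p.temp_breaks[2] and t + dt <= p.temp_breaks[3]:
            assert hi <= lo + 1e-12
        assert 0.0 <= lo <= 1.0


class TestY3Rainfall:
    @pytest.mark.parametrize("R,expected", [
        (39.9, 0.0), (40.0, 0.0), (220.0, 0.5), (400.0, 1.0),
        (600.0, 0.5), (800.0, 0.0), (1200.0, 0.0),
    ])
    def test_printed_formula(self, params, R, expected):
        y3a, _ = y3_rainfall(R, 1.0, params)
        assert y3a == pytest.approx(expected, abs=1e-12)

    def test_wetness_modulation(self, params):
        y3a, y3 = y3_rainfall(600.0, 0.5, params)
        assert y3a == pytest.approx(0.5) and y3 == pytest.approx(0.25)

    @pytest.mark.parametrize("b", [40.0, 400.0, 800.0])
    def test_continuity_at_breakpoints(self, params, b):
        eps = 1e-9
        vals = [y3_rainfall(b + s * eps, 1.0, params)[0] for s in (-1, 0, 1)]
        assert max(vals) - min(vals) < 1e-8

    def test_modulate_combiner_alternative(self):
        p = ModelParams(twi_combiner="modulate")
        _, y3 = y3_rainfall(400.0, 0.0, p)
        assert y3 == pytest.approx(0.5)  # dry extreme only halves the score


class TestY4Presence:
    def _arrays(self, y1v, y2v, y3v):
        Y1 = {s: np.array([y1v]) for s in SPECIES}
        Y2 = np.full((12, 1), y2v)
        Y3 = np.full((12, 1), y3v)
        return Y1, Y2, Y3

    def test_all_ones(self, params):
        per, agg = y4_presence(*self._arrays(1, 1, 1), params)
        assert agg[0] == 1.0 and all(v[0] == 1.0 for v in per.values())

    def test_any_zero_component_kills_presence(self, params):
        for comps in [(0, 1, 1), (1, 0, 1), (1, 1, 0)]:
            _, agg = y4_presence(*self._arrays(*comps), params)
            assert agg[0] == 0.0

    def test_product(self, params):
        _, agg = y4_presence(*self._arrays(0.6, 0.5, 0.5), params)
        assert agg[0] == pytest.approx(0.15)

    def test_month_max_at_least_mean(self, params):
        rng = np.random.default_rng(0)
        Y1 = {s: rng.uniform(0, 1, 5) for s in SPECIES}
        Y2 = rng.uniform(0, 1, (12, 5))
        Y3 = rng.uniform(0, 1, (12, 5))
        _, mean_agg = y4_presence(Y1, Y2, Y3, ModelParams(month_aggregate="mean"))
        _, max_agg = y4_presence(Y1, Y2, Y3, ModelParams(month_aggregate="max"))
        assert (max_agg >= mean_agg - 1e-12).all()

    def test_product_bounded_by_components(self, params):
        rng = np.random.default_rng(1)
        Y1 = {s: rng.uniform(0, 1, 4) for s in SPECIES}
        Y2 = rng.uniform(0, 1, (12, 4))
        Y3 = rng.uniform(0, 1, (12, 4))
        per, _ = y4_presence(Y1, Y2, Y3, params)
        for (m, s), v in per.items():
            bound = np.minimum(Y1[s], np.minimum(Y2[m - 1], Y3[m - 1]))
            assert (v <= bound + 1e-12).all()


class TestY5Insecticide:
    @pytest.mark.parametrize("code,expected", [
        (11, 0.0),    # b=1 forest: no agricultural pressure
        (41, 0.5),    # b=3 paddy: (3-1)/4
        (423, 0.75),  # b=4 orchard: structural maximum
    ])
    def test_pure_class_scores(self, weights, params, code, expected):
        y5a, _ = y5_landuse(sp_frame({code: 1.0}), weights, 1.0, params)
        assert y5a[0] == pytest.approx(expected)

    def test_wetness_modulates_y5(self, weights, params):
        y5a, y5 = y5_landuse(sp_frame({41: 1.0}), weights, 0.5, params)
        assert y5[0] == pytest.approx(0.25)

    def test_shifting_area_to_higher_score_never_decreases(self, weights, params):
        fracs = np.linspace(0, 1, 11)
        vals = [y5_landuse(sp_frame({11: 1 - f, 423: f}), weights, 1.0,
                           params)[0][0] for f in fracs]
        assert (np.diff(vals) >= -1e-12).all()


class TestY6Itn:
    @pytest.mark.parametrize("D,expected", [
        (0.0, 0.0), (0.049, 0.0), (0.275, 0.5), (0.5, 1.0), (0.6, 1.0),
    ])
    def test_printed_formula(self, params, D, expected):
        assert y6_itn(D, params) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("b", [0.05, 0.5])
    def test_continuity(self, params, b):
        eps = 1e-9
        vals = [y6_itn(b + s * eps, params) for s in (-1, 0, 1)]
        assert max(vals) - min(vals) < 1e-8


class TestY7Combine:
    @pytest.mark.parametrize("y5,y6,expected", [
        (0.0, 0.0, 0.0),
        (0.5, 1.0, 0.55),
        (0.75, 1.0, 0.775),  # global structural maximum
    ])
    def test_convex_combination(self, params, y5, y6, expected):
        assert y7_combine(y5, y6, params) == pytest.approx(expected)


class TestY8Vulnerability:
    def test_zero_population(self, params):
        y8a, y8b, y8 = y8_population(0.0, 0.0, params)
        assert y8a == 0 and y8b == 0 and y8 == 0

    def test_arctan_half_points(self, params):
        y8a, y8b, y8 = y8_population(5000.0, 1000.0, params)
        assert y8a == pytest.approx(0.5)   # (2/pi) atan(1)
        assert y8b == pytest.approx(0.5)
        assert y8 == pytest.approx(0.5)    # (0.5 + 3*0.5)/4

    def test_saturating_below_one(self, params):
        y8a, y8b, _ = y8_population(1e9, 1e9, params)
        assert y8a < 1.0 and y8b < 1.0

    @given(st.floats(min_value=0, max_value=1e6),
           st.floats(min_value=1, max_value=1e5))
    def test_strictly_increasing_in_population(self, p, dp):
        prm = ModelParams()
        a0, b0, _ = y8_population(p, p / 2, prm)
        a1, b1, _ = y8_population(p + dp, (p + dp) / 2, prm)
        assert a1 > a0 and b1 > b0


class TestY9Protection:
    @pytest.mark.parametrize("D,expected", [
        (0.0, 1.0), (0.049, 1.0), (0.35, 0.5), (0.5, 0.25), (2.0, 0.25),
    ])
    def test_printed_formula(self, params, D, expected):
        assert y9_protection(D, params) == pytest.approx(expected, abs=1e-12)

    def test_floor_is_exact_at_saturation(self, params):
        assert y9_protection(0.5, params) == 0.25

    @pytest.mark.parametrize("b", [0.05, 0.5])
    def test_continuity(self, params, b):
        eps = 1e-9
        vals = [y9_protection(b + s * eps, params) for s in (-1, 0, 1)]
        assert max(vals) - min(vals) < 1e-8

    @given(st.floats(min_value=0, max_value=2),
           st.floats(min_value=0, max_value=1))
    def test_more_nets_never_raise_vulnerability(self, d, dd):
        prm = ModelParams()
        y8 = 0.7
        v0 = y10_vulnerability(y8, y9_protection(d, prm))
        v1 = y10_vulnerability(y8, y9_protection(d + dd, prm))
        assert v1 <= v0 + 1e-12


class TestY10:
    @pytest.mark.parametrize("y8,y9,expected", [
        (0.0, 1.0, 0.0), (1.0, 0.25, 0.25), (0.5, 0.5, 0.25),
    ])
    def test_product(self, y8, y9, expected):
        assert y10_vulnerability(y8, y9) == pytest.approx(expected)
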