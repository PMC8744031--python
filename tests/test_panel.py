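"""Panel analytics: ratio series, rolling correlations, quadrants, bounding curves."""

import numpy as np
import pandas as pd
import pytest

import lifeineq as li


@pytest.fixture(scope="module")
def panel_df(transition_panel):
    records, series = transition_panel
    return li.build_panel(records, series), series


class TestBuildPanel:
    def test_all_indices_present(self, transition_panel):
        records, _ = transition_panel
        df = li.build_panel(records[:6], 122.0)
        assert len(df) == 6
        for col in li.INDEX_NAMES + ("Gstar",):
            assert col in df.columns
            assert df[col].notna().all()

    def test_fixed_omega_gstar_rowwise(self, transition_panel):
        records, _ = transition_panel
        df = li.build_panel(records[:10], 122.0)
        expected = df["G"] * 122.0 / (122.0 - df["e0"])
        assert np.allclose(df["Gstar"], expected, atol=1e-12)

    def test_series_policy_year_lookup(self, panel_df):
        df, series = panel_df
        for _, row in df.head(20).iterrows():
            assert row["omega"] == series.omega_at(int(row["year"]))

    def test_omega_below_support_rejected(self, transition_panel):
        records, _ = transition_panel
        with pytest.raises(li.LifeTableError, match="omega policy"):
            li.build_panel(records[:3], 100.0)

    def test_points_below_maximal_curve(self, panel_df):
        df, _ = panel_df
        for name in ("AID", "G", "sigma", "CV"):
            bound = np.array(
                [li.max_index_value(name, e, w) for e, w in zip(df["e0"], df["omega"])]
            )
            assert np.all(df[name].to_numpy() <= bound * (1 + 1e-9))


class TestRecordSeries:
    def test_step_lookup(self):
        series = li.RecordLifespanSeries({1900: 110.0, 1950: 115.0})
        assert series.omega_at(1900) == 110.0
        assert series.omega_at(1949) == 110.0
        assert series.omega_at(1975) == 115.0

    def test_decreasing_rejected(self):
        with pytest.raises(li.LifeTableError, match="non-decreasing"):
            li.RecordLifespanSeries({1900: 115.0, 1950: 110.0})

    def test_year_before_start_rejected(self):
        series = li.RecordLifespanSeries({1900: 110.0})
        with pytest.raises(li.LifeTableError, match="precedes"):
            series.omega_at(1890)


class TestRatioSeries:
    def test_division(self):
        panel = pd.DataFrame(
            {"population": ["X"], "sex": ["female"], "year": [2019], "e0": [84.7]}
        )
        series = li.RecordLifespanSeries({1997: 122.45})
        out = li.ratio_series(panel, series)
        assert out["ratio"].iloc[0] == pytest.approx(84.7 / 122.45)
        assert out["ratio"].iloc[0] == pytest.approx(0.6917, abs=5e-4)

    def test_ratio_rises_through_transition(self, panel_df):
        df, series = panel_df
        out = li.ratio_series(df[df["population"] == "POP00"], series)
        assert out["ratio"].iloc[-1] > out["ratio"].iloc[0]


class TestRollingCorrelation:
    def test_collinear_is_minus_one(self):
        years = np.repeat(np.arange(2000, 2005), 4)
        e0 = np.random.default_rng(1).uniform(70, 85, size=years.size)
        panel = pd.DataFrame({
            "population": ["P"] * years.size, "sex": ["f"] * years.size,
            "year": years, "e0": e0, "G": 1.0 - 0.01 * e0,
        })
        assert li.rolling_correlation(panel, "G", 2002) == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(99)
        n = 4000
        panel = pd.DataFrame({
            "population": ["P"] * n, "sex": ["f"] * n,
            "year": np.repeat(2000, n), "e0": rng.uniform(60, 85, n),
            "G": rng.uniform(0.1, 0.3, n),
        })
        r = li.rolling_correlation(panel, "G", 2000, window=1)
        assert abs(r) < 0.05

    def test_constant_index_absent(self):
        panel = pd.DataFrame({
            "population": ["P"] * 5, "sex": ["f"] * 5, "year": np.arange(2000, 2005),
            "e0": [70.0, 71, 72, 73, 74], "G": [0.2] * 5,
        })
        assert li.rolling_correlation(panel, "G", 2002) is None

    def test_too_few_points_absent(self):
        panel = pd.DataFrame({
            "population": ["P"], "sex": ["f"], "year": [2000], "e0": [70.0], "G": [0.2],
        })
        assert li.rolling_correlation(panel, "G", 2000) is None

    def test_transition_panel_strongly_negative(self, panel_df):
        df, _ = panel_df
        series = li.rolling_correlation_series(df, "G")
        assert series.dropna().max() < -0.5


class TestQuadrants:
    def test_monotone_panel_all_desirable(self, panel_df):
        df, _ = panel_df
        out = li.joint_change_quadrants(df, "G", from_year=0)
        assert out.desirable == pytest.approx(1.0)
        assert sum(out.shares.values()) == pytest.approx(1.0)

    def test_tie_bookkeeping(self):
        panel = pd.DataFrame({
            "population": ["P"] * 3, "sex": ["f"] * 3, "year": [2000, 2001, 2002],
            "e0": [70.0, 71.0, 71.0], "G": [0.3, 0.2, 0.1],
        })
        out = li.joint_change_quadrants(panel, "G", from_year=1990)
        assert out.n_ties == 1
        assert out.n_classified == 1

    def test_no_pairs_rejected(self, panel_df):
        df, _ = panel_df
        with pytest.raises(li.LifeTableError, match="no consecutive"):
            li.joint_change_quadrants(df, "G", from_year=3000)

    def test_ordering_invariance(self, panel_df):
        df, _ = panel_df
        shuffled = df.sample(frac=1.0, random_state=7)
        a = li.joint_change_quadrants(df, "Gstar", from_year=0)
        b = li.joint_change_quadrants(shuffled, "Gstar", from_year=0)
        assert a.shares == b.shares


class TestMaxInequalityCurve:
    def test_aid_parabola_peaks_at_half_omega(self):
        grid = np.linspace(1.0, 121.0, 241)
        curve = li.max_inequality_curve("AID", 122.0, grid)
        assert grid[int(np.argmax(curve))] == pytest.approx(61.0)

    def test_gini_line_endpoints(self):
        curve = li.max_inequality_curve("G", 122.0, [1e-9, 61.0, 122.0 - 1e-9])
        assert curve[0] == pytest.approx(1.0, abs=1e-9)
        assert curve[1] == pytest.approx(0.5)
        assert curve[2] == pytest.approx(0.0, abs=1e-9)
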