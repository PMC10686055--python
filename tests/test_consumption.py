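"""AUC consumption scoring: normalization, filters, bands, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pepferm as pf
from conftest import make_series


def riemann_auc_fraction(times, abundance, horizon=72.0, cells_per_interval=2000):
    """Independent midpoint-rule oracle on a dense grid.

    The midpoint rule is exact on each linear piece, so subdividing the
    observed intervals gives the piecewise-linear area without calling
    any trapezoid routine.
    """
    t = np.asarray(times, float)
    a = np.asarray(abundance, float)
    if t[-1] < horizon:
        raise ValueError("series too short")
    area = 0.0
    for t0, t1, a0, a1 in zip(t, t[1:], a, a[1:]):
        lo, hi = t0, min(t1, horizon)
        if hi <= lo:
            break
        edges = np.linspace(lo, hi, cells_per_interval + 1)
        mids = (edges[:-1] + edges[1:]) / 2
        vals = a0 + (a1 - a0) * (mids - t0) / (t1 - t0)
        area += float(np.sum(vals) * (edges[1] - edges[0]))
    return area / (100.0 * horizon)


class TestNormalize:
    def test_proportional_scaling(self):
        s = pf.normalize_series([1000, 500, 0], [0, 36, 72])
        assert np.allclose(s.abundance, [100, 50, 0])
        assert s.raw_max_ratio == 1.0

    def test_cap_retains_raw_max_ratio(self):
        s = pf.normalize_series([1000, 1300, 900], [0, 36, 72])
        assert np.allclose(s.abundance, [100, 100, 90])
        assert s.raw_max_ratio == pytest.approx(1.3)

    def test_constant_raw_stays_at_100(self):
        s = pf.normalize_series([42.0] * 4, [0, 24, 48, 72])
        assert np.allclose(s.abundance, 100.0)

    @pytest.mark.parametrize("raw0", [0.0, -10.0])
    def test_nonpositive_start_rejected(self, raw0):
        with pytest.raises(ValueError):
            pf.normalize_series([raw0, 50], [0, 72])

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            pf.normalize_series([100, 90, 80], [0, 48, 24])


class TestClassifyStatus:
    def test_over_20_percent_increase_excluded(self):
        s = make_series([0, 36, 72], [100, 100, 100], raw_max_ratio=1.25)
        assert pf.classify_status(s) == "excluded"

    def test_exactly_20_percent_increase_not_excluded(self):
        s = make_series([0, 36, 72], [100, 100, 100], raw_max_ratio=1.20)
        assert pf.classify_status(s) == "unchanged"

    def test_exactly_20_percent_reduction_is_consumption(self):
        s = make_series([0, 36, 72], [100, 80.0, 100])
        assert pf.classify_status(s) == "consumed"

    def test_neither_rule_fires(self):
        s = make_series([0, 36, 72], [100, 85, 100], raw_max_ratio=1.0)
        assert pf.classify_status(s) == "unchanged"


class TestAucFraction:
    def test_control_equals_one(self):
        s = make_series([0, 72], [100, 100])
        assert pf.auc_fraction(s) == pytest.approx(1.0)

    def test_linear_decay_is_half(self):
        s = make_series([0, 72], [100, 0])
        assert pf.auc_fraction(s) == pytest.approx(0.5)

    def test_single_trapezoid_drop(self):
        times = np.arange(0, 73, 6)
        ab = np.zeros_like(times, dtype=float)
        ab[0] = 100.0
        s = make_series(times, ab)
        assert pf.auc_fraction(s) == pytest.approx(300.0 / 7200.0)

    def test_samples_beyond_horizon_ignored(self):
        s1 = make_series([0, 72], [100, 50])
        s2 = make_series([0, 72, 288], [100, 50, 0])
        assert pf.auc_fraction(s1) == pf.auc_fraction(s2)

    def test_interpolates_when_no_sample_at_72(self):
        # linear 100 -> 0 over [0, 96]; value at 72 is 25
        s = make_series([0, 96], [100, 0])
        assert pf.auc_fraction(s) == pytest.approx((100 + 25) / 2 * 72 / 7200)

    def test_short_series_rejected(self):
        s = make_series([0, 48], [100, 50])
        with pytest.raises(ValueError):
            pf.auc_fraction(s)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 100), min_size=2, max_size=12))
    def test_agrees_with_riemann_oracle(self, values):
        values = [100.0] + values
        times = np.linspace(0, 84, len(values))
        s = make_series(times, values)
        assert pf.auc_fraction(s) == pytest.approx(
            riemann_auc_fraction(times, values), rel=1e-9, abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(0, 100), min_size=2, max_size=8))
    def test_grid_refinement_invariance(self, values):
        values = [100.0] + values
        times = np.linspace(0, 72, len(values))
        coarse = make_series(times, values)
        fine_t = np.sort(np.unique(np.concatenate(
            [times, (times[:-1] + times[1:]) / 2])))
        fine = make_series(fine_t, np.interp(fine_t, times, values))
        assert pf.auc_fraction(fine) == pytest.approx(
            pf.auc_fraction(coarse), rel=1e-12, abs=1e-12)

    def test_capped_series_never_exceeds_control(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            vals = np.concatenate([[100.0], rng.uniform(0, 100, 11)])
            s = make_series(np.linspace(0, 72, 12), vals)
            assert pf.auc_fraction(s) <= 1.0 + 1e-12


class TestAssignLevel:
    @pytest.mark.parametrize(
        "fraction, level",
        [(1.0, 0), (0.80, 0), (0.799, 1), (0.60, 1), (0.59, 2), (0.5, 2),
         (0.40, 2), (0.399, 3), (0.20, 3), (0.199, 4), (0.0, 4)],
    )
    def test_band_edges(self, fraction, level):
        assert pf.assign_level(fraction) == level

    @pytest.mark.parametrize("fraction", [-0.1, 1.2])
    def test_out_of_range_rejected(self, fraction):
        with pytest.raises(ValueError):
            pf.assign_level(fraction)

    def test_non_increasing_step_function(self):
        fractions = np.linspace(0, 1, 1001)
        levels = [pf.assign_level(f) for f in fractions]
        assert all(b <= a for a, b in zip(levels, levels[1:]))
        assert set(levels) == {0, 1, 2, 3, 4}


class TestScoreTable:
    @staticmethod
    def _long_table():
        rows = []
        for aid, vals in [("flat", [100, 100, 100, 100]),
                          ("gone", [100, 0, 0, 0]),
                          ("riser", [100, 130, 100, 100])]:
            for t, v in zip([0, 6, 36, 72], vals):
                rows.append(dict(strain="s1", medium="P200", analyte_id=aid,
                                 kind="peptide", length=2, time_h=t,
                                 abundance_pct=v))
        return pd.DataFrame(rows)

    def test_statuses_and_levels(self):
        res = pf.score_table(self._long_table())
        res = res.set_index("analyte_id")
        assert res.loc["flat", "status"] == "unchanged"
        assert res.loc["flat", "level"] == 0
        assert res.loc["gone", "status"] == "consumed"
        assert res.loc["gone", "level"] == 4
        assert res.loc["riser", "status"] == "excluded"
        assert pd.isna(res.loc["riser", "level"])

    def test_missing_length_rejected(self):
        bad = self._long_table()
        bad.loc[0, "length"] = np.nan
        with pytest.raises(ValueError):
            pf.score_table(bad)

    def test_matrix_summary_counts(self):
        results, summary = pf.consumption_matrix(self._long_table())
        # excluded analyte does not enter the per-length summary
        row = summary.iloc[0]
        assert row["n_analytes"] == 2
        assert row["n_level_0"] == 1 and row["n_level_4"] == 1


class TestEndToEnd:
    def test_noiseless_wild_type_pattern(self, media):
        cfg = pf.scenario("59A", media["P200"], noise_sigma=0.0, seed=0)
        series = pf.simulate_peptide_series(cfg)
        for s in series:
            if s.kind != "peptide":
                continue
            res = pf.score_series(s)
            if s.analyte_id == "pep2_PP":
                assert res.level == 0
            elif s.length <= 4:
                assert res.level == 4, (s.analyte_id, res.auc_fraction)
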