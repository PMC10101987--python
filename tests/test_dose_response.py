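"""4PL fitting and the DSS score family."""

import numpy as np
import pandas as pd
import pytest

from cllscreen import (
    ConcentrationSeries,
    DSSConfig,
    LibraryEntry,
    dss,
    fit_4pl,
    logistic4,
    score_screen,
)
from cllscreen.doseresponse import CurveFit4PL

MAX_DEFAULT_SCORE = 100.0 * 80.0 / 90.0  # cap rule ceiling at t=10, f=10


def _interp_crossing(x, y, level):
    """First grid crossing of y >= level, linearly interpolated."""
    idx = np.nonzero(y >= level)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    if i == 0 or y[i] == y[i - 1]:
        return x[i]
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return x[i - 1] + frac * (x[i] - x[i - 1])


def trapezoid_score(fit, series, cfg, n=10_001):
    """Brute-force oracle: dense-grid trapezoid integration of the capped,
    thresholded inhibition, assembled into the configured metric."""
    x = np.linspace(series.x_lo, series.x_hi, n)
    y = np.clip(100.0 - fit.viability(x), 0.0, 100.0)
    t, c = cfg.t, cfg.cap
    x1 = _interp_crossing(x, y, t)
    if x1 is None:
        return 0.0
    x2 = _interp_crossing(x, y, c)
    if x2 is None:
        x2 = series.x_hi
    g = np.clip(np.minimum(y, c) - t, 0.0, None)
    area = np.trapezoid(g, x)
    if cfg.tail_rule == "truncate":
        area -= (c - t) * (series.x_hi - x2)
    width = series.x_hi - series.x_lo
    dss1 = 100.0 * area / ((100.0 - t) * width)
    wf = (series.x_hi - x1) / width
    if cfg.metric == "dss1":
        return dss1
    if cfg.metric == "mdss3":
        return dss1 * wf
    d = min(y.max(), 100.0)
    if d <= 10.0:
        return 0.0
    dss2 = dss1 / np.log10(d)
    return dss2 if cfg.metric == "dss2" else dss2 * wf


def random_fits(n, seed=0):
    rng = np.random.default_rng(seed)
    return [
        CurveFit4PL(
            top=rng.uniform(90, 110), bottom=rng.uniform(-5, 20),
            log_ec50=rng.uniform(-1.5, 5.5), slope=rng.uniform(0.3, 5.0),
            rmse=0.0, converged=True,
        )
        for _ in range(n)
    ]


class TestFit4PL:
    def test_exact_recovery_from_noiseless_curve(self, series):
        v = logistic4(series.log10_values, 100, 0, 2, 1)
        assert np.allclose(v, [99.0099, 90.909, 50.0, 9.0909, 0.990], atol=1e-3)
        fit = fit_4pl(series, v)
        assert fit.converged
        assert abs(fit.top - 100) < 1e-6
        assert abs(fit.bottom) < 1e-6
        assert abs(fit.log_ec50 - 2) < 1e-6
        assert abs(fit.slope - 1) < 1e-6

    def test_flat_full_viability(self, series):
        fit = fit_4pl(series, [100.0] * 5)
        assert fit.is_flat and fit.converged and fit.rmse == 0.0
        assert dss(fit, series).score == 0.0

    def test_too_few_points(self):
        s = ConcentrationSeries((1.0, 10.0, 100.0))
        with pytest.raises(ValueError, match="at least 4"):
            fit_4pl(s, [100, 50, 0])

    def test_non_finite_viability_rejected(self, series):
        with pytest.raises(ValueError, match="finite"):
            fit_4pl(series, [100, np.nan, 50, 10, 0])

    def test_noisy_recovery_median_within_quarter_log(self, series):
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(50):
            true_m = rng.uniform(0.5, 3.5)
            v = logistic4(series.log10_values, 100, 0, true_m, 1.2)
            v = v * rng.lognormal(0, 0.05, size=5)
            fit = fit_4pl(series, v)
            errs.append(abs(fit.log_ec50 - true_m))
        assert np.median(errs) <= 0.25


class TestDSS:
    def test_complete_kill_at_min_hits_cap(self, series):
        fit = CurveFit4PL(0.0, 0.0, 2.0, 1e-3, 0.0, True)
        res = dss(fit, series)
        assert res.score == pytest.approx(MAX_DEFAULT_SCORE, abs=1e-9)
        assert "complete_kill_at_min" in res.flags
        assert res.x1 == series.x_lo

    def test_inactive_curve_scores_zero(self, series):
        fit = CurveFit4PL(100.0, 100.0, 2.0, 1e-3, 0.0, True)
        res = dss(fit, series)
        assert res.score == 0.0 and res.inactive and res.x1 is None

    def test_midwindow_curve_matches_oracle(self, series):
        fit = CurveFit4PL(100.0, 0.0, 2.0, 1.0, 0.0, True)
        cfg = DSSConfig()
        assert dss(fit, series, cfg).score == pytest.approx(
            trapezoid_score(fit, series, cfg), abs=1e-4
        )

    @pytest.mark.parametrize("metric", ["dss1", "dss2", "dss3", "mdss3"])
    @pytest.mark.parametrize("tail_rule", ["cap", "truncate"])
    def test_oracle_equivalence_over_random_draws(self, series, metric, tail_rule):
        cfg = DSSConfig(metric=metric, tail_rule=tail_rule)
        for fit in random_fits(25, seed=hash((metric, tail_rule)) % 2**31):
            assert dss(fit, series, cfg).score == pytest.approx(
                trapezoid_score(fit, series, cfg), abs=1e-4
            ), (fit, metric, tail_rule)

    def test_score_range_under_cap_rule(self, series):
        for fit in random_fits(100, seed=3):
            s = dss(fit, series).score
            assert 0.0 <= s <= MAX_DEFAULT_SCORE + 1e-9

    def test_monotone_in_potency(self, series):
        scores = [
            dss(CurveFit4PL(100, 0, m, 1.0, 0, True), series).score
            for m in np.linspace(5, -2, 30)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_width_factor_vanishes_at_window_edge(self, series):
        # threshold reached only at the very top dose -> mDSS3 ~ 0
        fit = CurveFit4PL(100, 0, 4.43, 2.0, 0, True)
        res = dss(fit, series)
        y_hi = float(fit.inhibition(series.x_hi))
        assert 10 <= y_hi < 15
        assert res.score < 1.0

    def test_variant_identities(self, series):
        width = series.x_hi - series.x_lo
        for fit in random_fits(30, seed=7):
            parts = {
                m: dss(fit, series, DSSConfig(metric=m))
                for m in ("dss1", "dss2", "dss3", "mdss3")
            }
            if parts["dss1"].inactive:
                continue
            wf = (series.x_hi - parts["dss1"].x1) / width
            assert parts["mdss3"].score == pytest.approx(
                parts["dss1"].score * wf, abs=1e-9
            )
            assert parts["dss3"].score == pytest.approx(
                parts["dss2"].score * wf, abs=1e-9
            )

    def test_truncate_never_exceeds_cap(self, series):
        for fit in random_fits(30, seed=9):
            s_cap = dss(fit, series, DSSConfig(tail_rule="cap")).score
            s_tr = dss(fit, series, DSSConfig(tail_rule="truncate")).score
            assert s_tr <= s_cap + 1e-9

    def test_degenerate_window_rejected(self):
        from types import SimpleNamespace

        fit = CurveFit4PL(100, 0, 0.5, 1, 0, True)
        collapsed = SimpleNamespace(x_lo=2.0, x_hi=2.0)
        with pytest.raises(ValueError, match="degenerate"):
            dss(fit, collapsed)

    def test_poor_fit_flag_on_high_rmse(self, series):
        fit = CurveFit4PL(100, 0, 2, 1, rmse=20.0, converged=True)
        assert "poor_fit" in dss(fit, series).flags

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DSSConfig(t=95, f=10)
        with pytest.raises(ValueError):
            DSSConfig(tail_rule="clip")
        with pytest.raises(ValueError):
            DSSConfig(metric="dss9")


class TestScoreScreen:
    def make_viab(self, series, curves):
        rows = []
        for entry_id, params in curves.items():
            v = logistic4(series.log10_values, *params)
            for ci, vi in enumerate(v):
                rows.append({"plate_id": "p", "entry_id": entry_id,
                             "conc_index": ci, "conc_nM": series.values_nM[ci],
                             "viability_percent": vi, "n_wells": 1, "wells": ""})
        return pd.DataFrame(rows)

    def make_library(self, series, ids):
        return [LibraryEntry(i, "single", (i,), series) for i in ids]

    def test_ranking_follows_potency(self, series):
        curves = {f"d{i}": (100, 0, m, 1.0) for i, m in enumerate([0.5, 1.5, 2.5, 3.5])}
        viab = self.make_viab(series, curves)
        out = score_screen(viab, self.make_library(series, curves))
        assert list(out["entry_id"]) == ["d0", "d1", "d2", "d3"]

    def test_identical_curves_identical_scores(self, series):
        curves = {"a": (100, 0, 2, 1.0), "b": (100, 0, 2, 1.0)}
        out = score_screen(self.make_viab(series, curves),
                           self.make_library(series, curves))
        assert out["score"].iloc[0] == out["score"].iloc[1]
        # deterministic tie-break: lexicographic by entry_id
        assert list(out["entry_id"]) == ["a", "b"]

    def test_inactive_entry_present_with_zero(self, series):
        curves = {"dead": (100, 0, 1, 1.0), "none": (100, 100, 2, 1.0)}
        out = score_screen(self.make_viab(series, curves),
                           self.make_library(series, curves))
        row = out[out.entry_id == "none"].iloc[0]
        assert row["score"] == 0.0 and "inactive" in row["flags"]

    def test_incomplete_series_skipped_with_warning(self, series, caplog):
        curves = {"ok": (100, 0, 2, 1.0)}
        viab = self.make_viab(series, curves)
        partial = self.make_viab(series, {"partial": (100, 0, 2, 1.0)}).iloc[:3]
        viab = pd.concat([viab, partial], ignore_index=True)
        lib = self.make_library(series, ["ok", "partial"])
        with caplog.at_level("WARNING"):
            out = score_screen(viab, lib)
        assert list(out["entry_id"]) == ["ok"]
        assert "partial" in caplog.text
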