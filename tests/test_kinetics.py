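import numpy as np
import pandas as pd
import pytest

import mitodwell as md
from mitodwell.kinetics import (
    CorrectionInvalidError,
    InsufficientDataError,
    KineticSummary,
    build_survival,
    correct_photobleach,
    extract_dwells,
    fit_biexponential,
    fit_biexponential_mle,
    summarize_conditions,
    time_to_fraction,
)
from mitodwell.tracking import Track


def make_track(tid, frames, x=1.0, y=1.0):
    return Track(id=tid, points=pd.DataFrame(
        {"frame": list(frames), "x_um": x, "y_um": y, "gap": False}))


class TestExtractDwells:
    def test_duration_convention(self):
        recs = extract_dwells([make_track(0, range(10, 31))], 0.2, 1000)
        assert len(recs) == 1
        assert recs[0].duration == pytest.approx(4.0)  # (30 - 10) * 0.2
        assert recs[0].n_frames == 21
        assert not recs[0].censored

    def test_short_tracks_excluded(self):
        recs = extract_dwells([make_track(0, [3, 4])], 0.2, 1000, min_frames=3)
        assert recs == []

    def test_final_frame_track_is_censored(self):
        recs = extract_dwells([make_track(0, range(995, 1000))], 0.2, 1000)
        assert recs[0].censored
        with pytest.raises(InsufficientDataError):
            build_survival(recs)  # censored dwells never enter the survival curve

    def test_min_frames_validation(self):
        with pytest.raises(ValueError):
            extract_dwells([], 0.2, 1000, min_frames=1)


class TestBuildSurvival:
    def test_hand_counted_curve(self):
        curve = build_survival([0.4, 0.4, 0.8, 1.2], min_dwells=1)
        np.testing.assert_allclose(curve.times, [0.4, 0.8, 1.2])
        np.testing.assert_allclose(curve.survival, [1.0, 0.5, 0.25])
        assert curve.n == 4

    def test_identical_dwells_single_step(self):
        curve = build_survival([0.6] * 20)
        assert curve.times.tolist() == [0.6]
        assert curve.survival.tolist() == [1.0]

    def test_starts_at_one_and_non_increasing(self):
        rng = np.random.default_rng(0)
        curve = build_survival(rng.exponential(5.0, 500))
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 0)

    def test_glivenko_cantelli_against_exponential(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(1 / 0.2, 100_000)
        curve = build_survival(x)
        t0 = curve.times[0]
        model = np.exp(-0.2 * (curve.times - t0))
        assert np.max(np.abs(curve.survival - model)) < 0.01

    def test_too_few_dwells_error_names_count(self):
        with pytest.raises(InsufficientDataError, match="got 3"):
            build_survival([1.0, 2.0, 3.0])


class TestFitBiexponential:
    def test_two_component_recovery(self):
        cfg = md.KineticConfig(frac_fast=0.5, k_fast=1.0, k_slow=0.1, k_bleach=0.0, seed=7)
        d = md.simulate_dwell_times(cfg, 100_000, discretize=False)
        fit = fit_biexponential(build_survival(d["duration"].to_numpy()))
        assert not fit.collapsed
        assert fit.f == pytest.approx(0.5, rel=0.05)
        assert fit.k_fast == pytest.approx(1.0, rel=0.05)
        assert fit.k_slow == pytest.approx(0.1, rel=0.05)

    def test_single_exponential_collapses(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(1 / 0.2, 100_000)
        fit = fit_biexponential(build_survival(x))
        assert fit.collapsed
        assert fit.k_slow == pytest.approx(0.2, rel=0.03)
        assert fit.k_fast == fit.k_slow

    def test_rate_recovery_survives_discretization(self):
        """Frame discretization and the minimum-length cut shift the apparent
        fast fraction but leave both rates intact (memorylessness)."""
        cfg = md.KineticConfig(frac_fast=0.4, k_fast=1.0, k_slow=0.1, k_bleach=0.0, seed=11)
        d = md.simulate_dwell_times(cfg, 100_000)
        fit = fit_biexponential(build_survival(d["duration"].to_numpy()))
        assert fit.k_slow == pytest.approx(0.1, rel=0.05)
        assert fit.k_fast == pytest.approx(1.0, rel=0.10)

    def test_time_unit_rescaling_invariance(self):
        cfg = md.KineticConfig(frac_fast=0.5, k_fast=1.0, k_slow=0.1, k_bleach=0.0, seed=9)
        d = md.simulate_dwell_times(cfg, 20_000, discretize=False)["duration"].to_numpy()
        fit_s = fit_biexponential(build_survival(d))
        fit_m = fit_biexponential(build_survival(d * 60.0))  # seconds -> minutes grid
        assert fit_m.k_slow * 60.0 == pytest.approx(fit_s.k_slow, rel=1e-3)
        assert fit_m.k_fast * 60.0 == pytest.approx(fit_s.k_fast, rel=1e-3)
        assert fit_m.f == pytest.approx(fit_s.f, abs=1e-3)

    def test_mle_cross_check_agrees_with_least_squares(self):
        cfg = md.KineticConfig(frac_fast=0.5, k_fast=1.0, k_slow=0.1, k_bleach=0.0, seed=21)
        d = md.simulate_dwell_times(cfg, 50_000, discretize=False)["duration"].to_numpy()
        ls = fit_biexponential(build_survival(d))
        ml = fit_biexponential_mle(d, t0=ls.t0)
        assert ml.k_slow == pytest.approx(ls.k_slow, rel=0.05)
        assert ml.k_fast == pytest.approx(ls.k_fast, rel=0.10)
        assert ml.f == pytest.approx(ls.f, abs=0.05)


class TestTimeToFraction:
    def test_collapsed_closed_form(self):
        fit = md.BiExpFit(f=0.0, k_fast=0.2, k_slow=0.2, t0=0.0, rss=0.0,
                          converged=True, collapsed=True)
        assert time_to_fraction(fit, 0.01) == pytest.approx(np.log(100) / 0.2, abs=1e-4)

    def test_p_equal_one_returns_origin(self):
        fit = md.BiExpFit(f=0.3, k_fast=1.0, k_slow=0.1, t0=0.4, rss=0.0,
                          converged=True, collapsed=False)
        assert time_to_fraction(fit, 1.0) == 0.4

    def test_bisection_matches_dense_grid_root(self):
        fit = md.BiExpFit(f=0.5, k_fast=1.0, k_slow=0.1, t0=0.0, rss=0.0,
                          converged=True, collapsed=False)
        t = time_to_fraction(fit, 0.01)
        grid = np.linspace(0, 100, 2_000_001)  # 5e-5 s spacing
        t_grid = grid[np.argmin(np.abs(fit.survival(grid) - 0.01))]
        assert t == pytest.approx(t_grid, abs=1e-4)

    def test_strictly_decreasing_in_p_and_rates(self):
        fit = md.BiExpFit(f=0.5, k_fast=1.0, k_slow=0.1, t0=0.0, rss=0.0,
                          converged=True, collapsed=False)
        ps = [0.5, 0.1, 0.05, 0.01]
        ts = [time_to_fraction(fit, p) for p in ps]
        assert all(a < b for a, b in zip(ts, ts[1:]))
        faster = md.BiExpFit(f=0.5, k_fast=2.0, k_slow=0.2, t0=0.0, rss=0.0,
                             converged=True, collapsed=False)
        assert time_to_fraction(faster, 0.01) < time_to_fraction(fit, 0.01)


class TestPhotobleachCorrection:
    def test_hand_arithmetic(self):
        k, r = correct_photobleach(0.20, 0.05)
        assert k == pytest.approx(0.15)
        assert r == pytest.approx(1 / 0.15)
        assert r * k == pytest.approx(1.0)

    def test_no_bleaching_control(self):
        k, r = correct_photobleach(0.25, 0.0)
        assert r == pytest.approx(4.0)

    def test_invalid_correction_raises(self):
        with pytest.raises(CorrectionInvalidError):
            correct_photobleach(0.04, 0.05)


def make_summary(rep, cond, residence, t1=None):
    k = 1.0 / residence
    return KineticSummary(k_apparent=k + 0.05, k_h2b=0.05, k_corrected=k,
                          residence_time=residence, t_1pct=t1 or residence * 4.6,
                          replicate_id=rep, condition=cond)


class TestSummarizeConditions:
    def test_hand_computed_ratio_and_sem(self):
        summaries = [make_summary(r, "interphase", v) for r, v in
                     zip("abc", [20.0, 18.0, 19.0])]
        summaries += [make_summary(r, "mitosis", v) for r, v in zip("abc", [8.0, 9.0, 7.0])]
        comp = summarize_conditions(summaries)
        assert comp.ratio_residence == pytest.approx(8.0 / 19.0)
        tbl = comp.table["residence_time"]
        assert tbl.loc["interphase", "mean"] == pytest.approx(19.0)
        assert tbl.loc["interphase", "sem"] == pytest.approx(np.std([20, 18, 19], ddof=1) / np.sqrt(3))
        assert comp.p_value < 0.01
        assert len(comp.paired_ratios) == 3

    def test_identical_conditions_give_ratio_one_and_high_p(self):
        summaries = [make_summary(r, c, 10.0) for r in "abc"
                     for c in ("interphase", "mitosis")]
        comp = summarize_conditions(summaries)
        assert comp.ratio_residence == pytest.approx(1.0)
        assert comp.p_value > 0.99

    def test_single_replicate_reports_means_without_test(self):
        comp = summarize_conditions([make_summary("a", "interphase", 20.0),
                                     make_summary("a", "mitosis", 8.0)])
        assert comp.ratio_residence == pytest.approx(0.4)
        assert comp.p_value is None

    def test_full_pipeline_ratio_recovery(self):
        """Simulated interphase/mitosis with known corrected rates recovers
        their residence-time ratio within 10%."""
        kb = 0.05
        k_i, k_m = 0.06, 0.15
        summaries = []
        for rep in ("r1", "r2"):
            seed = {"r1": 100, "r2": 200}[rep]
            h2b = md.simulate_dwell_times(
                md.KineticConfig(frac_fast=0.3, k_slow=1e-4, k_bleach=kb, seed=seed), 5000)
            h2b_fit = fit_biexponential(build_survival(h2b["duration"].to_numpy()))
            for cond, k in (("interphase", k_i), ("mitosis", k_m)):
                d = md.simulate_dwell_times(
                    md.KineticConfig(frac_fast=0.3, k_fast=1.0, k_slow=k,
                                     k_bleach=kb,
                                     seed=seed + {"interphase": 1, "mitosis": 2}[cond]), 5000)
                summaries.append(md.summarize_replicate(
                    d["duration"].to_numpy(), h2b_fit, replicate_id=rep, condition=cond))
        comp = summarize_conditions(summaries)
        assert comp.ratio_residence == pytest.approx(k_i / k_m, rel=0.10)
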