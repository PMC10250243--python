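import numpy as np
import pandas as pd
import pytest

import mitodwell as md
from mitodwell.synthetic_data import InvalidConfigError, survival_model


class TestDwellTimes:
    @pytest.mark.parametrize(
        "k_bleach,expected_mean",
        [(0.0, 10.0), (0.1, 5.0)],  # min of Exp(0.1) and Exp(k_bleach)
    )
    def test_mean_dwell_matches_exponential_oracle(self, k_bleach, expected_mean):
        cfg = md.KineticConfig(frac_fast=0.0, k_fast=1.0, k_slow=0.1,
                               k_bleach=k_bleach, seed=1)
        d = md.simulate_dwell_times(cfg, 100_000)
        assert d["duration"].mean() == pytest.approx(expected_mean, rel=0.02)

    def test_seeded_determinism(self):
        cfg = md.KineticConfig(seed=9)
        a = md.simulate_dwell_times(cfg, 50)
        b = md.simulate_dwell_times(cfg, 50)
        pd.testing.assert_frame_equal(a, b)

    def test_continuous_mode_keeps_all_molecules(self):
        cfg = md.KineticConfig(frac_fast=0.5, seed=2)
        d = md.simulate_dwell_times(cfg, 1000, discretize=False)
        assert len(d) == 1000
        assert (d["duration"] > 0).all()

    def test_discretized_durations_are_frame_multiples(self):
        cfg = md.KineticConfig(seed=4)
        d = md.simulate_dwell_times(cfg, 2000)
        np.testing.assert_allclose(
            d["duration"], d["n_intervals"] * cfg.frame_interval, rtol=1e-12
        )
        assert (d["n_intervals"] >= 1).all()

    def test_empirical_survival_converges_to_mixture_model(self):
        cfg = md.KineticConfig(frac_fast=0.4, k_fast=0.8, k_slow=0.08,
                               k_bleach=0.05, seed=6)
        d = md.simulate_dwell_times(cfg, 200_000, discretize=False)
        x = np.sort(d["duration"].to_numpy())
        grid = np.arange(0.2, 20.0, 0.2)
        s_emp = 1.0 - np.searchsorted(x, grid, side="left") / len(x)
        assert np.max(np.abs(s_emp - survival_model(grid, cfg))) < 0.01

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidConfigError):
            md.KineticConfig(frac_fast=0.5, k_fast=0.01, k_slow=0.1)
        with pytest.raises(InvalidConfigError):
            md.KineticConfig(k_slow=0.0)
        with pytest.raises(InvalidConfigError):
            md.KineticConfig(frame_interval=0.0)
        with pytest.raises(ValueError):
            md.simulate_dwell_times(md.KineticConfig(), 0)


class TestMovie:
    def test_empty_movie_is_pure_noise(self):
        kin = md.KineticConfig(n_molecules=0, n_frames=5, seed=0)
        mov = md.MovieConfig(width=64, height=64, kinetic=kin)
        stack, truth = md.simulate_movie(mov)
        assert len(truth.intervals) == 0
        assert len(truth.renderings) == 0
        # pure Gaussian background: close to the configured levels
        assert stack.mean() == pytest.approx(mov.background_mean, rel=0.01)
        assert stack.std() == pytest.approx(mov.background_sd, rel=0.05)

    def test_renderings_agree_with_intervals_frame_by_frame(self, small_movie):
        _, truth, _ = small_movie
        bound = truth.renderings[truth.renderings["state"] == "bound"]
        for _, iv in truth.intervals.iterrows():
            frames = set(bound.loc[bound["molecule_id"] == iv["molecule_id"], "frame"])
            assert frames == set(range(iv["start_frame"], iv["end_frame"] + 1))

    def test_rendered_spots_visible_in_stack(self):
        # immobile, never-bleaching molecules present from their start frame on
        kin = md.KineticConfig(frac_fast=0.0, k_slow=1e-6, k_bleach=0.0,
                               n_frames=10, n_molecules=5, seed=8)
        mov = md.MovieConfig(width=96, height=96, spot_amplitude=200.0, kinetic=kin)
        stack, truth = md.simulate_movie(mov)
        for _, r in truth.renderings.iterrows():
            y, x = int(round(r["y_px"])), int(round(r["x_px"]))
            assert stack[int(r["frame"]), y, x] > mov.background_mean + 5 * mov.background_sd

    def test_censoring_flag_set_at_movie_end(self):
        kin = md.KineticConfig(frac_fast=0.0, k_slow=1e-6, k_bleach=0.0,
                               n_frames=20, n_molecules=10, seed=1)
        _, truth = md.simulate_movie(md.MovieConfig(width=64, height=64, kinetic=kin))
        # with effectively infinite lifetimes, every molecule survives to the end
        assert truth.intervals["censored"].all()
        assert (truth.intervals["end_frame"] == 19).all()

    def test_seeded_determinism(self):
        kin = md.KineticConfig(n_frames=5, n_molecules=5, seed=12)
        mov = md.MovieConfig(width=48, height=48, kinetic=kin)
        s1, t1 = md.simulate_movie(mov)
        s2, t2 = md.simulate_movie(mov)
        np.testing.assert_array_equal(s1, s2)
        pd.testing.assert_frame_equal(t1.renderings, t2.renderings)


class TestCellImage:
    @pytest.mark.parametrize("ratio,score", [(1.0, 0.0), (2.0, 1.0)])
    def test_true_score_is_log2_ratio(self, ratio, score):
        _, _, true = md.simulate_cell_image(md.CellImageConfig(chromatin_to_cell_ratio=ratio))
        assert true == pytest.approx(score)

    def test_noiseless_image_reproduces_score_exactly(self):
        cfg = md.CellImageConfig(chromatin_to_cell_ratio=0.5, noise_sd=0.0)
        image, masks, _ = md.simulate_cell_image(cfg)
        halo = image[1]
        measured = np.log2(halo[masks["chromatin"]].mean() / halo[masks["cell"]].mean())
        assert measured == pytest.approx(-1.0, abs=1e-6)

    def test_whole_cell_mean_is_cell_mean(self):
        cfg = md.CellImageConfig(chromatin_to_cell_ratio=1.8, noise_sd=0.0)
        image, masks, _ = md.simulate_cell_image(cfg)
        assert image[1][masks["cell"]].mean() == pytest.approx(cfg.cell_mean, rel=1e-6)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(InvalidConfigError):
            md.CellImageConfig(chromatin_to_cell_ratio=0.0)
        with pytest.raises(InvalidConfigError):
            md.CellImageConfig(chromatin_axes=(100.0, 100.0))  # outside the cell


class TestSpikeInCounts:
    def _cfg(self, **kw):
        samples = kw.pop("samples", (("async", "asynchronous", 0.01),
                                     ("mitotic", "mitotic", 0.005)))
        return md.SpikeInSimConfig(samples=samples, **kw)

    def test_deterministic_counts_match_expectation(self):
        table = md.simulate_spikein_counts(self._cfg(deterministic=True,
                                                     total_reads=1_000_000))
        assert table["fly_reads"].tolist() == [10_000, 5_000]
        assert table["is_reference"].tolist() == [True, False]

    def test_seeded_determinism(self):
        cfg = self._cfg(seed=5)
        pd.testing.assert_frame_equal(md.simulate_spikein_counts(cfg),
                                      md.simulate_spikein_counts(cfg))

    def test_missing_reference_rejected(self):
        with pytest.raises(InvalidConfigError):
            md.SpikeInSimConfig(samples=(("m1", "mitotic", 0.01),))
        with pytest.raises(InvalidConfigError):
            self._cfg(samples=(("a", "asynchronous", 1.5),))
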