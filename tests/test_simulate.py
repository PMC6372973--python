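"""Synthetic-data generators: determinism, planted truth, distributional fidelity."""

import numpy as np
import pandas as pd
import pytest

from reprotrace.errors import ConfigurationError, PlacementError
from reprotrace.simulate import (
    AnticorrSimConfig,
    ExpressionSimConfig,
    FlowSimConfig,
    LogNormalComponent,
    ScreenSimConfig,
    TraceSimConfig,
    WellSimConfig,
    gen_anticorrelated,
    gen_expression,
    gen_flow_events,
    gen_screen_dataset,
    gen_traces,
    gen_well_image,
)


class TestExpressionSim:
    def test_zero_noise_transient_gene_hits_class_template(self):
        cfg = ExpressionSimConfig(n_genes=200, noise_sd=0.0, seed=1)
        matrix, truth = gen_expression(cfg)
        gene = truth.index[(truth["gene_class"] == "transient_MET") & ~truth["esc_elevated"]][0]
        row = matrix.values.loc[gene]
        # baseline in iPSC and lowKLF4; peak effect at day 8 high-KLF4
        assert row["iPSC_r1"] == cfg.baseline
        assert row["lowKLF4_d8_r1"] == cfg.baseline
        assert row["highKLF4_d8_r1"] == cfg.baseline + cfg.log2_effect
        assert row["keratinocyte_r2"] == cfg.baseline + cfg.log2_effect

    def test_deterministic_given_seed(self):
        cfg = ExpressionSimConfig(n_genes=100, seed=9)
        m1, t1 = gen_expression(cfg)
        m2, t2 = gen_expression(ExpressionSimConfig(n_genes=100, seed=9))
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1, t2)

    def test_every_gene_has_exactly_one_class(self):
        _, truth = gen_expression(ExpressionSimConfig(n_genes=333, seed=2))
        assert len(truth) == 333
        assert truth["gene_class"].notna().all()

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_expression(ExpressionSimConfig(class_proportions={"background": 0.5}))
        with pytest.raises(ConfigurationError):
            gen_expression(ExpressionSimConfig(noise_sd=-1))

    def test_noise_sd_matches_config_within_3se(self):
        cfg = ExpressionSimConfig(n_genes=1000, noise_sd=0.3, seed=4)
        noisy, _ = gen_expression(cfg)
        clean, _ = gen_expression(
            ExpressionSimConfig(n_genes=1000, noise_sd=0.0, seed=4)
        )
        resid = (noisy.values - clean.values).to_numpy().ravel()
        se = cfg.noise_sd / np.sqrt(2 * resid.size)
        assert resid.std() == pytest.approx(0.3, abs=3 * se)
        assert abs(resid.mean()) <= 3 * cfg.noise_sd / np.sqrt(resid.size)


class TestWellSim:
    def test_zero_colonies_gives_pure_background(self):
        cfg = WellSimConfig(
            n_colonies={}, noise_sd=0.0, gradient_amplitude=0.0, seed=0
        )
        images, truth = gen_well_image(cfg)
        assert truth.empty
        assert np.all(images["gfp"] == cfg.background_level)

    def test_bit_identical_given_seed(self):
        a, _ = gen_well_image(WellSimConfig(seed=5))
        b, _ = gen_well_image(WellSimConfig(seed=5))
        assert all(np.array_equal(a[ch], b[ch]) for ch in a)

    def test_truth_lists_every_colony_with_class_and_area(self):
        cfg = WellSimConfig(seed=3)
        _, truth = gen_well_image(cfg)
        assert len(truth) == sum(cfg.n_colonies.values())
        assert set(truth["colony_class"]) <= set(cfg.n_colonies)
        assert (truth["area"] >= np.pi * cfg.colony_radius_range[0] ** 2 * 0.8).all()

    def test_impossible_nonoverlap_placement_raises(self):
        cfg = WellSimConfig(
            image_shape=(64, 64),
            n_colonies={"negative": 40},
            colony_radius_range=(10, 12),
            max_attempts=50,
            seed=0,
        )
        with pytest.raises(PlacementError):
            gen_well_image(cfg)

    def test_intensities_exceeding_16bit_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_well_image(WellSimConfig(background_level=70000.0))


class TestFlowSim:
    def test_single_component_median_matches_closed_form(self):
        cfg = FlowSimConfig(
            channels={"c": (LogNormalComponent(np.log(3500.0), 0.5, 1.0),)},
            n_events=10001,
            seed=6,
        )
        events, comp = gen_flow_events(cfg)
        med = float(np.median(events["c"]))
        # 3*SE of the sample median of a log-normal
        se = 3500.0 * 0.5 * 1.2533 / np.sqrt(10001)
        assert med == pytest.approx(3500.0, abs=3 * se)
        assert (comp["c"] == 0).all()

    def test_zero_events_gives_empty_table(self):
        events, _ = gen_flow_events(FlowSimConfig(n_events=0))
        assert len(events) == 0

    def test_component_weights_respected_within_3se(self):
        events, comp = gen_flow_events(FlowSimConfig(n_events=4000, seed=7))
        frac = float((comp["TROP2"] == 1).mean())
        assert frac == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 4000))

    def test_bad_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_flow_events(
                FlowSimConfig(channels={"c": (LogNormalComponent(0, 1, 0.5),)})
            )


class TestScreenSim:
    def test_deterministic_and_labeled(self):
        a = gen_screen_dataset(ScreenSimConfig(seed=8))
        b = gen_screen_dataset(ScreenSimConfig(seed=8))
        pd.testing.assert_frame_equal(a, b)
        assert set(a.loc[a["is_control"], "gene"]) == {"sgRNA-"}
        # every targeting sgRNA belongs to exactly one gene
        per = a[~a["is_control"]].groupby("sgrna_id")["gene"].nunique()
        assert (per == 1).all()

    def test_control_moments_match_config_within_3se(self):
        cfg = ScreenSimConfig(n_control_sgrnas=1000, gene_effects={}, seed=9)
        ds = gen_screen_dataset(cfg)
        ctrl = ds[ds["readout_type"] == "pct_TROP2_pos"]["value"]
        assert ctrl.mean() == pytest.approx(50.0, abs=3 * 2.0 / np.sqrt(1000))
        assert ctrl.std(ddof=1) == pytest.approx(2.0, abs=3 * 2.0 / np.sqrt(2 * 1000))

    def test_minus_six_sigma_effect_puts_all_sgrnas_below_threshold(self):
        cfg = ScreenSimConfig(
            gene_effects={"X": {"pct_TROP2_pos": -12.0}}, seed=10
        )  # -6 * SD(=2)
        ds = gen_screen_dataset(cfg)
        vals = ds[(ds["gene"] == "X") & (ds["readout_type"] == "pct_TROP2_pos")]["value"]
        assert (vals < 50.0 - 3 * 2.0).all()


class TestTraceSim:
    def test_all_wt_spectrum_reproduces_control(self):
        cfg = TraceSimConfig(spectrum={0: 1.0}, noise_sd=0.0, seed=11)
        control, edited = gen_traces(cfg)
        np.testing.assert_array_equal(control.array(), edited.array())

    def test_upstream_of_cut_identical_to_control(self):
        cfg = TraceSimConfig(spectrum={0: 0.5, -2: 0.5}, noise_sd=0.0, seed=12)
        control, edited = gen_traces(cfg)
        cut = cfg.cut_site
        np.testing.assert_array_equal(control.array()[:cut], edited.array()[:cut])

    def test_invalid_spectra_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_traces(TraceSimConfig(spectrum={0: 0.5, 1: 0.4}))  # sums to 0.9
        with pytest.raises(ConfigurationError):
            gen_traces(TraceSimConfig(spectrum={0: 0.5, 99: 0.5}))  # outside window
        with pytest.raises(ConfigurationError):
            gen_traces(TraceSimConfig(spectrum={0: 1.5, -1: -0.5}))


class TestAnticorrSim:
    def test_planted_population_correlation_near_target(self):
        cfg = AnticorrSimConfig(n_planted=400, n_background=0, seed=13)
        matrix, truth = gen_anticorrelated(cfg)
        course, _ = matrix.timecourse("highKLF4")
        x = course.loc["REF"].to_numpy()
        y = course.loc[truth[truth].index].to_numpy()
        xc = x - x.mean()
        yc = y - y.mean(1, keepdims=True)
        r = (yc @ xc) / np.sqrt((yc**2).sum(1) * (xc @ xc))
        assert np.mean(r) == pytest.approx(-0.95, abs=0.02)
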