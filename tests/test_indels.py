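"""Indel decomposition: calibration, NNLS spectrum recovery, frame classes,
population enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from reprotrace.errors import InputError, TraceQualityError
from reprotrace.evaluation import grid_search_spectrum
from reprotrace.indels import (
    FrameClassSummary,
    IndelSpectrum,
    calibrate,
    classify_frames,
    compare_populations,
    decompose,
)
from reprotrace.simulate import TraceSignal, TraceSimConfig, gen_traces


def _make_signal(arr, cut):
    return TraceSignal(
        pd.DataFrame(arr, columns=["A", "C", "G", "T"]).rename_axis("pos"), cut
    )


class TestCalibrate:
    def test_doubled_intensity_gives_half_scale(self):
        control, _ = gen_traces(TraceSimConfig(spectrum={0: 1.0}, seed=51))
        doubled = _make_signal(2.0 * control.array(), control.cut_site)
        cal = calibrate(control, doubled)
        assert cal.scale == pytest.approx(0.5)
        assert cal.offset == 0 and cal.rmse < 1e-9

    def test_position_shift_recovered(self):
        control, _ = gen_traces(TraceSimConfig(spectrum={0: 1.0}, seed=52))
        arr = control.array()
        shifted = _make_signal(np.roll(arr, 1, axis=0), control.cut_site)
        cal = calibrate(control, shifted)
        # edited[p] = control[p-1] -> edited[p] ~ control[p + (-1)]
        assert cal.offset == -1

    def test_unrelated_traces_fail_quality_check(self):
        a, _ = gen_traces(TraceSimConfig(spectrum={0: 1.0}, seed=53))
        b, _ = gen_traces(TraceSimConfig(spectrum={0: 1.0}, seed=54))
        with pytest.raises(TraceQualityError):
            calibrate(a, b)


class TestDecompose:
    def test_identical_traces_are_pure_wt(self):
        control, edited = gen_traces(TraceSimConfig(spectrum={0: 1.0}, seed=55))
        spec = decompose(control, edited)
        assert spec.frequencies[0] == pytest.approx(1.0, abs=1e-9)
        assert sum(v for k, v in spec.frequencies.items() if k != 0) < 1e-9
        assert spec.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "spectrum",
        [{0: 0.7, -3: 0.3}, {0: 0.5, 1: 0.3, -2: 0.2}, {0: 0.2, -10: 0.5, 10: 0.3}],
    )
    def test_noise_free_mixture_recovered_to_1e6(self, spectrum):
        control, edited = gen_traces(TraceSimConfig(spectrum=spectrum, seed=56))
        spec = decompose(control, edited)
        for k in range(-10, 11):
            assert spec.frequencies[k] == pytest.approx(spectrum.get(k, 0.0), abs=1e-6)

    @given(st.integers(-10, 10))
    def test_shift_symmetry_single_allele_recovered(self, k):
        control, edited = gen_traces(TraceSimConfig(spectrum={k: 1.0}, seed=57))
        spec = decompose(control, edited)
        assert spec.frequencies[k] == pytest.approx(1.0, abs=1e-6)

    def test_scaled_edited_trace_handled_by_calibration(self):
        control, edited = gen_traces(
            TraceSimConfig(spectrum={0: 0.6, -1: 0.4}, edited_scale=1.7, seed=58)
        )
        spec = decompose(control, edited)
        assert spec.frequencies[0] == pytest.approx(0.6, abs=1e-6)
        assert spec.frequencies[-1] == pytest.approx(0.4, abs=1e-6)

    def test_region_past_trace_end_rejected(self):
        control, edited = gen_traces(TraceSimConfig(seed=59))
        with pytest.raises(InputError):
            decompose(control, edited, decomp_region=(control.cut_site + 5, 1000))

    def test_matches_grid_search_oracle_for_small_windows(self):
        # W=1 at grid resolution 0.01; W=2 at 0.02 (vectorized enumeration)
        for window, res, spectrum, seed in [
            (1, 0.01, {0: 0.6, -1: 0.25, 1: 0.15}, 60),
            (2, 0.02, {0: 0.5, -2: 0.3, 2: 0.2}, 61),
        ]:
            cfg = TraceSimConfig(spectrum=spectrum, window=window, noise_sd=0.01, seed=seed)
            control, edited = gen_traces(cfg)
            spec = decompose(control, edited, window=window)
            oracle = grid_search_spectrum(control, edited, window=window, resolution=res)
            for k, v in oracle.items():
                assert spec.frequencies[k] == pytest.approx(v, abs=res)


class TestClassifyFrames:
    @pytest.mark.parametrize(
        "k,cls",
        [(0, "WT"), (-3, "inframe_3n0"), (3, "inframe_3n0"), (1, "shift_3n1"),
         (-2, "shift_3n1"), (2, "shift_3n2"), (-1, "shift_3n2"), (4, "shift_3n1")],
    )
    def test_mathematical_modulus_convention(self, k, cls):
        spec = IndelSpectrum(window=10, frequencies={k: 1.0}, r_squared=1.0)
        assert classify_frames(spec).fractions[cls] == 1.0

    @given(
        st.dictionaries(
            st.integers(-10, 10), st.floats(0, 1, allow_nan=False), max_size=21
        )
    )
    def test_frame_classes_partition_total_mass(self, freqs):
        spec = IndelSpectrum(window=10, frequencies=freqs, r_squared=1.0)
        summary = classify_frames(spec)
        assert sum(summary.fractions.values()) == pytest.approx(sum(freqs.values()))


class TestComparePopulations:
    def test_identical_summaries_give_unit_ratios(self):
        s = FrameClassSummary({"WT": 0.4, "inframe_3n0": 0.1, "shift_3n1": 0.3, "shift_3n2": 0.2})
        comp = compare_populations(s, s)
        assert all(r == pytest.approx(1.0) for r in comp.ratios.values())

    def test_fitness_selection_forward_model_recovered(self):
        # selection with fitness w=2 on frameshift alleles, then renormalize
        a = {"WT": 0.5, "inframe_3n0": 0.1, "shift_3n1": 0.25, "shift_3n2": 0.15}
        w = {"WT": 1.0, "inframe_3n0": 1.0, "shift_3n1": 2.0, "shift_3n2": 2.0}
        z = sum(a[c] * w[c] for c in a)
        b = {c: a[c] * w[c] / z for c in a}
        comp = compare_populations(FrameClassSummary(a), FrameClassSummary(b))
        for c in a:
            assert comp.ratios[c] == pytest.approx(w[c] / z)
        assert comp.status("shift_3n1") == "enriched"
        assert comp.status("WT") == "depleted"

    def test_zero_reference_fraction_flagged_undefined(self):
        a = FrameClassSummary({"WT": 0.0, "inframe_3n0": 0.0, "shift_3n1": 1.0, "shift_3n2": 0.0})
        b = FrameClassSummary({"WT": 0.5, "inframe_3n0": 0.0, "shift_3n1": 0.5, "shift_3n2": 0.0})
        comp = compare_populations(a, b)
        assert comp.ratios["WT"] is None and comp.status("WT") == "undefined"


def test_end_to_end_frameshift_enrichment_between_populations():
    """Day-8 vs day-18 sorted populations: planting frameshift-selected
    spectra yields enriched 1/2-bp shifts and depleted WT, as decomposed."""
    day8 = {0: 0.4, -1: 0.25, 1: 0.2, -3: 0.15}
    day18 = {0: 0.1, -1: 0.4, 1: 0.35, -3: 0.15}
    summaries = {}
    for label, spectrum in [("a", day8), ("b", day18)]:
        control, edited = gen_traces(TraceSimConfig(spectrum=spectrum, seed=62))
        summaries[label] = classify_frames(decompose(control, edited))
    comp = compare_populations(summaries["a"], summaries["b"])
    assert comp.status("WT") == "depleted"
    assert comp.status("shift_3n1") == "enriched"
    assert comp.status("shift_3n2") == "enriched"
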