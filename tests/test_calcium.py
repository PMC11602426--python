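import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haircelltox.calcium import (
    CalciumTrace,
    align_to_endpoint,
    classify_responder,
    classify_trace,
    condition_stats,
    dff,
    dunn_posthoc,
    extract_traces,
    summarize_condition,
    traces_from_frame,
    traces_to_frame,
)
from haircelltox.imaging import register_rigid
from haircelltox.synthetic_data import (
    StackPhantomParams,
    TracePhantomParams,
    gen_calcium_traces,
    gen_timelapse,
)


def _trace(values, fate="dying", frag=None, baseline=5, cell=1, cond="c"):
    return CalciumTrace(cell, cond, fate, np.asarray(values, dtype=float),
                        baseline_frames=baseline, frag_frame=frag)


class TestDff:
    def test_ff0_arithmetic(self):
        tr = _trace([100, 100, 100, 100, 100, 150, 220], frag=6)
        ff0, mean, sd = dff(tr)
        assert ff0[-1] == pytest.approx(2.2)
        assert mean == 1.0
        assert sd == pytest.approx(0.0)

    def test_flat_trace_is_unity_with_zero_sd(self):
        ff0, _, sd = dff(_trace([80] * 10, fate="living"))
        assert np.allclose(ff0, 1.0)
        assert sd == 0.0

    def test_baseline_mean_is_exactly_one(self):
        tr = _trace([90, 110, 100, 95, 105, 130], frag=5)
        ff0, _, _ = dff(tr)
        assert ff0[:5].mean() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_baseline_is_an_error(self):
        tr = _trace([0, 0, 0, 0, 0, 10], frag=5)
        with pytest.raises(ValueError):
            dff(tr)


class TestClassify:
    def test_two_sd_rule_boundary(self):
        """Max 1.09 under threshold 1.10 is no responder; 1.11 is."""
        base = np.ones(5)
        below = np.concatenate([base, [1.09] * 3])
        above = np.concatenate([base, [1.11] * 3])
        assert not classify_responder(below, 1.0, 0.05, (5, 8))
        assert classify_responder(above, 1.0, 0.05, (5, 8))

    def test_zero_length_window_is_an_error(self):
        with pytest.raises(ValueError):
            classify_responder(np.ones(10), 1.0, 0.1, (5, 5))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.01, 2.0))
    def test_adding_positive_offset_never_unmakes_a_responder(self, offset):
        rng = np.random.default_rng(0)
        ff0 = np.concatenate([1 + rng.normal(0, 0.02, 5), [1.5], 1 + rng.normal(0, 0.02, 4)])
        sd = ff0[:5].std(ddof=1)
        assert classify_responder(ff0, 1.0, sd, (5, 10))
        boosted = ff0.copy()
        boosted[5:] += offset
        assert classify_responder(boosted, 1.0, sd, (5, 10))

    def test_generator_guaranteed_transients_all_classified(self):
        traces, _ = gen_calcium_traces(TracePhantomParams(seed=5, n_living=0))
        assert all(classify_trace(t).responder for t in traces)


class TestEndpointAlignment:
    def test_last_prefragmentation_values_share_index(self):
        t1 = _trace(np.linspace(100, 120, 11), frag=10)
        t2 = _trace(np.linspace(100, 140, 21), frag=20, cell=2)
        aligned = align_to_endpoint([t1, t2])
        assert aligned.index.min() == -20 and aligned.index.max() == 0
        assert not np.isnan(aligned.loc[0]).any()
        assert np.isnan(aligned.loc[-15, 1])  # shorter history padded

    def test_single_trace_is_identity_up_to_reindexing(self):
        t = _trace([100, 100, 100, 100, 100, 150, 200], frag=6)
        aligned = align_to_endpoint([t])
        ff0, _, _ = dff(t)
        np.testing.assert_allclose(aligned[1].to_numpy(), ff0)

    def test_living_traces_are_rejected(self):
        with pytest.raises(ValueError):
            align_to_endpoint([_trace([1] * 10, fate="living")])

    def test_mean_aligned_transient_peaks_near_generator_lag(self):
        params = TracePhantomParams(seed=3, n_dying=50, n_living=0)
        traces, _ = gen_calcium_traces(params)
        aligned = align_to_endpoint(traces)
        mean_trace = aligned.mean(axis=1)
        peak_index = int(mean_trace.idxmax())
        assert abs(peak_index + params.peak_to_frag_lag_frames) <= 2


class TestSummaries:
    def test_flat_traces_have_unit_maxima_and_no_responders(self):
        traces = [_trace([100.0] * 12, frag=11, cell=i) for i in range(1, 4)]
        s = summarize_condition(traces)
        assert s["n_responders"] == 0
        assert s["max_ff0_mean"] == pytest.approx(1.0)

    def test_known_labels_counted_exactly(self):
        resp = _trace([100, 100, 100, 100, 100, 300, 100], frag=6, cell=1)
        base = 100 * (1 + np.asarray([0.01, -0.01, 0.02, -0.02, 0.0, 0.01, 0.0]))
        non = _trace(base, frag=6, cell=2)
        s = summarize_condition([resp, non])
        assert s["n_dying"] == 2 and s["n_responders"] == 1

    def test_monte_carlo_mean_maximum_matches_generator(self):
        means = [
            summarize_condition(
                gen_calcium_traces(TracePhantomParams(seed=60_000 + r, n_living=0))[0]
            )["max_ff0_mean"]
            for r in range(200)
        ]
        se = 0.46 / np.sqrt(16)
        assert np.mean(means) == pytest.approx(2.2, abs=3 * se)


class TestConditionStats:
    @pytest.fixture()
    def printed_table(self):
        return pd.DataFrame(
            {
                "condition": ["neo100_acute", "g418_100_delayed", "g418_400_acute"],
                "n_dying": [16, 11, 14],
                "n_responders": [16, 2, 10],
            }
        )

    def test_responder_contingency_chi_square(self, printed_table):
        out = condition_stats(printed_table)
        assert out["chi2"] == pytest.approx(20.25, abs=0.005)
        assert out["chi2_dof"] == 2
        assert out["chi2_p"] < 0.0001

    def test_identical_proportions_give_zero(self):
        table = pd.DataFrame({"condition": list("abc"), "n_dying": [10, 20, 30],
                              "n_responders": [5, 10, 15]})
        assert condition_stats(table)["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_matches_hand_computation(self):
        """Pearson chi-square of {{3,7},{8,2}} from summing (O-E)^2/E."""
        table = pd.DataFrame({"condition": ["a", "b"], "n_dying": [10, 10],
                              "n_responders": [3, 8]})
        obs = np.array([[3, 7], [8, 2]])
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        by_hand = ((obs - expected) ** 2 / expected).sum()
        assert condition_stats(table)["chi2"] == pytest.approx(by_hand)

    def test_row_permutation_invariance(self, printed_table):
        shuffled = printed_table.iloc[[2, 0, 1]].reset_index(drop=True)
        assert condition_stats(shuffled)["chi2"] == pytest.approx(
            condition_stats(printed_table)["chi2"]
        )

    def test_empty_condition_is_an_error(self):
        table = pd.DataFrame({"condition": ["a", "b"], "n_dying": [0, 5],
                              "n_responders": [0, 1]})
        with pytest.raises(ValueError):
            condition_stats(table)

    def test_dunn_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(loc, 0.4, 12) for k, loc in
                  [("a", 2.2), ("b", 1.2), ("c", 1.7)]}
        dunn = dunn_posthoc(groups)
        assert (dunn.p_adj >= dunn.p_raw - 1e-12).all()

    def test_kruskal_attached_when_maxima_given(self, printed_table):
        rng = np.random.default_rng(2)
        groups = {"a": rng.normal(2.2, 0.46, 16), "b": rng.normal(1.2, 0.32, 11),
                  "c": rng.normal(1.7, 0.4, 14)}
        out = condition_stats(printed_table, groups)
        assert out["kruskal_p"] < 0.05
        assert len(out["dunn"]) == 3


@pytest.fixture(scope="module")
def timelapse():
    params = StackPhantomParams(
        seed=6, n_cells=6, cell_radius_um=3.0, shape_px=(20, 96, 96),
        voxel_size_um=(0.5, 0.25, 0.25), snr=None, drift_px_per_frame=(0.0, 0.0),
    )
    stack, _ = gen_timelapse(params, 8)
    return stack


class TestExtractTraces:
    def test_uniform_roi_yields_flat_trace(self, timelapse):
        data = timelapse.data.copy()
        data[:, 0] = 100.0
        stack = timelapse.with_data(data)
        rois = np.zeros(stack.shape_zyx[1:], dtype=np.int32)
        rois[10:20, 10:20] = 1
        traces = extract_traces(stack, rois, "reporter")
        assert len(traces) == 1
        assert np.allclose(traces[0].intensities, 100.0)

    def test_injected_transient_is_recovered(self, timelapse):
        data = timelapse.data.copy()
        rois = np.zeros(timelapse.shape_zyx[1:], dtype=np.int32)
        rois[40:50, 40:50] = 1
        waveform = 1.0 + np.array([0, 0, 0, 0, 0, 0.8, 1.2, 0.4])
        data[:, 0, :, 40:50, 40:50] *= waveform[:, None, None, None]
        stack = timelapse.with_data(data)
        tr = extract_traces(stack, rois, "reporter")[0]
        ff0 = tr.intensities / tr.intensities[:5].mean()
        assert np.allclose(ff0, waveform, atol=0.05)

    def test_alignment_reduces_trace_variance_under_drift(self, no_warnings):
        params = StackPhantomParams(
            seed=7, n_cells=6, cell_radius_um=3.0, shape_px=(20, 96, 96),
            voxel_size_um=(0.5, 0.25, 0.25), snr=None, drift_px_per_frame=(1.5, -1.5),
        )
        stack, _ = gen_timelapse(params, 6)
        aligned, _ = register_rigid(stack, "reporter", refine_rotation=False)
        rois = np.zeros(stack.shape_zyx[1:], dtype=np.int32)
        # ROI on a bright cell in frame 0
        ref = stack.data[0, 0].max(axis=0)
        cy, cx = np.unravel_index(np.argmax(ref), ref.shape)
        rois[cy - 4 : cy + 5, cx - 4 : cx + 5] = 1
        var_raw = np.var(extract_traces(stack, rois, "reporter")[0].intensities)
        var_aligned = np.var(extract_traces(aligned, rois, "reporter")[0].intensities)
        assert var_aligned < var_raw


def test_long_format_roundtrip():
    traces, _ = gen_calcium_traces(TracePhantomParams(seed=4, n_dying=3, n_living=2))
    back = traces_from_frame(traces_to_frame(traces))
    assert len(back) == len(traces)
    by_id = {t.cell_id: t for t in back}
    for t in traces:
        np.testing.assert_allclose(by_id[t.cell_id].intensities, t.intensities)
        assert by_id[t.cell_id].fate == t.fate
        assert by_id[t.cell_id].frag_frame == t.frag_frame
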