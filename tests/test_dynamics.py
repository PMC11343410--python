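import numpy as np
import pytest

from nucseg.dynamics import (
    NormalizedTrace,
    Trace,
    TraceError,
    impute_missing,
    marker_status,
    normalize_baseline_minmax,
    normalize_nuc_over_cell,
    read_traces_csv,
    resample,
    trace_distance,
    traces_to_frame,
)


def mk(times, values, stim, missing=None, cell="c0"):
    return Trace(times=np.asarray(times, float), values=np.asarray(values, float),
                 stim_time=stim, missing=missing, cell_id=cell)


class TestImpute:
    def test_no_missing_identity(self):
        tr = mk([0, 5, 10], [1, 2, 3], 5)
        out = impute_missing(tr)
        np.testing.assert_array_equal(out.values, [1, 2, 3])

    def test_mean_of_observed(self):
        tr = mk([0, 5, 10], [2, np.nan, 4], 5)
        out = impute_missing(tr)
        assert out.values[1] == 3.0
        assert out.values[0] == 2 and out.values[2] == 4

    def test_flags_retained_for_provenance(self):
        tr = mk([0, 5, 10], [2, np.nan, 4], 5)
        out = impute_missing(tr)
        assert list(out.missing) == [False, True, False]

    def test_neighbor_interpolation_option(self):
        tr = mk([0, 5, 10], [0, np.nan, 10], 5)
        out = impute_missing(tr, method="neighbor")
        assert out.values[1] == 5.0

    def test_all_missing_rejected(self):
        tr = mk([0, 5, 10], [np.nan] * 3, 5)
        with pytest.raises(TraceError):
            impute_missing(tr)


class TestResample:
    def test_worked_linear_interpolation_example(self):
        tr = mk([0, 9, 18], [0, 9, 18], 0)
        out = resample(tr, 7)
        np.testing.assert_allclose(out.times, [0, 7, 14])
        np.testing.assert_allclose(out.values, [0, 7, 14])

    def test_native_interval_identity(self):
        tr = mk([0, 7, 14, 21], [3, 1, 4, 1], 7)
        out = resample(tr, 7)
        np.testing.assert_allclose(out.times, tr.times)
        np.testing.assert_allclose(out.values, tr.values)

    def test_constant_trace_stays_constant(self):
        tr = mk([0, 5, 13], [2, 2, 2], 5)
        out = resample(tr, 7)
        np.testing.assert_allclose(out.values, 2.0)

    def test_no_extrapolation(self):
        tr = mk([0, 10], [0, 10], 0)
        out = resample(tr, 7)
        assert out.times[-1] <= 10

    def test_commutes_with_affine_value_rescaling(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 60, 9))
        times[0] = 0.0
        vals = rng.normal(5, 2, 9)
        tr = mk(times, vals, 30)
        a, b = 2.5, -1.0
        direct = resample(mk(times, a * vals + b, 30), 7).values
        after = a * resample(tr, 7).values + b
        np.testing.assert_allclose(direct, after, atol=1e-12)


class TestBaselineMinmax:
    def test_worked_example(self):
        tr = mk([0, 5, 10], [2, 2, 4], 10)
        (out,) = normalize_baseline_minmax([tr])
        # baseline 2 -> [1,1,2]; min-max -> [0,0,1]
        np.testing.assert_allclose(out.values, [0, 0, 1])

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(1)
        traces = [
            mk(np.arange(0, 70, 7), rng.uniform(1, 9, 10), 21, cell=f"c{i}")
            for i in range(5)
        ]
        for out in normalize_baseline_minmax(traces):
            assert out.values.min() >= 0 and out.values.max() <= 1

    def test_scale_invariance_of_baseline_division(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 5, 8)
        times = np.arange(0, 56, 7)
        a = [mk(times, vals, 21), mk(times, vals[::-1], 21, cell="c1")]
        b = [mk(times, 37.0 * vals, 21), mk(times, 37.0 * vals[::-1], 21, cell="c1")]
        for oa, ob in zip(normalize_baseline_minmax(a), normalize_baseline_minmax(b)):
            np.testing.assert_allclose(oa.values, ob.values, atol=1e-12)

    def test_constant_experiment_rejected(self):
        tr = mk([0, 5, 10], [3, 3, 3], 5)
        with pytest.raises(TraceError, match="min"):
            normalize_baseline_minmax([tr])

    def test_zero_baseline_names_cell(self):
        tr = mk([0, 5, 10], [0, 0, 4], 10, cell="bad_cell")
        with pytest.raises(TraceError, match="bad_cell"):
            normalize_baseline_minmax([tr])


class TestNucOverCell:
    def test_equal_traces_give_unity(self):
        t = np.arange(0, 28, 7)
        nuc = mk(t, [2, 2, 3, 4], 14)
        out = normalize_nuc_over_cell(nuc, mk(t, [2, 2, 3, 4], 14))
        np.testing.assert_allclose(out.values, 1.0)

    def test_worked_example(self):
        t = np.array([0.0, 7.0, 14.0])
        nuc = mk(t, [1, 1, 2], 14)
        cell = mk(t, [2, 2, 2], 14)
        out = normalize_nuc_over_cell(nuc, cell)
        np.testing.assert_allclose(out.values, [1, 1, 2])

    def test_prestim_mean_is_one(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 70, 7.0)
        nuc = mk(t, rng.uniform(1, 5, 10), 28)
        cell = mk(t, rng.uniform(2, 6, 10), 28)
        out = normalize_nuc_over_cell(nuc, cell)
        assert out.values[t < 28].mean() == pytest.approx(1.0)

    def test_zero_wholecell_rejected(self):
        t = np.array([0.0, 7.0, 14.0])
        with pytest.raises(TraceError):
            normalize_nuc_over_cell(mk(t, [1, 1, 1], 7), mk(t, [1, 0, 1], 7))


class TestTraceDistance:
    def norm(self, times, values):
        return NormalizedTrace(times=np.asarray(times, float),
                               values=np.asarray(values, float), stim_time=0)

    def test_identical_traces_zero(self):
        a = self.norm([0, 7], [0.2, 0.8])
        assert trace_distance(a, a) == 0.0

    def test_three_four_five(self):
        a = self.norm([0, 7], [0, 0])
        b = self.norm([0, 7], [3, 4])
        assert trace_distance(a, b) == pytest.approx(5.0)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 35, 7.0)
        for _ in range(50):
            a, b, c = (self.norm(t, rng.normal(size=5)) for _ in range(3))
            dab, dba = trace_distance(a, b), trace_distance(b, a)
            assert dab == pytest.approx(dba)
            assert dab >= 0
            assert trace_distance(a, c) <= dab + trace_distance(b, c) + 1e-12

    def test_overlap_only(self):
        a = self.norm([0, 7, 14], [1, 2, 3])
        b = self.norm([7, 14, 21], [2, 3, 4])
        assert trace_distance(a, b) == 0.0  # identical on the overlap

    def test_disjoint_grids_rejected(self):
        with pytest.raises(TraceError):
            trace_distance(self.norm([0], [1]), self.norm([7], [1]))

    def test_mixed_normalizations_rejected(self):
        a = self.norm([0, 7], [1, 1])
        b = NormalizedTrace(times=np.array([0.0, 7.0]), values=np.ones(2),
                            stim_time=0, normalization_kind="nuc_over_cell_baseline")
        with pytest.raises(TraceError):
            trace_distance(a, b)


class TestMarkerStatus:
    def test_ly6c_worked_threshold(self):
        # pre [0.9, 1.0, 1.1]: mean 1.0, sample sd 0.1 -> threshold 1.5
        tr = mk([0, 5, 10, 15], [0.9, 1.0, 1.1, 1.6], 12)
        status, thr = marker_status(tr, "Ly6C")
        assert thr == pytest.approx(1.5)
        assert status == "positive"

    def test_ly6c_threshold_mean_plus_five_sd(self):
        pre = [1.0, 1.2, 0.8, 1.0]
        tr = mk([0, 5, 10, 15, 20], pre + [1.1], 18)
        _, thr = marker_status(tr, "Ly6C")
        assert thr == pytest.approx(np.mean(pre) + 5 * np.std(pre, ddof=1))
        # population convention stays available
        _, thr0 = marker_status(tr, "Ly6C", sd_ddof=0)
        assert thr0 == pytest.approx(np.mean(pre) + 5 * np.std(pre))

    def test_cd115_three_times_mean(self):
        tr = mk([0, 5, 10], [1.0, 1.0, 2.5], 8)
        status, thr = marker_status(tr, "CD115")
        assert thr == pytest.approx(3.0)
        assert status == "negative"

    def test_flat_trace_negative_for_both(self):
        tr = mk([0, 5, 10, 15], [1, 1, 1, 1], 8)
        for marker in ("Ly6C", "CD115"):
            assert marker_status(tr, marker)[0] == "negative"

    def test_insufficient_prestim_rejected(self):
        tr = mk([0, 5, 10], [1, 2, 3], 3)
        with pytest.raises(TraceError):
            marker_status(tr, "Ly6C")


class TestCSVRoundTrip:
    def test_long_format_round_trip(self, tmp_path):
        traces = {
            "exp1": [mk([0, 7, 14], [1, np.nan, 3], 7, cell="a"),
                     mk([0, 7, 14], [2, 2, 2], 7, cell="b")],
        }
        df = traces_to_frame(traces)
        p = tmp_path / "traces.csv"
        df.to_csv(p, index=False)
        back = read_traces_csv(p)
        assert set(back) == {"exp1"}
        assert len(back["exp1"]) == 2
        a = next(t for t in back["exp1"] if t.cell_id == "a")
        assert list(a.missing) == [False, True, False]
        np.testing.assert_allclose(a.times, [0, 7, 14])
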