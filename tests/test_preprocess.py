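import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronopls.core import BinMeta, FeatureMatrix, SampleMeta
from chronopls.preprocess import (
    PreprocessConfig,
    autoscale,
    baseline_whittaker,
    blank_subtraction,
    glog,
    normalize_total_area,
    occurrence_filter,
    rsd_filter,
    run_preprocess,
    snr_filter,
    trim_rt,
    whittaker_system,
)


def _fm(values, rts=None, groups=None, days=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    rts = rts or [12.0 + j for j in range(p)]
    samples = []
    for i in range(n):
        g = groups[i] if groups else "B"
        d = days[i] if days else (1 if g in ("B", "F") else None)
        samples.append(SampleMeta(f"s{i}", g, d, (i % 3) + 1))
    bins = [BinMeta(j + 1, rt_min=rts[j]) for j in range(p)]
    return FeatureMatrix(values, samples, bins)


class TestTrimRT:
    def test_window_is_closed(self):
        fm = _fm(np.ones((2, 4)), rts=[5.0, 11.5, 31.0, 45.0])
        out = trim_rt(fm, PreprocessConfig())
        assert [b.rt_min for b in out.bins] == [11.5, 31.0]
        assert out.stage == "trimmed"

    def test_inside_window_identity(self):
        fm = _fm(np.ones((2, 3)), rts=[12.0, 20.0, 30.0])
        out = trim_rt(fm, PreprocessConfig())
        assert out.bin_ids == fm.bin_ids

    def test_all_removed_errors(self):
        fm = _fm(np.ones((2, 2)), rts=[5.0, 6.0])
        with pytest.raises(ValueError, match="no bins inside"):
            trim_rt(fm, PreprocessConfig())


class TestWhittakerBaseline:
    def test_constant_trace(self):
        y = np.full(50, 7.0)
        z, corrected = baseline_whittaker(y)
        np.testing.assert_allclose(z, 7.0, atol=1e-8)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-8)

    def test_linear_trace_is_its_own_baseline(self):
        y = 2.0 + 0.5 * np.arange(60)
        z, corrected = baseline_whittaker(y)
        np.testing.assert_allclose(z, y, atol=1e-6)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-6)

    def test_sparse_solver_matches_dense_oracle(self):
        rng = np.random.default_rng(0)
        cfg = PreprocessConfig()
        for m in (50, 120, 200):
            y = np.abs(rng.normal(size=m)).cumsum() / 5 + rng.uniform(0, 3, m)
            w = np.full(m, 1 - cfg.whittaker_p)
            for _ in range(3):
                a, rhs = whittaker_system(y, w, cfg.whittaker_lambda)
                z_dense = np.linalg.solve(a.toarray(), rhs)
                from scipy.sparse.linalg import spsolve

                z_sparse = spsolve(a, rhs)
                np.testing.assert_allclose(z_sparse, z_dense, rtol=1e-8, atol=1e-10)
                w = np.where(y > z_sparse, cfg.whittaker_p, 1 - cfg.whittaker_p)

    def test_infinite_lambda_limit_is_straight_line(self):
        """lambda -> inf leaves only the null space of the 2nd difference."""
        rng = np.random.default_rng(1)
        m = 50
        x = np.arange(m, dtype=float)
        y = 3.0 + 0.2 * x + rng.normal(0, 0.5, m)
        w = np.full(m, 0.5)  # symmetric weights: plain least squares
        cfg = PreprocessConfig(whittaker_lambda=1e12, whittaker_p=0.5, whittaker_max_iter=1)
        a, rhs = whittaker_system(y, w, cfg.whittaker_lambda)
        from scipy.sparse.linalg import spsolve

        z = spsolve(a, rhs)
        slope, intercept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(np.polyfit(x, z, 1), [slope, intercept], atol=1e-3)

    def test_peak_on_drift_recovers_area(self):
        """Corrected area of a Gaussian peak on a linear drift within 5%."""
        x = np.linspace(0, 10, 600)
        peak = 50.0 * np.exp(-0.5 * ((x - 5.0) / 0.3) ** 2)
        drift = 5.0 + 0.8 * x
        true_area = np.trapezoid(peak, x)
        _, corrected = baseline_whittaker(
            peak + drift, PreprocessConfig(whittaker_lambda=1e4)
        )
        got = np.trapezoid(corrected, x)
        assert got == pytest.approx(true_area, rel=0.05)

    def test_short_or_nonfinite_traces_rejected(self):
        with pytest.raises(ValueError, match="length >= 4"):
            baseline_whittaker(np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="non-finite"):
            baseline_whittaker(np.array([1.0, np.nan, 2.0, 3.0]))


class TestRowColumnTransforms:
    def test_normalize_arithmetic(self):
        fm = _fm([[2.0, 3.0, 5.0]])
        out = normalize_total_area(fm)
        np.testing.assert_allclose(out.values, [[0.2, 0.3, 0.5]])
        assert out.stage == "normalized"

    def test_normalize_idempotent_and_preserves_zero(self):
        fm = _fm([[0.0, 1.0, 3.0]])
        once = normalize_total_area(fm)
        twice = normalize_total_area(once)
        np.testing.assert_allclose(once.values, twice.values)
        assert once.values[0, 0] == 0.0

    def test_normalize_zero_row_names_sample(self):
        fm = _fm([[0.0, 0.0]])
        with pytest.raises(ValueError, match="'s0'"):
            normalize_total_area(fm)

    def test_glog_at_zero_closed_form(self):
        fm = _fm([[0.0]])
        out = glog(fm, PreprocessConfig(glog_lambda=0.1))
        assert out.values[0, 0] == pytest.approx(np.log(np.sqrt(0.1)), abs=1e-6)
        assert out.values[0, 0] == pytest.approx(-1.151293, abs=1e-6)

    def test_glog_small_lambda_limit(self):
        fm = _fm([[3.7]])
        out = glog(fm, PreprocessConfig(glog_lambda=1e-12))
        assert out.values[0, 0] == pytest.approx(np.log(2 * 3.7), abs=1e-6)

    @settings(deadline=None, max_examples=50)
    @given(
        st.tuples(
            st.floats(min_value=0, max_value=1e6),
            st.floats(min_value=0, max_value=1e6),
        ).filter(lambda t: abs(t[0] - t[1]) > 1e-6 * (1 + max(t)))
    )
    def test_glog_strictly_monotone(self, pair):
        lo, hi = sorted(pair)
        lam = 0.1
        g = lambda x: np.log(x + np.sqrt(x * x + lam))
        assert g(lo) < g(hi)

    def test_autoscale_unit_columns(self):
        fm = _fm([[1.0, 5.0], [2.0, 7.0], [3.0, 6.0]])
        out = autoscale(fm)
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-12)
        assert out.stage == "autoscaled"

    def test_autoscale_constant_column_names_bin(self):
        fm = _fm([[1.0, 4.0], [1.0, 5.0], [1.0, 6.0]])
        with pytest.raises(ValueError, match="zero-variance bin 1"):
            autoscale(fm)

    def test_glog_autoscale_commute_with_reordering(self):
        rng = np.random.default_rng(4)
        fm = _fm(rng.uniform(1, 9, size=(6, 3)))
        perm = rng.permutation(6)
        reordered = FeatureMatrix(
            fm.values[perm], [fm.samples[i] for i in perm], fm.bins, fm.stage
        )
        direct = autoscale(glog(fm)).values[perm]
        swapped = autoscale(glog(reordered)).values
        np.testing.assert_allclose(direct, swapped, atol=1e-12)


class TestFilters:
    def _with_qc(self, qc_block):
        qc_block = np.asarray(qc_block, dtype=float)
        n_qc, p = qc_block.shape
        study = np.full((3, p), 100.0)
        values = np.vstack([study, qc_block])
        groups = ["B"] * 3 + ["QC"] * n_qc
        days = [1, 1, 1] + [None] * n_qc
        return _fm(values, groups=groups, days=days)

    def test_rsd_keeps_stable_and_drops_noisy(self):
        fm = self._with_qc([[100.0, 100.0], [100.0, 150.0], [100.0, 200.0]])
        out, removed = rsd_filter(fm)
        assert out.bin_ids == [1]  # bin 2: sd 50, mean 150 -> 33.33% > 25%
        assert removed[0]["bin_id"] == 2 and "33.33" in removed[0]["reason"]

    def test_rsd_zero_mean_is_undefined(self):
        fm = self._with_qc([[100.0, 0.0], [100.0, 0.0], [100.0, 0.0]])
        out, removed = rsd_filter(fm)
        assert out.bin_ids == [1]
        assert "undefined RSD" in removed[0]["reason"]

    def test_rsd_needs_two_qc(self, small_fm):
        with pytest.raises(ValueError, match="QC samples"):
            rsd_filter(small_fm)

    def test_snr_threshold(self):
        fm = _fm([[10.0, 4.0]] * 3)
        out, removed = snr_filter(fm, noise_level=1.0)
        assert out.bin_ids == [1]
        assert removed[0]["bin_id"] == 2

    def test_snr_rejects_zero_noise(self, small_fm):
        with pytest.raises(ValueError, match="noise_level"):
            snr_filter(small_fm, noise_level=0.0)

    def test_occurrence_kept_when_one_cell_complete(self):
        # bin 1 present in all 3 replicates of one cell; bin 2 in 2/3 everywhere
        values = np.array(
            [[5.0, 5.0], [5.0, 5.0], [5.0, 0.0], [0.0, 5.0], [0.0, 5.0], [0.0, 0.0]]
        )
        fm = _fm(values, groups=["B"] * 6, days=[1, 1, 1, 4, 4, 4])
        out, removed = occurrence_filter(fm, detection_floor=1.0)
        assert out.bin_ids == [1]
        assert removed[0]["bin_id"] == 2

    def test_blank_subtraction_and_cm_flag(self, small_fm):
        out, log = blank_subtraction(small_fm, os_bins=[3], cm_bins=[1])
        assert 3 not in out.bin_ids
        assert out.bins[0].label == "culture_medium"
        with pytest.raises(ValueError, match="unknown bin_id"):
            blank_subtraction(small_fm, os_bins=[99])

    def test_blank_subtraction_empty_is_identity(self, small_fm):
        out, log = blank_subtraction(small_fm)
        np.testing.assert_array_equal(out.values, small_fm.values)
        assert log == []


class TestRunPreprocess:
    def test_pipeline_smoke_on_synthetic(self, default_sim):
        fm_b, fm_f, _, _ = default_sim
        pooled = FeatureMatrix(
            np.vstack([fm_b.values, fm_f.values]),
            list(fm_b.samples)
            + [
                SampleMeta(s.sample_id + "_F", s.group, s.day, s.replicate)
                for s in fm_f.samples
            ],
            fm_b.bins,
        )
        noise = 0.001 * float(np.median(pooled.values))
        out, log = run_preprocess(pooled, noise_level=noise)
        assert out.stage == "autoscaled"
        assert out.n_bins <= 25
        assert len(log) >= 0
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-10)

    def test_noiseless_data_pass_rsd(self):
        from chronopls.simulate import SimConfig, simulate_dataset

        fm_b, _, _, _ = simulate_dataset(SimConfig(seed=1, replicate_cv=0.0))
        out, removed = rsd_filter(fm_b)
        assert removed == []

    def test_extreme_rsd_threshold_removes_all_noisy_bins(self, default_sim):
        """Every bin carries QC noise, so a near-zero cap empties the matrix."""
        fm_b, _, _, _ = default_sim
        cfg = PreprocessConfig(rsd_max_pct=1e-9)
        with pytest.raises(ValueError, match="empty selection"):
            rsd_filter(fm_b, cfg)

    def test_rsd_and_occurrence_commute_on_default_synthetic(self, default_sim):
        fm_b, _, _, _ = default_sim
        floor = 0.001 * float(np.median(fm_b.values))
        a = occurrence_filter(rsd_filter(fm_b)[0], floor)[0]
        b = rsd_filter(occurrence_filter(fm_b, floor)[0])[0]
        assert a.bin_ids == b.bin_ids
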