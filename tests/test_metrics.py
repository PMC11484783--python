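"""Metric definitions against brute-force and analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from eegdenoise import metrics
from eegdenoise.metrics import Band, CAP_DB, band_powers, band_snr, cc, nmse, rmse, sar
from eegdenoise.types import ArtifactKind, Segment

from conftest import make_segments


class TestNMSE:
    def test_identity_is_zero(self):
        x = np.array([1.0, -2.0, 3.0])
        assert nmse(x, x) == 0.0

    def test_hand_computed_value(self):
        # org [1,2,3], rec [1,2,4]: MSE = 1/3, ||org||^2 = 14
        assert nmse([1, 2, 3], [1, 2, 4]) == pytest.approx((1 / 3) / 14)

    def test_scale_invariance(self, rng):
        a = rng.standard_normal(256)
        b = rng.standard_normal(256)
        for c in (0.1, 3.0, 250.0):
            assert nmse(c * a, c * b) == pytest.approx(nmse(a, b), rel=1e-12)

    def test_brute_force_agreement(self, rng):
        a = rng.standard_normal(100)
        b = rng.standard_normal(100)
        expected = (np.sum((a - b) ** 2) / 100) / np.sum(a**2)
        assert nmse(a, b) == pytest.approx(expected, abs=1e-9)

    def test_all_zero_original_rejected(self):
        with pytest.raises(ValueError):
            nmse(np.zeros(5), np.ones(5))

    def test_variance_normalized_variant(self, rng):
        a = rng.standard_normal(64) + 5.0
        b = a + 0.1
        expected = (np.mean((a - b) ** 2)) / (64 * np.var(a))
        assert nmse(a, b, variance_normalized=True) == pytest.approx(expected)


class TestRMSE:
    def test_identity_and_hand_value(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([1, 2, 3], [1, 2, 4]) == pytest.approx(np.sqrt(1 / 3))

    def test_symmetry_and_triangle(self, rng):
        a, b, c = (rng.standard_normal(128) for _ in range(3))
        assert rmse(a, b) == pytest.approx(rmse(b, a), rel=1e-14)
        assert rmse(a, c) <= rmse(a, b) + rmse(b, c) + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])


class TestCC:
    def test_perfect_correlation_cases(self, rng):
        a = rng.standard_normal(50)
        assert cc(a, a) == pytest.approx(1.0)
        assert cc(a, -a) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(10_000)
        b = rng.standard_normal(10_000)
        assert abs(cc(a, b)) < 0.05

    def test_matches_textbook_formula(self, rng):
        a = rng.standard_normal(200)
        b = 0.3 * a + rng.standard_normal(200)
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert cc(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_positive_affine_invariance(self, rng):
        a = rng.standard_normal(128)
        b = rng.standard_normal(128)
        assert cc(2.5 * a + 1.0, b) == pytest.approx(cc(a, b), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cc(np.ones(10), np.arange(10.0))


class TestBandSNR:
    def test_two_tone_zero_db(self):
        # 10 Hz and 45 Hz on exact bins of a 640-sample window at 128 Hz:
        # equal amplitudes put equal power in and out of the alpha band.
        fs, n = 128, 640
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 45 * t)
        assert band_snr(x, fs, Band("Alpha", 8, 13)) == pytest.approx(0.0, abs=1e-9)

    def test_pure_tone_capped(self):
        fs, n = 128, 640
        x = np.sin(2 * np.pi * 10 * np.arange(n) / fs)
        assert band_snr(x, fs, Band("Alpha", 8, 13)) == CAP_DB

    def test_parseval_partition(self, rng):
        fs, n = 128.0, 640
        x = rng.standard_normal(n)
        p_in, p_out = band_powers(x, fs, Band("Alpha", 8, 13))
        energy_ac = np.sum(x**2) - n * np.mean(x) ** 2
        assert (p_in + p_out) / n == pytest.approx(energy_ac, rel=1e-9)

    def test_disjoint_cover_recovers_total_ac_power(self, rng):
        fs, n = 128.0, 511  # odd length: no bin sits exactly on Nyquist
        x = rng.standard_normal(n)
        cover = [Band(f"b{i}", lo, hi) for i, (lo, hi) in enumerate(
            [(1e-9, 4), (4, 8), (8, 13), (13, 30), (30, 50), (50, 64)])]
        total = sum(band_powers(x, fs, b)[0] for b in cover)
        energy_ac = (np.sum(x**2) - n * np.mean(x) ** 2) * n
        assert total == pytest.approx(energy_ac, rel=1e-9)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_snr(np.ones(64), 128.0, Band("bad", 50, 70))


class TestSAR:
    def test_null_cleaner_zero_db(self, rng):
        a = rng.standard_normal(100)
        assert sar(a, np.zeros(100)) == pytest.approx(0.0, abs=1e-12)

    def test_half_amplitude_cleaning(self, rng):
        a = rng.standard_normal(100)
        assert sar(a, a / 2) == pytest.approx(10 * np.log10(2), abs=1e-12)

    def test_perfect_cleaning_capped(self, rng):
        a = rng.standard_normal(100)
        assert sar(a, a) == CAP_DB

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            sar(np.full(10, 2.0), np.zeros(10))


finite_vec = hnp.arrays(
    np.float64, st.integers(8, 64),
    elements=st.floats(-100, 100, allow_nan=False))


@settings(max_examples=50, derandomize=True)
@given(a=finite_vec)
def test_error_metrics_vanish_only_at_identity(a):
    """NMSE and RMSE are non-negative and zero exactly when rec == org."""
    if not np.any(a):
        return
    b = a + 1.0
    assert metrics.rmse(a, a) == 0.0
    assert metrics.nmse(a, a) == 0.0
    assert metrics.rmse(a, b) > 0.0
    assert metrics.nmse(a, b) > 0.0


@settings(max_examples=50, derandomize=True)
@given(a=finite_vec, scale=st.floats(0.01, 100))
def test_cc_bounded_and_scale_stable(a, scale):
    if np.std(a) == 0:
        return
    b = np.sin(np.arange(a.size))
    r = metrics.cc(a, b)
    assert -1.0 <= r <= 1.0
    assert metrics.cc(scale * a, b) == pytest.approx(r, abs=1e-9)


class TestEvaluate:
    def _triples(self, n_electrodes=32, per_electrode=2, seed=0):
        channels = [f"E{i:02d}" for i in range(n_electrodes)]
        n = n_electrodes * per_electrode
        orig = make_segments(n, length=256, channels=channels, seed=seed)
        rng = np.random.default_rng(seed + 1)
        wav = [s.with_data(s.x + 0.1 * rng.standard_normal(len(s)))
               for s in orig]
        mod = [s.with_data(s.x) for s in orig]
        return orig, wav, mod

    def test_perfect_model_columns(self):
        orig, wav, mod = self._triples(n_electrodes=4)
        report = metrics.evaluate(orig, wav, mod)
        assert np.allclose(report.per_electrode["nmse_model"], 0.0)
        assert np.allclose(report.per_electrode["rmse_model"], 0.0)
        assert np.allclose(report.per_electrode["cc_model"], 1.0)
        # perfect cleaning trips the SAR guard and is flagged
        assert all(f[1] == "sar_model" for f in report.flagged)

    def test_thirty_two_electrode_table_layout(self):
        orig, wav, mod = self._triples(n_electrodes=32)
        report = metrics.evaluate(orig, wav, mod)
        table = report.electrode_table()
        assert len(table) == 33 and table.index[-1] == "Mean"
        assert list(report.band_snr.index) == ["Theta", "Alpha", "Beta", "Gamma"]

    def test_mean_row_is_arithmetic_mean(self):
        orig, wav, mod = self._triples(n_electrodes=8)
        report = metrics.evaluate(orig, wav, mod)
        table = report.electrode_table()
        expected = report.per_electrode.mean(axis=0)
        assert np.allclose(table.loc["Mean"], expected, atol=1e-12)

    def test_misaligned_inputs_rejected(self):
        orig, wav, mod = self._triples(n_electrodes=2)
        with pytest.raises(ValueError):
            metrics.evaluate(orig, wav, mod[:-1])
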