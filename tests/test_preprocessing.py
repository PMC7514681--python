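import numpy as np
import pytest
from scipy import signal as sps

from nirsmse import (
    CohortSpec,
    FilterSpec,
    bandpass_filter,
    detrend_linear,
    fit_sbf,
    generate_cohort,
    preprocess_session,
    remove_sbf,
)


def butter_gain(freq_hz: float, fs: float, spec: FilterSpec) -> float:
    """Analytic magnitude response oracle (squared when zero-phase)."""
    b, a = sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs)
    _, h = sps.freqz(b, a, worN=[freq_hz], fs=fs)
    g = float(np.abs(h[0]))
    return g * g if spec.zero_phase else g


class TestBandpass:
    def test_zero_input(self):
        out = bandpass_filter(np.zeros(1000), 10.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_passband_rms(self):
        t = np.arange(6000) / 10.0
        x = np.sin(2 * np.pi * 0.1 * t)
        y = bandpass_filter(x, 10.0)
        rms_ratio = np.sqrt(np.mean(y**2)) / np.sqrt(np.mean(x**2))
        assert rms_ratio == pytest.approx(1.0, abs=0.25)
        # and it matches the analytic response oracle
        assert rms_ratio == pytest.approx(butter_gain(0.1, 10.0, FilterSpec()), abs=0.02)

    def test_stopband_below_passband(self):
        t = np.arange(6000) / 10.0
        y_pass = bandpass_filter(np.sin(2 * np.pi * 0.1 * t), 10.0)
        y_stop = bandpass_filter(np.sin(2 * np.pi * 2.0 * t), 10.0)
        assert np.sqrt(np.mean(y_stop**2)) < np.sqrt(np.mean(y_pass**2))

    def test_analytic_ordering(self):
        spec = FilterSpec()
        assert butter_gain(2.0, 10.0, spec) < butter_gain(0.1, 10.0, spec)

    def test_too_short_names_minimum(self):
        with pytest.raises(ValueError, match="minimum"):
            bandpass_filter(np.ones(5), 10.0)

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.ones(1000), 10.0, FilterSpec(low_hz=0.5, high_hz=0.1))
        with pytest.raises(ValueError):
            bandpass_filter(np.ones(1000), 1.0, FilterSpec(high_hz=0.6))

    def test_matrix_input(self, rng):
        x = rng.normal(size=(4, 500))
        y = bandpass_filter(x, 10.0)
        assert y.shape == x.shape
        np.testing.assert_allclose(y[2], bandpass_filter(x[2], 10.0))

    def test_causal_mode(self, rng):
        x = rng.normal(size=500)
        y = bandpass_filter(x, 10.0, FilterSpec(zero_phase=False))
        assert y.shape == x.shape
        assert not np.allclose(y, bandpass_filter(x, 10.0))


class TestDetrend:
    def test_exact_line_removal(self):
        t = np.arange(200.0)
        out = detrend_linear(3.0 * t + 5.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_noise_residual_is_line(self, rng):
        x = rng.normal(size=300)
        out = detrend_linear(x)
        resid = x - out
        # the removed part is exactly a line: second differences vanish
        np.testing.assert_allclose(np.diff(resid, 2), 0.0, atol=1e-9)
        # fitted line of the output is ~0
        coef = np.polyfit(np.arange(300), out, 1)
        np.testing.assert_allclose(coef, 0.0, atol=1e-9)

    def test_length_one_error(self):
        with pytest.raises(ValueError):
            detrend_linear(np.array([1.0]))


class TestFitSbf:
    def test_duplicated_channel_symmetry(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=600)
        rest = np.vstack([base, base, rng.normal(size=600) * 0.01])
        model = fit_sbf(rest, 1)
        v = model.component_vectors[:, 0]
        assert abs(v[0]) == pytest.approx(abs(v[1]), abs=1e-6)

    def test_zero_components(self, rng):
        model = fit_sbf(rng.normal(size=(4, 100)), 0)
        assert model.component_vectors.shape == (4, 0)

    def test_matches_eigh_oracle(self, rng):
        rest = rng.normal(size=(4, 600))
        model = fit_sbf(rest, 3)
        centered = rest - rest.mean(axis=1, keepdims=True)
        cov = centered @ centered.T / rest.shape[1]
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1][:3]
        for k, idx in enumerate(order):
            got = model.component_vectors[:, k]
            ref = v[:, idx]
            assert abs(abs(got @ ref) - 1.0) < 1e-9  # equal up to sign

    def test_orthonormal(self, rng):
        model = fit_sbf(rng.normal(size=(4, 300)), 3)
        v = model.component_vectors
        np.testing.assert_allclose(v.T @ v, np.eye(3), atol=1e-10)

    def test_too_many_components(self, rng):
        with pytest.raises(ValueError):
            fit_sbf(rng.normal(size=(4, 100)), 5)


class TestRemoveSbf:
    def test_zero_components_identity(self, rng):
        task = rng.normal(size=(4, 200))
        model = fit_sbf(rng.normal(size=(4, 100)), 0)
        np.testing.assert_array_equal(remove_sbf(task, model), task)

    def test_full_projection_of_spanned_data(self, rng):
        rest = rng.normal(size=(4, 600))
        model = fit_sbf(rest, 3)
        v = model.component_vectors
        coeffs = rng.normal(size=(3, 150))
        task = v @ coeffs + model.channel_means[:, None]
        out = remove_sbf(task, model)
        np.testing.assert_allclose(out - model.channel_means[:, None], 0.0, atol=1e-9)

    def test_matches_projector_oracle(self, rng):
        rest = rng.normal(size=(4, 500))
        task = rng.normal(size=(4, 300))
        model = fit_sbf(rest, 3)
        v = model.component_vectors
        centered = task - model.channel_means[:, None]
        oracle = (np.eye(4) - v @ v.T) @ centered + model.channel_means[:, None]
        np.testing.assert_allclose(remove_sbf(task, model), oracle, atol=1e-10)

    def test_idempotent(self, rng):
        rest = rng.normal(size=(4, 500))
        task = rng.normal(size=(4, 300))
        model = fit_sbf(rest, 2)
        once = remove_sbf(task, model)
        twice = remove_sbf(once, model)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_output_projection_is_zero(self, rng):
        rest = rng.normal(size=(4, 500))
        task = rng.normal(size=(4, 300))
        model = fit_sbf(rest, 3)
        out = remove_sbf(task, model)
        proj = model.component_vectors.T @ (out - model.channel_means[:, None])
        np.testing.assert_allclose(proj, 0.0, atol=1e-9)

    def test_energy_never_increases(self, rng):
        for _ in range(5):
            rest = rng.normal(size=(4, 400))
            task = rng.normal(size=(4, 250))
            model = fit_sbf(rest, 3)
            out = remove_sbf(task, model)
            c_in = task - model.channel_means[:, None]
            c_out = out - model.channel_means[:, None]
            assert np.sum(c_out**2) <= np.sum(c_in**2) + 1e-9

    def test_channel_mismatch(self, rng):
        model = fit_sbf(rng.normal(size=(4, 100)), 2)
        with pytest.raises(ValueError):
            remove_sbf(rng.normal(size=(3, 100)), model)


class TestPreprocessSession:
    def test_sbf_stage_identity_with_zero_components(self):
        spec = CohortSpec(n_participants=2, sbf_rank=0, sbf_amplitude=0.0,
                          artifact_amplitudes={}, seed=5)
        session = generate_cohort(spec)[0]
        full = preprocess_session(session, n_components=0)
        # with n_components=0 the SBF stage is the exact identity:
        # output == filtered + detrended input
        from nirsmse.preprocessing import bandpass_filter, detrend_linear

        ref = detrend_linear(bandpass_filter(session.task, 10.0))
        np.testing.assert_allclose(full.task, ref, atol=1e-10)

    def test_projection_energy_on_sbf_free_data(self):
        # On data with no shared component, projecting out 3 of 4 spatial
        # dimensions removes ~3/4 of the (centered) energy: the stage is
        # NOT near-identity with the default component count.
        spec = CohortSpec(n_participants=2, sbf_rank=0, sbf_amplitude=0.0,
                          artifact_amplitudes={}, seed=5)
        session = generate_cohort(spec)[0]
        full = preprocess_session(session, n_components=0)
        with_proj = preprocess_session(session, n_components=3)
        kept = np.sum(with_proj.task**2) / np.sum(full.task**2)
        assert kept == pytest.approx(0.25, abs=0.12)

    def test_sbf_removal_reduces_interchannel_correlation(self):
        # Removing all channels-1 components leaves a rank-1 residual whose
        # channels are perfectly correlated, so the correlation-decrease
        # property is only meaningful with n_components < channels-1.
        spec = CohortSpec(n_participants=2, sbf_amplitude=6.0, sbf_rank=2, seed=9)
        session = generate_cohort(spec)[0]
        before = preprocess_session(session, n_components=0)
        after = preprocess_session(session, n_components=2)

        def mean_abs_corr(mat):
            cm = np.corrcoef(mat)
            return np.abs(cm[np.triu_indices(4, 1)]).mean()

        assert mean_abs_corr(after.task) < mean_abs_corr(before.task)

    def test_deterministic(self, small_spec):
        session = generate_cohort(small_spec)[0]
        a = preprocess_session(session)
        b = preprocess_session(session)
        np.testing.assert_array_equal(a.task, b.task)
        np.testing.assert_array_equal(a.rest, b.rest)

    def test_no_nan_inf(self, small_spec):
        session = generate_cohort(small_spec)[0]
        out = preprocess_session(session)
        assert np.all(np.isfinite(out.task)) and np.all(np.isfinite(out.rest))

    def test_empty_task_error(self, small_spec):
        import dataclasses

        session = generate_cohort(small_spec)[0]
        broken = dataclasses.replace(
            session, task=np.empty((4, 0)), rest=session.rest
        )
        with pytest.raises(ValueError):
            preprocess_session(broken)
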