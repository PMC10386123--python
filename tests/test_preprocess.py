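"""Filtering, beat-detection, and EDA-decomposition tests.

The decomposition is checked against an independent dense oracle: the same
convex objective assembled as an explicit matrix and solved exactly by a
Lawson-Hanson active-set iteration.
"""

import numpy as np
import pytest

from cogload import preprocess
from cogload.preprocess import (ParameterError, bandpass,
                                accel_magnitude, decompose_eda, detect_beats,
                                phasic_from_driver, scr_kernel)

FS = 51.2


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

class TestBandpass:
    def test_stopband_attenuation_exceeds_20db(self):
        t = np.arange(0, 120, 1 / FS)
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x, 0.5, 8.0, fs=FS)
        core = slice(int(20 * FS), int(100 * FS))
        assert np.max(np.abs(y[core])) < 0.1  # > 20 dB down

    def test_passband_preserved_within_1pc(self):
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 2.0 * t)
        y = bandpass(x, 0.5, 8.0, fs=FS)
        core = slice(int(10 * FS), int(50 * FS))
        assert np.max(np.abs(y[core])) == pytest.approx(1.0, rel=0.01)

    def test_zero_signal_maps_to_zero(self):
        assert np.allclose(bandpass(np.zeros(1000), 0.5, 8.0, fs=FS), 0.0)

    @pytest.mark.parametrize("low,high", [(0.0, 8.0), (8.0, 0.5), (0.5, 30.0)])
    def test_invalid_band_rejected(self, low, high):
        with pytest.raises(ParameterError):
            bandpass(np.zeros(100), low, high, fs=FS)

    def test_zero_phase_impulse_train(self):
        x = np.zeros(int(30 * FS))
        x[int(5 * FS)::int(FS)] = 1.0
        y = bandpass(x, 0.5, 8.0, fs=FS)
        xc = np.correlate(y - y.mean(), x - x.mean(), mode="full")
        lag = int(np.argmax(xc)) - (len(x) - 1)
        assert lag == 0


class TestAccelMagnitude:
    def test_pythagorean(self):
        n = 16
        out = accel_magnitude(np.full(n, 3.0), np.full(n, 4.0), np.zeros(n))
        assert np.allclose(out, 5.0)

    def test_zero_axes(self):
        assert np.allclose(accel_magnitude(*(np.zeros(8),) * 3), 0.0)

    def test_axis_permutation_symmetry(self, rng):
        a, b, c = rng.normal(size=(3, 64))
        np.testing.assert_allclose(accel_magnitude(a, b, c),
                                   accel_magnitude(c, a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accel_magnitude(np.zeros(4), np.zeros(5), np.zeros(4))


# ---------------------------------------------------------------------------
# Beat detection
# ---------------------------------------------------------------------------

def _pulse_train(beat_times, duration, fs=FS):
    t = np.arange(0, duration, 1 / fs)
    x = np.zeros_like(t)
    for tb in beat_times:
        x += np.exp(-0.5 * ((t - tb) / 0.06) ** 2)
    return x


class TestDetectBeats:
    def test_steady_60bpm_all_within_half_bpm(self):
        beats = np.arange(0.5, 119.5, 1.0)
        x = _pulse_train(beats, 120.0)
        b = detect_beats(x, FS)
        assert len(b.hr) >= len(beats) - 2
        assert np.all(np.abs(b.hr - 60.0) < 0.5)

    def test_ectopic_peak_rejected_by_10pc_rule(self):
        beats = list(np.arange(0.5, 30.5, 1.0))
        beats.append(10.0)  # ectopic halfway through an interval
        x = _pulse_train(sorted(beats), 31.0)
        b = detect_beats(x, FS)
        ect_idx = int(round(10.0 * FS))
        dist = np.abs(b.peak_indices - ect_idx)
        assert dist.min() < 5  # the ectopic was a candidate...
        assert not b.accepted[int(np.argmin(dist))]  # ...but not a heartbeat
        assert np.all(np.abs(b.hr - 60.0) < 1.0)

    def test_constant_signal_yields_empty_series(self):
        b = detect_beats(np.full(1024, 3.3), FS)
        assert len(b) == 0 and len(b.hr) == 0

    def test_single_peak_yields_empty_series(self):
        x = np.zeros(1024)
        x[500] = 1.0
        assert len(detect_beats(x, FS).hr) == 0

    def test_accepted_interval_chain_invariant(self):
        # consecutive accepted intervals obey the 10% rule by construction
        rng = np.random.default_rng(3)
        beats = np.cumsum(0.9 + rng.normal(0, 0.015, 130))
        x = _pulse_train(beats, float(beats[-1] + 1))
        b = detect_beats(x, FS)
        consec = np.abs(np.diff(b.ibi)) <= 0.10 * b.ibi[:-1] + 1e-12
        # rejections may interrupt the chain; the rule holds wherever the
        # closing peak of one interval opens the next
        closing = b.hr_times[:-1]
        opening = b.hr_times[1:] - b.ibi[1:]
        contiguous = np.abs(closing - opening) < 1e-9
        assert np.all(consec[contiguous])

    def test_acceptance_idempotent_on_clean_train(self):
        beats = np.arange(0.5, 60.5, 0.8)
        x = _pulse_train(beats, 61.0)
        b1 = detect_beats(x, FS)
        assert bool(b1.accepted.all())
        x2 = _pulse_train(b1.accepted_times, 61.0)
        b2 = detect_beats(x2, FS)
        np.testing.assert_array_equal(b1.peak_indices[b1.accepted],
                                      b2.peak_indices[b2.accepted])

    def test_hr_equals_60_over_ibi(self):
        beats = np.arange(0.5, 40.5, 0.75)
        b = detect_beats(_pulse_train(beats, 41.0), FS)
        np.testing.assert_allclose(b.hr, 60.0 / b.ibi)


# ---------------------------------------------------------------------------
# EDA decomposition
# ---------------------------------------------------------------------------

def _dense_oracle(y, fs, alpha, gamma, knot_spacing, tol=1e-10):
    """Same objective assembled densely, solved exactly by a Lawson-Hanson
    active-set iteration (KKT point of the bound-constrained quadratic)."""
    n = len(y)
    K = np.column_stack([
        phasic_from_driver(np.eye(n)[:, j], fs) for j in range(n)])
    B = preprocess._spline_basis(n, fs, knot_spacing).toarray()
    t = np.arange(n) / fs
    C = np.column_stack([np.ones(n), t / t[-1]])
    nl = B.shape[1]
    A = np.hstack([K, B, C])
    nvar = A.shape[1]
    reg = np.r_[np.zeros(n), 2 * gamma * np.ones(nl), np.zeros(2)]
    H = A.T @ A + np.diag(reg)
    b = A.T @ y - np.r_[alpha * np.ones(n), np.zeros(nl + 2)]

    free = list(range(n, nvar))          # spline + drift: never bound
    passive = []                          # driver support
    x = np.zeros(nvar)

    def solve_on(support):
        z = np.zeros(nvar)
        idx = np.array(support)
        z[idx] = np.linalg.solve(H[np.ix_(idx, idx)], b[idx])
        return z

    x = solve_on(free)
    for _ in range(4 * n):
        w = b - H @ x                     # negative gradient
        candidates = [j for j in range(n) if j not in passive]
        if not candidates:
            break
        j = max(candidates, key=lambda k: w[k])
        if w[j] <= tol:
            break
        passive.append(j)
        z = solve_on(passive + free)
        while True:
            neg = [k for k in passive if z[k] <= 0.0]
            if not neg:
                break
            step = min((x[k] / (x[k] - z[k]) for k in neg), default=0.0)
            x = x + step * (z - x)
            passive = [k for k in passive if x[k] > tol]
            z = solve_on(passive + free)
        x = z
    q = np.maximum(x[:n], 0.0)
    tonic = B @ x[n:n + nl] + C @ x[n + nl:]
    phasic = K @ q
    return q, tonic, phasic


class TestDecomposeEda:
    def test_zero_input_gives_zero_components(self):
        eda = decompose_eda(np.zeros(int(30 * FS)), FS)
        assert np.allclose(eda.tonic, 0) and np.allclose(eda.phasic, 0)
        assert np.allclose(eda.smna, 0) and np.allclose(eda.residual, 0)

    def test_reconstruction_is_exact_identity(self, rng):
        for _ in range(5):
            y = 2 + 0.3 * rng.random() + np.abs(
                np.cumsum(rng.normal(0, 1e-3, int(40 * FS))))
            eda = decompose_eda(y, FS)
            np.testing.assert_allclose(eda.tonic + eda.phasic + eda.residual,
                                       y, atol=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            decompose_eda(np.full(2048, -1.0), FS)

    def test_nonfinite_input_rejected(self):
        y = np.ones(2048)
        y[5] = np.nan
        with pytest.raises(ValueError):
            decompose_eda(y, FS)

    def test_linear_ramp_with_large_alpha_is_all_tonic(self):
        t = np.arange(0, 60, 1 / FS)
        y = 1.0 + 0.01 * t
        eda = decompose_eda(y, FS, alpha=1.0)
        assert np.max(eda.smna) < 1e-6
        # oracle: unpenalised least-squares fit of the tonic basis alone
        n = len(y) // 4
        yd = y[:n * 4].reshape(n, 4).mean(axis=1)
        B = preprocess._spline_basis(n, FS / 4, 10.0).toarray()
        td = np.arange(n) / (FS / 4)
        A = np.hstack([B, np.column_stack([np.ones(n), td / td[-1]])])
        fit = A @ np.linalg.lstsq(A, yd, rcond=None)[0]
        ton = eda.tonic[: n * 4].reshape(n, 4).mean(axis=1)
        np.testing.assert_allclose(ton, fit, atol=5e-3)
        np.testing.assert_allclose(eda.tonic, y, atol=0.02)

    def test_single_scr_localised_within_1s(self):
        n = int(90 * FS)
        driver = np.zeros(n)
        driver[int(30 * FS)] = 0.5
        y = 2.0 + np.convolve(driver, scr_kernel(FS))[:n]
        eda = decompose_eda(y, FS)
        assert abs(np.argmax(eda.smna) / FS - 30.0) < 1.0

    def test_driver_nonnegative_and_phasic_nonnegative(self, rng):
        y = 2.0 + np.abs(rng.normal(0, 0.02, int(45 * FS)))
        eda = decompose_eda(y, FS)
        assert eda.smna.min() >= 0.0
        assert eda.phasic.min() >= 0.0

    def test_driver_sparsity_under_strong_penalty(self):
        n = int(120 * FS)
        driver = np.zeros(n)
        for on in (20.0, 55.0, 90.0):
            driver[int(on * FS)] = 0.4
        rng = np.random.default_rng(1)
        y = 2.0 + np.convolve(driver, scr_kernel(FS))[:n] \
            + rng.normal(0, 0.003, n)
        y = np.clip(y, 0, None)
        eda = decompose_eda(y, FS, alpha=8e-3)
        assert np.mean(eda.smna > 0) < 0.05

    def test_qp_matches_dense_oracle_on_30s_toy(self):
        fs = 12.8
        n = int(30 * fs)
        rng = np.random.default_rng(5)
        driver = np.zeros(n)
        driver[int(8 * fs)] = 0.4
        driver[int(19 * fs)] = 0.25
        y = 1.5 + 0.003 * np.arange(n) / fs \
            + phasic_from_driver(driver, fs) + rng.normal(0, 0.004, n)
        q, tonic, phasic, status, _ = preprocess._solve_qp(
            y, fs, 8e-4, 1e-2, 10.0, 0.7, 2.0, maxiter=60000, tol=1e-12)
        assert status == "converged"
        q_o, tonic_o, phasic_o = _dense_oracle(y, fs, 8e-4, 1e-2, 10.0)
        np.testing.assert_allclose(phasic, phasic_o, atol=1e-4)
        np.testing.assert_allclose(tonic, tonic_o, atol=1e-4)

    def test_solver_reports_convergence(self):
        y = 2.0 + np.zeros(int(20 * FS))
        eda = decompose_eda(y, FS)
        assert eda.solver_status == "converged"


class TestSmnaEventCount:
    def test_zero_driver_counts_zero(self):
        assert preprocess.smna_event_count(np.zeros(1000), FS) == 0

    def test_two_separated_events(self):
        q = np.zeros(int(10 * FS))
        q[int(2 * FS)] = 0.5
        q[int(7 * FS)] = 0.5
        assert preprocess.smna_event_count(q, FS) == 2

    def test_close_events_merge(self):
        q = np.zeros(int(10 * FS))
        q[int(2.0 * FS)] = 0.5
        q[int(2.5 * FS)] = 0.5
        assert preprocess.smna_event_count(q, FS) == 1
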