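"""Band coherence: oracle equivalence, closed forms, split halves, band power.

The brute-force oracle below re-implements band-averaged magnitude-squared
coherence with explicit DFT sums over pairs — an independent code path from
the vectorised rFFT implementation it checks.
"""

import numpy as np
import pytest

from ecogplast.core_io import Recording, ValidationError
from ecogplast.coherence import (
    band_power,
    band_summary,
    coherence_matrix,
    make_bands,
    split_half_coherence,
)

from conftest import make_channels, make_recording

FS = 1000.0


def brute_force_band_coherence(data, fs, window_s, bands):
    """Direct-DFT band coherence: per pair, per bin, naive summation."""
    n = int(round(window_s * fs))
    n_ch = data.shape[0]
    n_win = data.shape[1] // n
    m = np.arange(n)
    taper = 0.54 - 0.46 * np.cos(2 * np.pi * m / n)  # periodic hamming
    freqs = np.arange(n // 2 + 1) * fs / n
    # explicit DFT per window/channel
    X = np.empty((n_win, n_ch, freqs.size), dtype=complex)
    for w in range(n_win):
        for c in range(n_ch):
            seg = data[c, w * n : (w + 1) * n].astype(np.float64)
            seg = (seg - seg.mean()) * taper
            for k in range(freqs.size):
                X[w, c, k] = np.sum(seg * np.exp(-2j * np.pi * k * m / n))
    C = np.zeros((n_ch, n_ch, len(bands)))
    for b, (lo, hi) in enumerate(bands):
        bins = [k for k in range(freqs.size) if lo <= freqs[k] < hi and freqs[k] > 0]
        for i in range(n_ch):
            for j in range(n_ch):
                vals = []
                for k in bins:
                    gxy = np.mean(X[:, i, k] * np.conj(X[:, j, k]))
                    gxx = np.mean(np.abs(X[:, i, k]) ** 2)
                    gyy = np.mean(np.abs(X[:, j, k]) ** 2)
                    vals.append(np.abs(gxy) ** 2 / (gxx * gyy))
                C[i, j, b] = np.mean(vals)
        np.fill_diagonal(C[:, :, b], 1.0)
    return C


class TestOracleEquivalence:
    def test_matches_brute_force_dft(self):
        """4-channel 30 s fixture: vectorised path == naive DFT within 1e-10."""
        rec = make_recording(n_channels=4, duration=30.0, seed=9)
        bands = make_bands(4.0, 12.0)
        C = coherence_matrix(rec, window_s=10.0, band_hz=4.0, fmax=12.0)
        ref = brute_force_band_coherence(rec.data, FS, 10.0, bands)
        np.testing.assert_allclose(C.C, ref, atol=1e-10)


class TestClosedForms:
    def test_self_coherence_unity(self, small_recording):
        rec = make_recording(n_channels=3, duration=25.0)
        C = coherence_matrix(rec, window_s=10.0, fmax=20.0)
        for b in range(len(C.bands)):
            np.testing.assert_array_equal(np.diag(C.C[:, :, b]), 1.0)

    def test_pure_delay_copy_keeps_unit_coherence(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40_000)
        data = np.vstack([x[10:30_010], x[:30_000]])  # 10 ms delayed copy
        rec = Recording(data=data, fs=FS, channels=make_channels(2))
        C = coherence_matrix(rec, window_s=10.0, fmax=100.0)
        th = band_summary(C, (4.0, 8.0))
        assert th[0, 1] > 0.98
        mid = band_summary(C, (40.0, 44.0))
        assert mid[0, 1] > 0.98

    def test_independent_noise_hits_analytic_bias_floor(self):
        """E[coherence] of independent signals with L windows is 1/L."""
        rec = make_recording(n_channels=4, duration=100.0, seed=11)
        C = coherence_matrix(rec, window_s=10.0, fmax=500.0)
        L = C.n_windows
        iu = np.triu_indices(4, 1)
        mean_coh = np.array([C.C[:, :, b][iu].mean() for b in range(len(C.bands))]).mean()
        assert mean_coh == pytest.approx(1.0 / L, rel=0.05)

    def test_single_window_rejected(self):
        rec = make_recording(duration=12.0)
        with pytest.raises(ValidationError):
            coherence_matrix(rec, window_s=10.0)


class TestInvariances:
    def test_gain_and_sign_invariance(self):
        rec = make_recording(n_channels=3, duration=25.0, seed=5)
        C1 = coherence_matrix(rec, fmax=20.0)
        scaled = Recording(
            data=rec.data.astype(np.float64) * np.array([[2.5], [-1.0], [0.3]]),
            fs=FS, channels=rec.channels,
        )
        C2 = coherence_matrix(scaled, fmax=20.0)
        np.testing.assert_allclose(C1.C, C2.C, atol=1e-7)

    def test_symmetry_and_bounds(self):
        rec = make_recording(n_channels=4, duration=30.0, seed=6)
        C = coherence_matrix(rec, fmax=100.0)
        assert (C.C >= 0).all() and (C.C <= 1).all()
        np.testing.assert_array_equal(C.C, C.C.transpose(1, 0, 2))


class TestBandSummary:
    def test_theta_is_second_band(self):
        rec = make_recording(duration=25.0)
        C = coherence_matrix(rec, fmax=12.0)
        assert C.bands[1] == (4.0, 8.0)
        np.testing.assert_array_equal(band_summary(C, (4.0, 8.0)), C.C[:, :, 1])

    def test_misaligned_band_rejected(self):
        rec = make_recording(duration=25.0)
        C = coherence_matrix(rec, fmax=12.0)
        with pytest.raises(ValidationError):
            band_summary(C, (5.0, 9.0))

    def test_theta_coupled_pair_peaks_in_theta(self):
        rng = np.random.default_rng(7)
        n = 100_000
        shared = rng.standard_normal(n + 4000)
        from scipy import signal as sps

        sos = sps.butter(4, [5.0 / 500, 7.0 / 500], btype="band", output="sos")
        s6 = sps.sosfiltfilt(sos, shared)[2000:-2000]
        s6 /= s6.std()
        data = np.vstack([
            s6 + 0.7 * rng.standard_normal(n),
            s6 + 0.7 * rng.standard_normal(n),
        ])
        rec = Recording(data=data, fs=FS, channels=make_channels(2))
        C = coherence_matrix(rec, fmax=60.0)
        theta = band_summary(C, (4.0, 8.0))[0, 1]
        others = [C.C[0, 1, b] for b, band in enumerate(C.bands) if band != (4.0, 8.0)]
        assert theta > max(others)


class TestSplitHalf:
    def test_20s_gives_two_windows_per_parity(self):
        rec = make_recording(duration=20.0)
        sp = split_half_coherence(rec)
        assert sp.C_alpha.n_windows == 2
        assert sp.C_beta.n_windows == 2

    def test_too_short_rejected(self):
        rec = make_recording(duration=15.0)
        with pytest.raises(ValidationError):
            split_half_coherence(rec)

    def test_halves_agree_on_stationary_data_and_converge(self):
        from ecogplast.synthetic import NetworkConfig, generate_baseline

        cfg = NetworkConfig.default(n_channels=4)
        diffs = []
        for dur in (40.0, 160.0):
            rec = generate_baseline(cfg, dur, seed=3)
            sp = split_half_coherence(rec, fmax=8.0)
            a = band_summary(sp.C_alpha, (4.0, 8.0))
            b = band_summary(sp.C_beta, (4.0, 8.0))
            iu = np.triu_indices(4, 1)
            diffs.append(np.abs(a[iu] - b[iu]).mean())
        assert diffs[1] < diffs[0]  # sampling error shrinks with length

    def test_split_noise_uncorrelated_across_seeds(self):
        """Alpha/beta estimation errors are uncorrelated on stationary data."""
        from ecogplast.synthetic import NetworkConfig, generate_baseline

        cfg = NetworkConfig.default(n_channels=4)
        iu = np.triu_indices(4, 1)
        errs_a, errs_b = [], []
        truth = None
        for s in range(30):
            rec = generate_baseline(cfg, 40.0, seed=100 + s)
            sp = split_half_coherence(rec, fmax=8.0)
            a = band_summary(sp.C_alpha, (4.0, 8.0))[iu]
            b = band_summary(sp.C_beta, (4.0, 8.0))[iu]
            errs_a.append(a)
            errs_b.append(b)
        A = np.array(errs_a)
        B = np.array(errs_b)
        # per-pair correlation of (alpha - mean) with (beta - mean) over seeds
        rs = []
        for p in range(A.shape[1]):
            rs.append(np.corrcoef(A[:, p], B[:, p])[0, 1])
        assert abs(np.mean(rs)) < 0.25


class TestExport:
    def test_hdf5_round_trip(self, tmp_path):
        from ecogplast.coherence import coherence_from_hdf5, coherence_to_hdf5

        rec = make_recording(n_channels=3, duration=25.0, seed=8)
        C = coherence_matrix(rec, fmax=12.0)
        path = tmp_path / "coh.h5"
        coherence_to_hdf5(C, path)
        C2 = coherence_from_hdf5(path)
        np.testing.assert_array_equal(C.C, C2.C)
        assert C2.bands == C.bands
        assert C2.channel_ids == C.channel_ids

    def test_long_format_frame(self):
        from ecogplast.coherence import coherence_to_frame

        rec = make_recording(n_channels=3, duration=25.0, seed=8)
        C = coherence_matrix(rec, fmax=8.0)
        df = coherence_to_frame(C)
        assert set(df.columns) == {"chan_i", "chan_j", "band_low", "band_high", "value"}
        assert len(df) == 3 * 2 * len(C.bands) / 2  # upper-triangle pairs x bands


class TestBandPower:
    def test_unit_sine_half_power(self):
        t = np.arange(30_000) / FS
        data = np.sin(2 * np.pi * 6.0 * t)[None, :]
        rec = Recording(data=data, fs=FS, channels=make_channels(1))
        p = band_power(rec, (4.0, 8.0))
        assert p[0] == pytest.approx(0.5, rel=0.05)

    def test_quadratic_in_amplitude(self):
        t = np.arange(30_000) / FS
        one = Recording(data=np.sin(2 * np.pi * 6.0 * t)[None, :], fs=FS,
                        channels=make_channels(1))
        two = Recording(data=2 * np.sin(2 * np.pi * 6.0 * t)[None, :], fs=FS,
                        channels=make_channels(1))
        assert band_power(two, (4.0, 8.0))[0] == pytest.approx(
            4 * band_power(one, (4.0, 8.0))[0], rel=1e-6
        )
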