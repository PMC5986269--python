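"""Pairwise magnitude-squared coherence in contiguous frequency bands.

Coherence between channels x and y is C_xy(f) = |G_xy(f)|^2 / (G_xx(f) G_yy(f)),
with spectral densities estimated by averaging Hamming-tapered periodograms
over non-overlapping windows (10 s by default).  Coherence is computed per
FFT bin and then averaged within half-open 4 Hz bands; the theta band
[4, 8) Hz carries the analyses of interest.

The odd/even split-half estimator (`split_half_coherence`) produces two
independent baseline-coherence estimates from alternating 5 s windows; this
is what removes regression-to-the-mean bias from the Hebbian regression in
`ecogplast.stats`.

Estimator bias: with L independent windows, the expected coherence of two
independent signals is 1/L (the squared sample correlation of two
independent complex L-vectors), so estimates from few windows sit on a
noise floor that cancels only in differences of like-for-like estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from ecogplast.core_io import Recording, ValidationError


@dataclass
class CoherenceMatrix:
    """channels x channels x bands coherence with its estimation parameters.

    ``channel_ids`` maps matrix rows to channel ids (good channels only).
    Bands are half-open ``[low, high)`` and contiguous.
    """

    C: np.ndarray
    bands: list[tuple[float, float]]
    window_s: float
    n_windows: int
    channel_ids: list[int]

    def band_index(self, band: tuple[float, float]) -> int:
        for i, b in enumerate(self.bands):
            if np.isclose(b[0], band[0]) and np.isclose(b[1], band[1]):
                return i
        raise ValidationError(f"band {band} not aligned with stored bands {self.bands}")

    def pair_value(self, i: int, j: int, band: tuple[float, float]) -> float:
        return float(self.C[i, j, self.band_index(band)])


@dataclass
class SplitCoherence:
    """Independent odd(alpha)/even(beta) window coherence estimates."""

    C_alpha: CoherenceMatrix
    C_beta: CoherenceMatrix
    parity: str = "alpha=windows 1,3,5,... (1-based); beta=windows 2,4,6,..."


def _window_ffts(data: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Hamming-tapered rFFTs of non-overlapping windows: (n_win, n_ch, n_freq).

    Each window is demeaned before tapering (the DC bin is excluded from
    band averaging regardless).
    """
    data = np.asarray(data, dtype=np.float64)
    n = int(round(window_s * fs))
    n_win = data.shape[1] // n
    if n_win < 1:
        raise ValidationError(f"segment shorter than one {window_s} s window")
    taper = sps.get_window("hamming", n, fftbins=True)
    segs = data[:, : n_win * n].reshape(data.shape[0], n_win, n)
    segs = segs - segs.mean(axis=2, keepdims=True)
    return np.fft.rfft(segs * taper, axis=2).transpose(1, 0, 2)


def _band_bins(n: int, fs: float, bands: list[tuple[float, float]]) -> list[np.ndarray]:
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    out = []
    for low, high in bands:
        idx = np.flatnonzero((freqs >= low) & (freqs < high))
        idx = idx[freqs[idx] > 0]  # DC never contributes
        out.append(idx)
    return out


def make_bands(band_hz: float, fmax: float) -> list[tuple[float, float]]:
    """Contiguous half-open bands [0,b), [b,2b), ... up to fmax."""
    edges = np.arange(0.0, fmax + 0.5 * band_hz, band_hz)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(len(edges) - 1)]


def _coherence_from_ffts(
    X: np.ndarray, bin_sets: list[np.ndarray]
) -> np.ndarray:
    """Band-averaged magnitude-squared coherence from windowed FFTs.

    X: (n_win, n_ch, n_freq).  Per bin, averages the cross- and
    auto-spectra over windows, forms |Gxy|^2/(Gxx Gyy), then averages the
    bins within each band.
    """
    n_win, n_ch, _ = X.shape
    if n_win < 2:
        raise ValidationError("coherence needs >= 2 windows (one window is identically 1)")
    C = np.empty((n_ch, n_ch, len(bin_sets)), dtype=np.float64)
    for b, bins in enumerate(bin_sets):
        if bins.size == 0:
            C[:, :, b] = np.nan
            continue
        Xb = X[:, :, bins]  # (n_win, n_ch, n_bins)
        G = np.einsum("wib,wjb->ijb", Xb, Xb.conj())
        auto = np.real(np.einsum("iib->ib", G))
        denom = auto[:, None, :] * auto[None, :, :]
        coh_bins = np.abs(G) ** 2 / np.maximum(denom, np.finfo(float).tiny)
        C[:, :, b] = coh_bins.mean(axis=2)
    # exact symmetry and unit diagonal
    C = 0.5 * (C + C.transpose(1, 0, 2))
    for b in range(len(bin_sets)):
        np.fill_diagonal(C[:, :, b], 1.0)
    return np.clip(C, 0.0, 1.0)


def coherence_matrix(
    rec: Recording,
    window_s: float = 10.0,
    band_hz: float = 4.0,
    fmax: float | None = None,
) -> CoherenceMatrix:
    """Pairwise band coherence over all good channels.

    ``fmax`` limits the band grid (default: Nyquist); restricting it cuts
    memory and time roughly proportionally.
    """
    if rec.duration < 2 * window_s:
        raise ValidationError(
            f"segment of {rec.duration:.1f} s shorter than two {window_s} s windows"
        )
    good = rec.good_indices()
    data = rec.data[good]
    if fmax is None:
        fmax = rec.fs / 2
    bands = make_bands(band_hz, fmax)
    X = _window_ffts(data, rec.fs, window_s)
    bins = _band_bins(int(round(window_s * rec.fs)), rec.fs, bands)
    C = _coherence_from_ffts(X, bins)
    return CoherenceMatrix(
        C=C, bands=bands, window_s=window_s, n_windows=X.shape[0],
        channel_ids=[rec.channels[i].channel_id for i in good],
    )


def band_summary(C: CoherenceMatrix, band: tuple[float, float] = (4.0, 8.0)) -> np.ndarray:
    """The stored channels x channels slice for one band."""
    return C.C[:, :, C.band_index(band)].copy()


def split_half_coherence(
    rec: Recording,
    window_s: float = 5.0,
    band_hz: float = 4.0,
    fmax: float | None = None,
) -> SplitCoherence:
    """Coherence separately from odd (alpha) and even (beta) 5 s windows.

    Windows are non-overlapping and alternate 1-based odd/even, so the two
    estimates share no data and their estimation noise is independent on
    stationary signals.
    """
    if rec.duration < 4 * window_s:
        raise ValidationError(
            f"split-half coherence needs >= {4 * window_s:.0f} s (2 windows per parity)"
        )
    good = rec.good_indices()
    data = rec.data[good]
    if fmax is None:
        fmax = rec.fs / 2
    bands = make_bands(band_hz, fmax)
    X = _window_ffts(data, rec.fs, window_s)
    bins = _band_bins(int(round(window_s * rec.fs)), rec.fs, bands)
    ids = [rec.channels[i].channel_id for i in good]
    halves = []
    for parity in (0, 1):  # 0-based even = 1-based odd = alpha
        Xp = X[parity::2]
        halves.append(
            CoherenceMatrix(
                C=_coherence_from_ffts(Xp, bins), bands=bands,
                window_s=window_s, n_windows=Xp.shape[0], channel_ids=ids,
            )
        )
    return SplitCoherence(C_alpha=halves[0], C_beta=halves[1])


def band_power(
    rec: Recording,
    band: tuple[float, float] = (4.0, 8.0),
    window_s: float = 10.0,
) -> np.ndarray:
    """Per-channel band-integrated power (µV^2) for good channels.

    Integrates the Welch power spectral density (Hamming taper,
    non-overlapping windows — the same estimator settings as the coherence)
    over the half-open band, so a unit-amplitude sinusoid inside the band
    yields ~0.5 µV^2.
    """
    if rec.duration < 2 * window_s:
        raise ValidationError("band_power needs >= 2 windows")
    good = rec.good_indices()
    nper = int(round(window_s * rec.fs))
    freqs, psd = sps.welch(
        rec.data[good].astype(np.float64), fs=rec.fs, window="hamming",
        nperseg=nper, noverlap=0, detrend="constant", axis=-1,
    )
    df = freqs[1] - freqs[0]
    sel = (freqs >= band[0]) & (freqs < band[1]) & (freqs > 0)
    return psd[:, sel].sum(axis=1) * df


def coherence_to_hdf5(C: CoherenceMatrix, path, dataset: str = "coherence") -> None:
    """Export a coherence matrix with its band grid and estimation metadata."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset(dataset, data=C.C)
        d.attrs["window_s"] = C.window_s
        d.attrs["n_windows"] = C.n_windows
        f.create_dataset("bands", data=np.asarray(C.bands))
        f.create_dataset("channel_ids", data=np.asarray(C.channel_ids))


def coherence_from_hdf5(path, dataset: str = "coherence") -> CoherenceMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        d = f[dataset]
        return CoherenceMatrix(
            C=d[:], bands=[tuple(b) for b in f["bands"][:]],
            window_s=float(d.attrs["window_s"]),
            n_windows=int(d.attrs["n_windows"]),
            channel_ids=[int(c) for c in f["channel_ids"][:]],
        )


def coherence_to_frame(C: CoherenceMatrix) -> pd.DataFrame:
    """Long-format export: chan_i, chan_j (i<j), band_low, band_high, value."""
    rows = []
    ids = C.channel_ids
    n = len(ids)
    for b, (lo, hi) in enumerate(C.bands):
        iu, ju = np.triu_indices(n, k=1)
        for i, j in zip(iu, ju):
            rows.append((ids[i], ids[j], lo, hi, C.C[i, j, b]))
    return pd.DataFrame(rows, columns=["chan_i", "chan_j", "band_low", "band_high", "value"])
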