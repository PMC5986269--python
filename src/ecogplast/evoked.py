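"""Stimulus-evoked response characterization and the SERR connectivity measure.

The delay of an evoked response is the latency of its trough in the
broadband (0.1-500 Hz) bootstrap-averaged waveform, within 20 ms of pulse
onset.  Delays across the grid are bimodal — short in the stimulated area
("primary" sites), 3-6 ms longer in the other area ("secondary" sites) —
and a gap-based threshold separates the two classes.

The stimulus-evoked response ratio (SERR) is the per-pulse ratio of
high-gamma (60-200 Hz) peak-to-trough amplitude at a secondary site over
that at the stimulation site, averaged over pulses: an evoked measure of
inter-area functional connectivity, dimensionless and gain-invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ecogplast.core_io import ValidationError

logger = logging.getLogger(__name__)

DELAY_WINDOW = (0.0, 0.020)  # s, post-onset search window for the trough
MIN_MODE_GAP = 0.0015  # s, minimum separation between delay modes


class BimodalityError(ValidationError):
    """Delay distribution has no acceptable primary/secondary separation.

    Mirrors the exclusion of sessions without a detectable secondary
    response.
    """


@dataclass
class EvokedSummary:
    """Per-channel evoked response summary."""

    channel_id: int
    mean_waveform: np.ndarray
    delay: float | None  # s; None when no detectable response
    p2t_amplitude: float
    klass: str = "none"  # {"primary", "secondary", "none"}


@dataclass
class SERRResult:
    """SERR of every secondary channel against one stimulation site."""

    stim_channel: int
    per_channel: dict[int, tuple[np.ndarray, float]] = field(default_factory=dict)

    @property
    def serr(self) -> dict[int, float]:
        return {ch: v for ch, (_, v) in self.per_channel.items()}

    @property
    def mean_serr(self) -> float:
        vals = [v for _, v in self.per_channel.values()]
        return float(np.mean(vals)) if vals else float("nan")


def bootstrap_mean_waveform(
    epochs: np.ndarray, n_boot: int = 1000, seed=0
) -> np.ndarray:
    """Bootstrap-averaged waveform for one channel: epochs (n_ep, n_samp).

    Averages the means of ``n_boot`` bootstrap resamples; this converges
    on the plain epoch mean but is the estimator used throughout for
    delay measurement.
    """
    epochs = np.asarray(epochs, dtype=np.float64)
    if epochs.ndim != 2:
        raise ValidationError("bootstrap_mean_waveform expects (n_epochs, n_samples)")
    n_ep = epochs.shape[0]
    if n_ep < 10:
        raise ValidationError(f"only {n_ep} epochs; >= 10 required for bootstrap averaging")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_ep, size=(n_boot, n_ep))
    return epochs[idx].mean(axis=(0, 1))


def estimate_delay(
    mean_waveform: np.ndarray,
    fs: float,
    window: tuple[float, float] = DELAY_WINDOW,
    flat_tol: float = 1e-9,
) -> float | None:
    """Trough latency (s) of the broadband mean waveform in [0, 20) ms.

    Ties break toward the earlier sample.  Returns None for a flat
    waveform (no detectable response).
    """
    w = np.asarray(mean_waveform, dtype=np.float64)
    i0 = int(round(window[0] * fs))
    i1 = min(int(round(window[1] * fs)), w.size)
    if i1 <= i0:
        raise ValidationError("waveform does not cover the delay window")
    seg = w[i0:i1]
    if seg.max() - seg.min() < flat_tol:
        return None
    return (i0 + int(np.argmin(seg))) / fs


def classify_delays(
    delays: dict[int, float | None],
    min_gap: float = MIN_MODE_GAP,
    threshold: float | None = None,
) -> tuple[dict[int, str], float]:
    """Split channels into primary (short delay) and secondary (long delay).

    The threshold is placed at the midpoint of the largest gap between
    sorted delays and accepted only if that gap is at least ``min_gap``
    (1.5 ms); otherwise the delay distribution is not usably bimodal and
    `BimodalityError` is raised.  A manual ``threshold`` overrides the
    automatic choice.
    """
    defined = {ch: d for ch, d in delays.items() if d is not None}
    if len(defined) < 6:
        raise ValidationError(f"only {len(defined)} channels with defined delays (>= 6 needed)")
    if threshold is None:
        vals = np.sort(np.array(list(defined.values())))
        gaps = np.diff(vals)
        gi = int(np.argmax(gaps))
        if gaps[gi] < min_gap:
            raise BimodalityError(
                f"largest delay gap {gaps[gi]*1e3:.2f} ms < {min_gap*1e3:.1f} ms; "
                "no secondary response detected"
            )
        threshold = float(0.5 * (vals[gi] + vals[gi + 1]))
    labels = {
        ch: ("primary" if d < threshold else "secondary") for ch, d in defined.items()
    }
    for ch, d in delays.items():
        if d is None:
            labels[ch] = "none"
    return labels, threshold


def peak_to_trough(
    waveform: np.ndarray, fs: float, window: tuple[float, float] = DELAY_WINDOW
) -> float:
    """max - min of the (high-gamma) waveform over the half-open window."""
    w = np.asarray(waveform, dtype=np.float64)
    i0 = int(round(window[0] * fs))
    i1 = min(int(round(window[1] * fs)), w.size)
    seg = w[i0:i1]
    return float(seg.max() - seg.min())


def _p2t_per_pulse(epochs: np.ndarray, fs: float, window) -> np.ndarray:
    i0 = int(round(window[0] * fs))
    i1 = min(int(round(window[1] * fs)), epochs.shape[-1])
    seg = epochs[..., i0:i1]
    return seg.max(axis=-1) - seg.min(axis=-1)


def compute_serr(
    epochs_hg: np.ndarray,
    fs: float,
    stim_index: int,
    secondary_indices,
    channel_ids=None,
    window: tuple[float, float] = DELAY_WINDOW,
    flags: np.ndarray | None = None,
    stim_floor: float = 0.0,
    ratio_of_means: bool = False,
) -> SERRResult:
    """SERR from high-gamma epochs (pulses x channels x samples).

    Per pulse, the ratio of peak-to-trough at each secondary channel over
    that at the stimulation site; the SERR is the mean ratio over pulses
    (``ratio_of_means=True`` instead divides the mean amplitudes — a
    sensitivity variant).  Pulses whose stimulation-site amplitude falls
    at or below ``stim_floor`` are excluded for all channels; ``flags``
    (pulses x channels, True = artifact) excludes flagged entries.
    """
    epochs_hg = np.asarray(epochs_hg, dtype=np.float64)
    if epochs_hg.ndim != 3 or epochs_hg.shape[0] == 0:
        raise ValidationError("epochs must be non-empty (pulses x channels x samples)")
    secondary_indices = list(secondary_indices)
    if not secondary_indices:
        raise ValidationError("at least one secondary channel required")
    if channel_ids is None:
        channel_ids = list(range(epochs_hg.shape[1]))
    p2t = _p2t_per_pulse(epochs_hg, fs, window)  # pulses x channels
    stim_amp = p2t[:, stim_index]
    pulse_ok = stim_amp > stim_floor
    if flags is not None:
        pulse_ok &= ~flags[:, stim_index]
    n_excl = int((~pulse_ok).sum())
    if n_excl:
        logger.info("compute_serr: excluded %d pulses below the stimulation-site floor", n_excl)
    if not pulse_ok.any():
        raise ValidationError("no usable pulses: stimulation-site response below floor")
    result = SERRResult(stim_channel=channel_ids[stim_index])
    for j in secondary_indices:
        ok = pulse_ok.copy()
        if flags is not None:
            ok &= ~flags[:, j]
        ratios = p2t[ok, j] / stim_amp[ok]
        if ratio_of_means:
            val = float(p2t[ok, j].mean() / stim_amp[ok].mean())
        else:
            val = float(ratios.mean())
        result.per_channel[channel_ids[j]] = (ratios, val)
    return result


ALT_MEASURES = ("hg_p2t", "hg_energy", "bb_energy", "bb_amplitude", "bb_slope")


def alt_measures(
    epochs_bb: np.ndarray,
    epochs_hg: np.ndarray,
    fs: float,
    stim_index: int,
    secondary_indices,
    channel_ids=None,
    window: tuple[float, float] = DELAY_WINDOW,
) -> dict[str, dict[int, float]]:
    """Alternative normalized evoked-response measures.

    Alongside the default high-gamma peak-to-trough: high-gamma energy and
    broadband energy (sum of squares over the window; scale as gain^2),
    broadband amplitude (peak-to-trough of the 0.1-500 Hz signal), and
    broadband slope (steepest falling slope over 1 ms).  Each is the
    per-pulse secondary/stimulation-site ratio averaged over pulses.
    """
    epochs_bb = np.asarray(epochs_bb, dtype=np.float64)
    epochs_hg = np.asarray(epochs_hg, dtype=np.float64)
    if channel_ids is None:
        channel_ids = list(range(epochs_bb.shape[1]))
    i0 = int(round(window[0] * fs))
    i1 = min(int(round(window[1] * fs)), epochs_bb.shape[-1])
    n1ms = max(1, int(round(0.001 * fs)))

    bb = epochs_bb[..., i0:i1]
    hg = epochs_hg[..., i0:i1]
    feats = {
        "hg_p2t": hg.max(axis=-1) - hg.min(axis=-1),
        "hg_energy": (hg**2).sum(axis=-1),
        "bb_energy": (bb**2).sum(axis=-1),
        "bb_amplitude": bb.max(axis=-1) - bb.min(axis=-1),
        # steepest 1 ms falling slope (magnitude, µV/s)
        "bb_slope": np.maximum(
            (bb[..., :-n1ms] - bb[..., n1ms:]).max(axis=-1), 0.0
        ) * fs / n1ms,
    }
    out: dict[str, dict[int, float]] = {}
    for name, f in feats.items():
        stim = f[:, stim_index]
        ok = stim > 0
        if not ok.any():
            raise ValidationError(f"{name}: stimulation-site feature is zero on all pulses")
        out[name] = {
            channel_ids[j]: float((f[ok, j] / stim[ok]).mean())
            for j in secondary_indices
        }
    return out


def summarize_evoked(
    epochs_bb: np.ndarray,
    epochs_hg: np.ndarray,
    fs: float,
    channel_ids,
    n_boot: int = 1000,
    seed=0,
) -> list[EvokedSummary]:
    """Bootstrap waveforms, delays and high-gamma amplitudes for all channels."""
    summaries = []
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    child = ss.spawn(epochs_bb.shape[1])
    for c in range(epochs_bb.shape[1]):
        wf = bootstrap_mean_waveform(epochs_bb[:, c, :], n_boot=n_boot, seed=child[c])
        delay = estimate_delay(wf, fs)
        hg_mean = epochs_hg[:, c, :].mean(axis=0)
        summaries.append(
            EvokedSummary(
                channel_id=channel_ids[c],
                mean_waveform=wf,
                delay=delay,
                p2t_amplitude=peak_to_trough(hg_mean, fs),
            )
        )
    delays = {s.channel_id: s.delay for s in summaries}
    try:
        labels, _ = classify_delays(delays)
        for s in summaries:
            s.klass = labels[s.channel_id]
    except ValidationError:
        logger.warning("delay classification failed; all channels left unclassified")
    return summaries


def serr_to_frame(result: SERRResult, session: str = "", block: int = 0) -> pd.DataFrame:
    """Tidy export: session, block, channel, measure, value."""
    rows = [
        (session, block, ch, "serr", val)
        for ch, (_, val) in result.per_channel.items()
    ]
    return pd.DataFrame(rows, columns=["session", "block", "channel", "measure", "value"])


def rank_corr(a: dict[int, float], b: dict[int, float]) -> float:
    """Spearman rank correlation between two per-channel measures."""
    keys = sorted(set(a) & set(b))
    return float(sstats.spearmanr([a[k] for k in keys], [b[k] for k in keys]).statistic)
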