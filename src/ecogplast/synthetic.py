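"""Synthetic µECoG sessions with a latent Hebbian two-area network.

The generator produces full sessions with the statistical structure the
analysis pipeline assumes, from a single latent nonnegative connectivity
matrix ``W``:

* **Baseline blocks** mix per-channel narrowband theta (4-8 Hz) sources
  through ``M = I + mix_gain * sqrt(W)`` plus 1/f and white noise, so
  pairwise theta coherence is an increasing, approximately linear function
  of ``W`` entries.
* **Stimulation blocks** add a biphasic evoked transient per pulse whose
  peak-to-trough amplitude at channel j is ``W[site, j]`` relative to the
  stimulated site, with the trough at ``intra_delay`` in the stimulated
  area and ``intra_delay + inter_delay_extra`` (default 4.5 ms, within the
  observed 3-6 ms separation) in the other area.
* **Conditioning** updates ``W`` with a mean-centred Hebbian rule driven
  by the coactivation of evoked-response envelopes, applied after every
  100-pulse segment so evoked amplitudes grow within a conditioning block;
  ``eta = 0`` is the exact null model.  Rhythmic stimulation additionally
  entrains a shared narrowband oscillation at the pulse rate, projected to
  each channel by its evoked amplitude, so coherence measured during
  stimulation carries the coactivation pattern.

The same ``W`` therefore drives evoked amplitudes (hence SERR), baseline
coherence, and plasticity — giving every cross-measure regression in the
pipeline a known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ecogplast.core_io import (
    ChannelInfo,
    PulseEvent,
    Recording,
    SessionData,
    SessionProtocol,
    ValidationError,
)
from ecogplast.preprocessing import FilterSpec, bandpass_array, epoch_pulses

# Learning rate giving conditioning-induced theta-coherence increases of a
# few hundredths per session — the scale of effect the analyses target.
DEFAULT_ETA = 0.75


@dataclass
class NetworkConfig:
    """Latent network and signal parameters for session synthesis.

    ``W`` is the nonnegative, zero-diagonal latent connectivity; it sets
    both evoked amplitude ratios (directly) and baseline theta coherence
    (via source mixing ``I + mix_gain * sqrt(W)``).  Amplitudes in µV.
    """

    n_channels: int = 96
    areas: np.ndarray | None = None  # per-channel "M1"/"S1"
    W: np.ndarray | None = None
    fs: float = 1000.0
    intra_delay: float = 0.006
    inter_delay_extra: float = 0.0045
    eta: float = 0.0
    w_max: float = 1.0
    noise_sd: float = 5.0
    source_sd: float = 20.0
    pink_sd: float = 10.0
    mix_gain: float = 0.35
    evoked_amp: float = 100.0
    pulse_jitter_sd: float = 0.1
    theta_band: tuple[float, float] = (4.0, 8.0)
    # evoked kernel shape: a partial rebound leaves net low-frequency area,
    # as in physiological evoked potentials, so repetitive stimulation
    # injects energy at the conditioning rate as well as in high gamma
    trough_width: float = 0.0015
    rebound_width: float = 0.0030
    rebound_frac: float = 0.35
    # rhythmic stimulation entrains a shared narrowband oscillation at the
    # pulse rate (bandwidth ~1 Hz); each channel receives it scaled by its
    # evoked amplitude, so coherence during stimulation carries the
    # coactivation pattern a_i * a_j across the band around the pulse rate
    entrain_gain: float = 2.5

    def __post_init__(self):
        if self.areas is None:
            half = self.n_channels // 2
            self.areas = np.array(
                ["M1"] * half + ["S1"] * (self.n_channels - half)
            )
        self.areas = np.asarray(self.areas)
        if self.W is None:
            self.W = default_connectivity(self.areas, seed=0)
        self.W = np.asarray(self.W, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.W.shape != (self.n_channels, self.n_channels):
            raise ValidationError("W shape does not match n_channels")
        if np.any(self.W < 0):
            raise ValidationError("W must be nonnegative")
        if np.any(np.diag(self.W) != 0):
            raise ValidationError("W must have a zero diagonal")
        if self.eta < 0:
            raise ValidationError("eta must be >= 0")
        if len(self.areas) != self.n_channels:
            raise ValidationError("areas length does not match n_channels")

    def channels(self) -> list[ChannelInfo]:
        n_cols = int(math.ceil(math.sqrt(self.n_channels)))
        return [
            ChannelInfo(
                channel_id=i, grid_row=i // n_cols, grid_col=i % n_cols,
                area=str(self.areas[i]),
            )
            for i in range(self.n_channels)
        ]

    @classmethod
    def default(cls, n_channels: int = 96, seed: int = 0, eta: float = 0.0,
                **overrides) -> "NetworkConfig":
        half = n_channels // 2
        areas = np.array(["M1"] * half + ["S1"] * (n_channels - half))
        W = default_connectivity(areas, seed=seed)
        return cls(n_channels=n_channels, areas=areas, W=W, eta=eta, **overrides)


@dataclass
class GroundTruth:
    """Latent quantities recorded during synthesis, for recovery tests."""

    W_pre: np.ndarray
    W_post: np.ndarray
    W_trajectory: list[np.ndarray] = field(default_factory=list)
    true_delays: dict[int, np.ndarray] = field(default_factory=dict)  # laser -> per-channel s
    amp_ratios: dict[int, np.ndarray] = field(default_factory=dict)  # laser -> W[site, :]

    def __post_init__(self):
        if self.W_trajectory == []:
            self.W_trajectory = [self.W_pre.copy(), self.W_post.copy()]


def default_connectivity(areas: np.ndarray, seed: int = 0,
                         intra_mean: float = 0.30, inter_mean: float = 0.25,
                         jitter_sd: float = 0.50) -> np.ndarray:
    """Symmetric nonnegative W: stronger within-area than between-area links,
    log-normal heterogeneity across pairs."""
    rng = np.random.default_rng(seed)
    n = len(areas)
    same = areas[:, None] == areas[None, :]
    base = np.where(same, intra_mean, inter_mean)
    jit = np.exp(rng.normal(-0.5 * jitter_sd**2, jitter_sd, size=(n, n)))
    W = base * jit
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return np.clip(W, 0.0, 1.0)


def mixing_from_w(W: np.ndarray, mix_gain: float) -> np.ndarray:
    """Source-mixing matrix tied to latent connectivity.

    Each channel owns one theta source and picks up its neighbours'
    sources with weight ``mix_gain * sqrt(W_ij)``; the square root makes
    small-signal theta coherence approximately linear in ``W_ij``.
    """
    M = mix_gain * np.sqrt(W)
    np.fill_diagonal(M, 1.0)
    return M


def _theta_sources(rng, n_sources: int, n_samples: int, fs: float,
                   band: tuple[float, float]) -> np.ndarray:
    pad = int(2 * fs)
    white = rng.standard_normal((n_sources, n_samples + 2 * pad))
    sos = sps.butter(4, [band[0] / (fs / 2), band[1] / (fs / 2)],
                     btype="band", output="sos")
    src = sps.sosfiltfilt(sos, white, axis=-1)[:, pad:-pad]
    sd = src.std(axis=-1, keepdims=True)
    return src / np.maximum(sd, np.finfo(float).tiny)


def _pink_noise(rng, n_channels: int, n_samples: int) -> np.ndarray:
    """Unit-SD 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    pink = np.fft.irfft(spec * shape, n=n_samples, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    return pink / np.maximum(sd, np.finfo(float).tiny)


def _background(config: NetworkConfig, W: np.ndarray, n_samples: int, rng) -> np.ndarray:
    M = mixing_from_w(W, config.mix_gain)
    src = _theta_sources(rng, config.n_channels, n_samples, config.fs,
                         config.theta_band)
    x = config.source_sd * (M @ src)
    if config.pink_sd > 0:
        x += config.pink_sd * _pink_noise(rng, config.n_channels, n_samples)
    if config.noise_sd > 0:
        x += config.noise_sd * rng.standard_normal((config.n_channels, n_samples))
    return x


def generate_baseline(
    config: NetworkConfig, duration: float, seed, W: np.ndarray | None = None
) -> Recording:
    """Spontaneous activity whose theta coherence tracks the latent network.

    ``seed`` may be an int or a `numpy.random.SeedSequence`-compatible
    object.  Requires ``duration >= 20 s`` (two 10 s coherence windows).
    """
    if duration < 20.0:
        raise ValidationError("baseline must be >= 20 s (two coherence windows)")
    rng = np.random.default_rng(seed)
    W = config.W if W is None else W
    n_samples = int(round(duration * config.fs))
    x = _background(config, W, n_samples, rng)
    return Recording(data=x, fs=config.fs, channels=config.channels(), events=[])


# ---------------------------------------------------------------------------
# Evoked responses

def biphasic_kernel(
    fs: float,
    delay: float,
    trough_width: float = 0.0015,
    rebound_width: float = 0.0030,
    rebound_frac: float = 0.55,
    support: float = 0.030,
) -> np.ndarray:
    """Difference-of-Gaussians biphasic evoked kernel, unit peak-to-trough.

    Negative lobe (trough) then positive rebound, total support <= 30 ms.
    The sampled waveform is shifted so its minimum falls exactly on the
    sample nearest ``delay``.  The narrow trough carries broadband energy
    well into the high-gamma range.
    """
    if not 0 < delay < support:
        raise ValidationError(f"delay {delay} outside kernel support")
    n = int(round(support * fs))
    t = np.arange(n) / fs
    k = -np.exp(-0.5 * ((t - delay) / trough_width) ** 2)
    k += rebound_frac * np.exp(-0.5 * ((t - delay - 3 * trough_width) / rebound_width) ** 2)
    # pin the sampled trough onto the requested delay sample
    shift = int(round(delay * fs)) - int(np.argmin(k))
    if shift:
        k = np.roll(k, shift)
        if shift > 0:
            k[:shift] = 0.0
        else:
            k[shift:] = 0.0
    return k / (k.max() - k.min())


def _pulse_response(
    config: NetworkConfig,
    W: np.ndarray,
    pulse_plan: list[tuple[float, int]],
    site_of_laser: dict[int, int],
    n_samples: int,
    rng,
) -> np.ndarray:
    """Superimposed evoked transients for an arbitrary pulse plan.

    Per pulse, a shared log-normal gain models stimulation-efficacy
    fluctuation; it scales all channels equally so per-pulse amplitude
    ratios stay exact.
    """
    x = np.zeros((config.n_channels, n_samples))
    jitter_on = config.pulse_jitter_sd > 0 and config.noise_sd > 0
    gains = [
        float(np.exp(rng.normal(-0.5 * config.pulse_jitter_sd**2,
                                config.pulse_jitter_sd))) if jitter_on else 1.0
        for _ in pulse_plan
    ]
    for laser, site in site_of_laser.items():
        amps = W[site].copy()
        amps[site] = 1.0
        if amps.max() <= 0:
            raise ValidationError(f"laser {laser}: site {site} drives no response")
        site_area = config.areas[site]
        same = np.asarray(config.areas) == site_area
        onsets = [(o, g) for (o, l), g in zip(pulse_plan, gains) if l == laser]
        if not onsets:
            continue
        train = np.zeros(n_samples)
        for onset, g in onsets:
            idx = int(round(onset * config.fs))
            if 0 <= idx < n_samples:
                train[idx] += g
        for mask, d in ((same, config.intra_delay),
                        (~same, config.intra_delay + config.inter_delay_extra)):
            if not mask.any():
                continue
            kern = biphasic_kernel(
                config.fs, d, trough_width=config.trough_width,
                rebound_width=config.rebound_width,
                rebound_frac=config.rebound_frac,
            )
            conv = sps.fftconvolve(train, kern)[:n_samples]
            x[mask] += config.evoked_amp * np.outer(amps[mask], conv)
    return x


def _entrained_oscillation(
    config: NetworkConfig, W: np.ndarray, site: int, rate: float,
    n_samples: int, rng,
) -> np.ndarray:
    """Shared narrowband oscillation at the pulse rate, weighted by evoked
    amplitude per channel (network entrainment by rhythmic stimulation)."""
    lo = max(0.5, rate - 1.0)
    hi = min(rate + 1.0, config.fs / 2 - 1.0)
    pad = int(2 * config.fs)
    white = rng.standard_normal(n_samples + 2 * pad)
    sos = sps.butter(4, [lo / (config.fs / 2), hi / (config.fs / 2)],
                     btype="band", output="sos")
    osc = sps.sosfiltfilt(sos, white)[pad:-pad]
    osc /= max(osc.std(), np.finfo(float).tiny)
    amps = W[site].copy()
    amps[site] = 1.0
    return config.entrain_gain * config.source_sd * np.outer(amps, osc)


def _pulse_block(
    config: NetworkConfig,
    W: np.ndarray,
    pulse_plan: list[tuple[float, int]],
    site_of_laser: dict[int, int],
    duration: float,
    seed,
    rate: float | None = None,
    pulse_width: float = 0.005,
) -> Recording:
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * config.fs))
    x = _pulse_response(config, W, pulse_plan, site_of_laser, n_samples, rng)
    if config.noise_sd > 0:
        x += _background(config, W, n_samples, rng)
        if rate is not None and config.entrain_gain > 0 and pulse_plan:
            for laser, site in site_of_laser.items():
                if any(l == laser for _, l in pulse_plan):
                    x += _entrained_oscillation(config, W, site, rate, n_samples, rng)
    events = [PulseEvent(onset, laser, pulse_width)
              for onset, laser in sorted(pulse_plan)]
    return Recording(data=x, fs=config.fs, channels=config.channels(), events=events)


def generate_evoked(
    config: NetworkConfig,
    W: np.ndarray,
    site: int,
    n_pulses: int,
    rate: float,
    seed,
    laser_id: int = 0,
    start_time: float = 0.0,
) -> Recording:
    """A single-laser pulse train: ``n_pulses`` pulses at ``rate`` Hz.

    Pulse onsets are ``start_time + k / rate``; each pulse evokes a
    biphasic transient at every channel with amplitude ``W[site, j]``
    relative to the stimulated site.  With ``noise_sd == 0`` the output is
    the noiseless superposition of kernels (exact amplitude ratios).
    """
    if not 0 <= site < config.n_channels:
        raise ValidationError(f"site {site} out of range")
    if 1.0 / rate < 0.030:
        raise ValidationError(f"rate {rate} Hz leaves < 30 ms between pulses")
    plan = [(start_time + k / rate, laser_id) for k in range(n_pulses)]
    duration = start_time + n_pulses / rate
    return _pulse_block(config, W, plan, {laser_id: site}, duration, seed, rate=rate)


# ---------------------------------------------------------------------------
# Hebbian plasticity

def hebbian_update(
    W: np.ndarray, coactivation: np.ndarray, eta: float, w_max: float = 1.0
) -> np.ndarray:
    """Mean-centred Hebbian step: W' = clip(W + eta*(A - mean(A)), 0, w_max).

    ``A`` is the symmetric coactivation matrix; its mean is taken over
    off-diagonal entries, so a uniform drive leaves ``W`` unchanged.  The
    update is symmetric and preserves the zero diagonal.
    """
    W = np.asarray(W, dtype=np.float64)
    A = np.asarray(coactivation, dtype=np.float64)
    if A.shape != W.shape:
        raise ValidationError("coactivation shape does not match W")
    if not np.allclose(A, A.T):
        raise ValidationError("coactivation must be symmetric")
    if eta < 0:
        raise ValidationError("eta must be >= 0")
    if eta == 0:
        return W.copy()
    n = W.shape[0]
    off = ~np.eye(n, dtype=bool)
    drive = A - A[off].mean()
    Wp = np.clip(W + eta * 0.5 * (drive + drive.T), 0.0, w_max)
    np.fill_diagonal(Wp, 0.0)
    return Wp


def coactivation_matrix(
    rec: Recording,
    site_of_laser: dict[int, int],
    window: tuple[float, float] = (0.0, 0.030),
) -> np.ndarray:
    """Per-pulse coactivation of evoked high-gamma envelopes, block-averaged.

    For each pulse, the response envelope at every channel is the
    peak-to-trough of the high-gamma-filtered epoch, normalised by the
    envelope at that pulse's stimulation site; the coactivation matrix is
    the mean over pulses of the outer product of normalised envelopes.
    """
    hg = bandpass_array(rec.data, rec.fs, FilterSpec.high_gamma())
    rec_hg = Recording(data=hg, fs=rec.fs, channels=rec.channels, events=rec.events)
    epochs, kept = epoch_pulses(rec_hg, window, return_kept=True)
    if epochs.shape[0] == 0:
        raise ValidationError("no pulses available for coactivation")
    env = epochs.max(axis=2) - epochs.min(axis=2)  # pulses x channels
    lasers = np.array([rec.events[k].laser_id for k in kept])
    A = np.zeros((rec.n_channels, rec.n_channels))
    n_used = 0
    for k in range(epochs.shape[0]):
        site = site_of_laser[int(lasers[k])]
        ref = env[k, site]
        if ref <= 0:
            continue
        e = env[k] / ref
        A += np.outer(e, e)
        n_used += 1
    if n_used == 0:
        raise ValidationError("all pulses had zero stimulation-site response")
    A /= n_used
    np.fill_diagonal(A, 0.0)
    return 0.5 * (A + A.T)


def latent_coactivation(
    W: np.ndarray, site_of_laser: dict[int, int], laser_seq: list[int]
) -> np.ndarray:
    """Exact per-pulse evoked-envelope coactivation for a pulse sequence.

    The normalised evoked envelope of a pulse from laser L is the
    amplitude vector ``a = W[site_L]`` with 1 at the site itself, so the
    block-averaged coactivation is the mean over pulses of ``outer(a, a)``.
    This is the latent drive behind `coactivation_matrix`, which recovers
    it (noisily) from the synthesised signal.
    """
    n = W.shape[0]
    A = np.zeros((n, n))
    for laser in laser_seq:
        site = site_of_laser[laser]
        a = W[site].copy()
        a[site] = 1.0
        A += np.outer(a, a)
    A /= max(len(laser_seq), 1)
    np.fill_diagonal(A, 0.0)
    return A


def _conditioning_block(
    config: NetworkConfig,
    W: np.ndarray,
    protocol: SessionProtocol,
    duration: float,
    seed,
    site_of_laser: dict[int, int],
    seg_pulses: int = 100,
) -> tuple[Recording, np.ndarray]:
    """One conditioning block with plasticity evolving across 100-pulse
    segments.

    The evoked response of each segment is synthesised with the current
    ``W``; after each segment the Hebbian rule is applied with the
    segment's share of the learning rate, so evoked amplitudes (hence
    SERR) grow within the block while the cumulative update matches one
    block-level step.  Background and entrained oscillation use the
    block-entry ``W`` (baseline coherence drifts much more slowly than
    evoked amplitudes).
    """
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * config.fs))
    plan = sorted(_conditioning_plan(protocol, duration))
    x = np.zeros((config.n_channels, n_samples))
    W0 = W.copy()
    W_cur = W.copy()
    n_total = len(plan)
    for s0 in range(0, n_total, seg_pulses):
        seg = plan[s0 : s0 + seg_pulses]
        x += _pulse_response(config, W_cur, seg, site_of_laser, n_samples, rng)
        if config.eta > 0:
            A = latent_coactivation(W_cur, site_of_laser, [l for _, l in seg])
            W_cur = hebbian_update(
                W_cur, A, config.eta * len(seg) / n_total, config.w_max
            )
    if config.noise_sd > 0:
        x += _background(config, W0, n_samples, rng)
        if config.entrain_gain > 0 and plan:
            for laser, site in site_of_laser.items():
                if any(l == laser for _, l in plan):
                    x += _entrained_oscillation(
                        config, W0, site, protocol.cond_rate, n_samples, rng
                    )
    events = [PulseEvent(onset, laser, 0.005) for onset, laser in plan]
    rec = Recording(data=x, fs=config.fs, channels=config.channels(), events=events)
    return rec, W_cur


# ---------------------------------------------------------------------------
# Full sessions

def _test_plan(protocol: SessionProtocol) -> list[tuple[float, int]]:
    """One continuous train at test_rate, alternating lasers every 10 pulses."""
    lasers = [l for l, _ in protocol.laser_sites]
    plan = []
    total = protocol.test_pulses * len(lasers)
    for k in range(total):
        laser = lasers[(k // 10) % len(lasers)]
        plan.append((k / protocol.test_rate, laser))
    return plan


def _conditioning_plan(protocol: SessionProtocol, duration: float) -> list[tuple[float, int]]:
    lasers = [l for l, _ in protocol.laser_sites]
    n = int(np.floor(duration * protocol.cond_rate + 1e-9))
    plan = [(k / protocol.cond_rate, lasers[0]) for k in range(n)]
    if len(lasers) == 2:
        lat = protocol.inter_laser_latency or 0.0
        plan += [(k / protocol.cond_rate + lat, lasers[1]) for k in range(n)]
    return plan


def simulate_session(
    config: NetworkConfig, protocol: SessionProtocol, seed: int
) -> tuple[SessionData, GroundTruth]:
    """Synthesize a full session and its latent ground truth.

    Baseline blocks draw from the current ``W`` (so baseline coherence
    tracks the latent network as it changes); after each conditioning
    block ``W`` is updated by the Hebbian rule with the coactivation of
    that block's evoked responses.  Control sessions are expressed as
    ``eta = 0`` or by a conditioning plan with no pulses (see
    `simulate_control_session`).
    """
    protocol.validate()
    site_of_laser = dict(protocol.laser_sites)
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5E55])
    block_seeds = ss.spawn(protocol.n_blocks)
    W = config.W.copy()
    traj = [W.copy()]
    segments: dict[int, Recording] = {}
    for i, (kind, dur) in enumerate(protocol.blocks):
        bs = block_seeds[i]
        if kind == "baseline":
            segments[i] = generate_baseline(config, dur, bs, W=W)
        elif kind == "test":
            plan = _test_plan(protocol)
            segments[i] = _pulse_block(config, W, plan, site_of_laser, dur, bs,
                                       rate=protocol.test_rate)
        else:  # conditioning
            segments[i], W = _conditioning_block(
                config, W, protocol, dur, bs, site_of_laser,
            )
            traj.append(W.copy())
    gt = GroundTruth(
        W_pre=traj[0], W_post=W.copy(), W_trajectory=traj,
        true_delays={
            laser: np.where(
                np.asarray(config.areas) == config.areas[site],
                config.intra_delay,
                config.intra_delay + config.inter_delay_extra,
            )
            for laser, site in site_of_laser.items()
        },
        amp_ratios={laser: config.W[site].copy() for laser, site in site_of_laser.items()},
    )
    return SessionData(protocol=protocol, segments=segments), gt


def simulate_control_session(
    config: NetworkConfig, protocol: SessionProtocol, seed: int
) -> tuple[SessionData, GroundTruth]:
    """A control session: identical block structure, no conditioning pulses."""
    site_of_laser = dict(protocol.laser_sites)
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5E55])
    block_seeds = ss.spawn(protocol.n_blocks)
    W = config.W.copy()
    segments: dict[int, Recording] = {}
    for i, (kind, dur) in enumerate(protocol.blocks):
        bs = block_seeds[i]
        if kind == "baseline":
            segments[i] = generate_baseline(config, dur, bs, W=W)
        elif kind == "test":
            plan = _test_plan(protocol)
            segments[i] = _pulse_block(config, W, plan, site_of_laser, dur, bs,
                                       rate=protocol.test_rate)
        else:
            segments[i] = generate_baseline(config, max(dur, 20.0), bs, W=W)
    gt = GroundTruth(W_pre=W.copy(), W_post=W.copy())
    return SessionData(protocol=protocol, segments=segments), gt
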