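"""End-to-end orchestration: synthesize/load -> preprocess -> SERR ->
coherence -> plasticity statistics -> report bundle.

`analyze_session` is the core entry point: it runs the full per-session
analysis on a `SessionData` (synthetic or loaded from the HDF5 container)
and returns a `SessionReport`.  `run_pipeline` wraps it with config
handling, synthesis and on-disk outputs; `run_cohort` aggregates session
reports and performs the stimulation-vs-control group comparisons.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ecogplast import __version__
from ecogplast.core_io import (
    Recording,
    SessionData,
    SessionProtocol,
    ValidationError,
    read_session,
    write_session,
)
from ecogplast.preprocessing import (
    FilterSpec,
    bandpass,
    downsample_to_1khz,
    epoch_pulses,
)
from ecogplast.evoked import (
    classify_delays,
    compute_serr,
    estimate_delay,
    bootstrap_mean_waveform,
    peak_to_trough,
)
from ecogplast.coherence import (
    CoherenceMatrix,
    band_power,
    band_summary,
    coherence_matrix,
    split_half_coherence,
)
from ecogplast.stats import (
    BlockSeries,
    ChangeResult,
    RegressionResult,
    band_change_comparison,
    connectivity_change,
    dynamics,
    hebbian_regression,
    serr_coherence_regression,
)
from ecogplast.synthetic import (
    GroundTruth,
    NetworkConfig,
    simulate_control_session,
    simulate_session,
)

logger = logging.getLogger(__name__)

THETA = (4.0, 8.0)


@dataclass
class AnalysisOptions:
    """Tunable analysis parameters; defaults mirror the standard settings."""

    theta_band: tuple[float, float] = THETA
    band_hz: float = 4.0
    fmax: float = 60.0  # upper edge of the analysed band grid
    coh_window_s: float = 10.0
    split_window_s: float = 5.0
    epoch_window: tuple[float, float] = (0.0, 0.030)
    n_boot: int = 1000
    artifact_threshold_sd: float = 8.0
    stim_site_mode: str = "max_primary"  # or "nearest"
    secondary_only_pairs: bool = False
    transpose_hebbian: bool = False


@dataclass
class SessionReport:
    """All per-session analysis outputs."""

    labels: dict[int, str]
    delay_threshold: float
    stim_sites: dict[int, int]  # laser -> channel id used as stimulation site
    test_serr: list[float]
    serr_per_channel: list[dict[int, float]]  # per test block
    baseline_theta: list[np.ndarray]  # per baseline block, good x good theta slice
    channel_ids: list[int]
    serr_coh_fits: dict[tuple[float, float], RegressionResult]
    serr_change: ChangeResult | None
    coherence_change: ChangeResult | None
    band_deltas: dict[tuple[float, float], float]
    theta_power_change: ChangeResult | None
    hebbian: RegressionResult | None
    hebbian_naive: RegressionResult | None
    block_series: BlockSeries | None
    conditioned: bool = True


def _split_epochs_by_laser(rec: Recording, epochs, kept):
    lasers = np.array([rec.events[k].laser_id for k in kept])
    return {l: epochs[lasers == l] for l in np.unique(lasers)}


def _serr_for_block(
    rec_hg: Recording,
    opts: AnalysisOptions,
    per_laser: dict[int, "LaserClassification"],
) -> tuple[float, dict[int, float]]:
    """Mean SERR and per-channel SERR for one test block (averaged over lasers).

    Each laser's SERR uses its own primary/secondary labelling (a channel
    primary for one laser is secondary for the other in two-site
    sessions) and only that laser's pulses.
    """
    epochs_hg, kept = epoch_pulses(rec_hg, opts.epoch_window, return_kept=True)
    by_laser = _split_epochs_by_laser(rec_hg, epochs_hg, kept)
    ids = [c.channel_id for c in rec_hg.channels]
    idx_of = {cid: i for i, cid in enumerate(ids)}
    per_channel: dict[int, list[float]] = {}
    for laser, cls in per_laser.items():
        if laser not in by_laser:
            continue
        secondary = [idx_of[ch] for ch, lab in cls.labels.items()
                     if lab == "secondary" and rec_hg.channels[idx_of[ch]].good]
        res = compute_serr(
            by_laser[laser], rec_hg.fs, idx_of[cls.stim_site], secondary,
            channel_ids=ids, window=(0.0, 0.020),
        )
        for ch, v in res.serr.items():
            per_channel.setdefault(ch, []).append(v)
    merged = {ch: float(np.mean(vs)) for ch, vs in per_channel.items()}
    return float(np.mean(list(merged.values()))), merged


@dataclass
class LaserClassification:
    """Per-laser delay classification and chosen stimulation-site channel."""

    labels: dict[int, str]
    threshold: float
    stim_site: int


def classify_session(
    session: SessionData, opts: AnalysisOptions, seed: int = 0
) -> dict[int, LaserClassification]:
    """Per-laser delays, primary/secondary labels and stimulation sites.

    Uses the first test block: for each laser, broadband bootstrap
    waveforms of that laser's pulses give per-channel trough delays; the
    gap-based threshold splits primary (stimulated area) from secondary
    (other area).  The stimulation-site channel is the maximal-amplitude
    primary channel (``stim_site_mode="max_primary"``) or the electrode
    nearest the laser (``"nearest"``).
    """
    ti = session.protocol.block_indices("test")[0]
    rec = session.segments[ti]
    rec_bb = bandpass(rec, FilterSpec.broadband())
    rec_hg = bandpass(rec, FilterSpec.high_gamma())
    epochs_bb, kept = epoch_pulses(rec_bb, opts.epoch_window, return_kept=True)
    epochs_hg, _ = epoch_pulses(rec_hg, opts.epoch_window, return_kept=True)
    ids = [c.channel_id for c in rec.channels]
    good = rec.good_mask
    bb_by_laser = _split_epochs_by_laser(rec_bb, epochs_bb, kept)
    hg_by_laser = _split_epochs_by_laser(rec_hg, epochs_hg, kept)
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xB0])
    out: dict[int, LaserClassification] = {}
    for laser, site_ch in session.protocol.laser_sites:
        eps_bb = bb_by_laser.get(laser)
        eps_hg = hg_by_laser.get(laser)
        if eps_bb is None:
            continue
        child = ss.spawn(len(ids))
        delays = {}
        for i, cid in enumerate(ids):
            if not good[i]:
                continue
            wf = bootstrap_mean_waveform(eps_bb[:, i, :], n_boot=opts.n_boot,
                                         seed=child[i])
            delays[cid] = estimate_delay(wf, rec.fs)
        labels, threshold = classify_delays(delays)
        if opts.stim_site_mode == "nearest":
            best = site_ch
        else:
            # maximal mean high-gamma p2t among primary-labelled good channels
            best, best_amp = site_ch, -np.inf
            for i, cid in enumerate(ids):
                if labels.get(cid) != "primary" or not good[i]:
                    continue
                amp = peak_to_trough(eps_hg[:, i, :].mean(axis=0), rec.fs)
                if amp > best_amp:
                    best, best_amp = cid, amp
        out[laser] = LaserClassification(labels=labels, threshold=threshold,
                                         stim_site=best)
    if not out:
        raise ValidationError("first test block has no laser pulses to classify")
    return out


def _theta_with_stim(C: CoherenceMatrix, band, stim_ch: int) -> dict[int, float]:
    b = C.band_index(band)
    si = C.channel_ids.index(stim_ch)
    return {cid: float(C.C[si, j, b]) for j, cid in enumerate(C.channel_ids) if j != si}


def _cond_segment_serr(
    rec: Recording,
    opts: AnalysisOptions,
    per_laser: dict[int, LaserClassification],
    seg_pulses: int = 100,
) -> list[float]:
    """Mean SERR of consecutive 100-pulse segments of a conditioning block."""
    rec_hg = bandpass(rec, FilterSpec.high_gamma())
    epochs, kept = epoch_pulses(rec_hg, opts.epoch_window, return_kept=True)
    if epochs.shape[0] == 0:
        return []
    ids = [c.channel_id for c in rec.channels]
    idx_of = {cid: i for i, cid in enumerate(ids)}
    good = rec.good_mask
    lasers = np.array([rec.events[k].laser_id for k in kept])
    vals = []
    for s in range(0, epochs.shape[0] - seg_pulses + 1, seg_pulses):
        seg = slice(s, s + seg_pulses)
        per = []
        for laser, cls in per_laser.items():
            mask = lasers[seg] == laser
            if mask.sum() < 5:
                continue
            secondary = [idx_of[ch] for ch, lab in cls.labels.items()
                         if lab == "secondary" and good[idx_of[ch]]]
            res = compute_serr(
                epochs[seg][mask], rec.fs, idx_of[cls.stim_site], secondary,
                channel_ids=ids, window=(0.0, 0.020),
            )
            per.append(res.mean_serr)
        if per:
            vals.append(float(np.mean(per)))
    return vals


def analyze_session(
    session: SessionData,
    opts: AnalysisOptions | None = None,
    seed: int = 0,
    with_dynamics: bool = True,
    lean: bool = False,
) -> SessionReport:
    """Run the complete per-session analysis.

    ``lean=True`` computes only the session-level connectivity changes
    (classification, per-block SERR, baseline coherence and band deltas)
    and skips the per-band regressions, the Hebbian fit, the band-power
    control and the dynamics — sufficient for cohort-level group
    comparisons at a fraction of the cost.
    """
    opts = opts or AnalysisOptions()
    proto = session.protocol
    theta = opts.theta_band
    per_laser = classify_session(session, opts, seed=seed)
    ref = session.segments[0]
    channel_ids = [c.channel_id for c in ref.channels if c.good]
    first_laser = proto.laser_sites[0][0]
    cls0 = per_laser[first_laser]
    labels, threshold = cls0.labels, cls0.threshold
    stim_sites = {l: c.stim_site for l, c in per_laser.items()}
    stim_ch = cls0.stim_site

    # --- evoked connectivity per test block
    test_serr: list[float] = []
    serr_per_channel: list[dict[int, float]] = []
    for _, rec in session.blocks_of_kind("test"):
        rec_hg = bandpass(rec, FilterSpec.high_gamma())
        mean_serr, per_ch = _serr_for_block(rec_hg, opts, per_laser)
        test_serr.append(mean_serr)
        serr_per_channel.append(per_ch)

    # --- baseline coherence (band grid to fmax; 10 s windows) + split halves
    base_C: list[CoherenceMatrix] = []
    base_split = []
    for _, rec in session.blocks_of_kind("baseline"):
        base_C.append(coherence_matrix(rec, opts.coh_window_s, opts.band_hz, opts.fmax))
        if not lean:
            base_split.append(
                split_half_coherence(rec, opts.split_window_s, opts.band_hz, theta[1])
            )
    baseline_theta = [band_summary(C, theta) for C in base_C]

    # --- conditioning-block coherence (theta only)
    cond_idx = proto.block_indices("conditioning")
    cond_theta: list[np.ndarray | None] = []
    conditioned = False
    for bi in cond_idx:
        rec = session.segments[bi]
        if rec.events:
            conditioned = True
        if not lean and rec.duration >= 2 * opts.coh_window_s:
            Cc = coherence_matrix(rec, opts.coh_window_s, opts.band_hz, theta[1])
            cond_theta.append(band_summary(Cc, theta))
        else:
            cond_theta.append(None)

    # --- baseline SERR <-> coherence regression per band (first baseline/test)
    serr_coh_fits = {}
    if not lean and serr_per_channel:
        coh_with_stim = {
            band: _theta_with_stim(base_C[0], band, stim_ch) for band in base_C[0].bands
        }
        try:
            serr_coh_fits = serr_coherence_regression(serr_per_channel[0], coh_with_stim)
        except ValidationError as e:
            logger.warning("SERR-coherence regression skipped: %s", e)

    # --- pre/post changes (first vs last measurement)
    secondary_ids = [ch for ch, lab in labels.items() if lab == "secondary"
                     and ch in serr_per_channel[0]]
    serr_change = None
    if len(serr_per_channel) >= 2 and len(secondary_ids) >= 3:
        pre = np.array([serr_per_channel[0][ch] for ch in secondary_ids])
        post = np.array([serr_per_channel[-1][ch] for ch in secondary_ids])
        serr_change = connectivity_change(pre, post, "serr")

    coh_change = None
    band_deltas: dict[tuple[float, float], float] = {}
    if len(base_C) >= 2:
        pre_stim = _theta_with_stim(base_C[0], theta, stim_ch)
        post_stim = _theta_with_stim(base_C[-1], theta, stim_ch)
        chans = [c for c in secondary_ids if c in pre_stim]
        if len(chans) >= 3:
            coh_change = connectivity_change(
                np.array([pre_stim[c] for c in chans]),
                np.array([post_stim[c] for c in chans]),
                "coherence",
            )
        # session-level change per band: coherence of each secondary site
        # with the stimulation site, averaged over secondary sites
        si = base_C[0].channel_ids.index(stim_ch)
        sec_pos = [base_C[0].channel_ids.index(c) for c in secondary_ids
                   if c in base_C[0].channel_ids]
        for band in base_C[0].bands:
            b = base_C[0].band_index(band)
            band_deltas[band] = float(
                (base_C[-1].C[si, sec_pos, b] - base_C[0].C[si, sec_pos, b]).mean()
            )

    # --- theta band-power control (no power change expected)
    power_change = None
    base_blocks = session.blocks_of_kind("baseline")
    if not lean and len(base_blocks) >= 2:
        p_pre = band_power(base_blocks[0][1], theta, opts.coh_window_s)
        p_post = band_power(base_blocks[-1][1], theta, opts.coh_window_s)
        power_change = connectivity_change(p_pre, p_post, "power")

    # --- split-window Hebbian regression pooled over conditioning blocks
    hebbian = hebbian_naive = None
    base_idx = proto.block_indices("baseline")
    good_pairs = None
    if opts.secondary_only_pairs:
        good_pairs = np.array([cid in secondary_ids or cid == stim_ch
                               for cid in base_C[0].channel_ids])
    ccs, pas, pbs, poas = [], [], [], []
    for k, bi in enumerate(cond_idx):
        if cond_theta[k] is None:
            continue
        pre_k = k  # baseline of the same repeat
        post_k = k + 1
        if post_k >= len(base_idx):
            continue
        alpha_pre = band_summary(base_split[pre_k].C_alpha, theta)
        beta_pre = band_summary(base_split[pre_k].C_beta, theta)
        alpha_post = band_summary(base_split[post_k].C_alpha, theta)
        ccs.append(cond_theta[k])
        pas.append(alpha_pre)
        pbs.append(beta_pre)
        poas.append(alpha_post)
    if ccs:
        try:
            hebbian = hebbian_regression(ccs, pas, pbs, poas, good=good_pairs,
                                         transpose=opts.transpose_hebbian)
            hebbian_naive = hebbian_regression(ccs, pas, pbs, poas, good=good_pairs,
                                               naive=True,
                                               transpose=opts.transpose_hebbian)
        except ValidationError as e:
            logger.warning("Hebbian regression skipped: %s", e)

    # --- dynamics
    series = None
    if not lean and with_dynamics and len(test_serr) >= 2:
        # inter-area coherence time course: stim site <-> secondary sites,
        # the same session-level measure as the pre/post change analyses
        si = base_C[0].channel_ids.index(stim_ch)
        sec_pos = [base_C[0].channel_ids.index(c) for c in secondary_ids
                   if c in base_C[0].channel_ids]
        base_mean = [float(Ct[si, sec_pos].mean()) for Ct in baseline_theta]
        seg_serr = [
            _cond_segment_serr(session.segments[bi], opts, per_laser)
            for bi in cond_idx
        ]
        try:
            series = dynamics(test_serr, seg_serr, base_mean)
        except ValidationError as e:
            logger.warning("dynamics skipped: %s", e)

    return SessionReport(
        labels=labels, delay_threshold=threshold, stim_sites=stim_sites,
        test_serr=test_serr, serr_per_channel=serr_per_channel,
        baseline_theta=baseline_theta, channel_ids=list(base_C[0].channel_ids),
        serr_coh_fits=serr_coh_fits, serr_change=serr_change,
        coherence_change=coh_change, band_deltas=band_deltas,
        theta_power_change=power_change, hebbian=hebbian,
        hebbian_naive=hebbian_naive, block_series=series,
        conditioned=conditioned,
    )


# ---------------------------------------------------------------------------
# Config-driven runs

@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    seed: int = 0
    input_path: str | None = None  # load this session instead of synthesizing
    out_dir: str | None = None
    figures: bool = False  # write PNG figures into out_dir
    control: bool = False  # no conditioning pulses
    # synthesis
    n_channels: int = 16
    eta: float = 0.0
    network_seed: int | None = None  # fixed latent network ("subject"); None -> seed
    baseline_s: float = 60.0
    conditioning_s: float = 60.0
    n_repeats: int = 2
    final_measurement: bool = True
    cond_rate: float = 5.0
    test_pulses: int = 100
    two_lasers: bool = False
    inter_laser_latency: float | None = None
    # analysis
    options: AnalysisOptions = field(default_factory=AnalysisOptions)

    @classmethod
    def hebbian_study(cls, seed: int, eta: float | None = None,
                      **overrides) -> "RunConfig":
        """Desk-scale session sized for the split-window Hebbian regression.

        24 channels, three baseline/test/conditioning repeats plus a final
        measurement, 90 s baselines and 120 s conditioning blocks; the
        latent network is fixed (one synthetic subject) while noise and
        plasticity realizations follow ``seed``.
        """
        from ecogplast.synthetic import DEFAULT_ETA

        kw = dict(
            n_channels=24, n_repeats=3, baseline_s=90.0, conditioning_s=120.0,
            final_measurement=True, network_seed=42,
            eta=DEFAULT_ETA if eta is None else eta,
            options=AnalysisOptions(n_boot=50, fmax=16.0),
        )
        kw.update(overrides)
        return cls(seed=seed, **kw)

    @classmethod
    def null_study(cls, seed: int, **overrides) -> "RunConfig":
        """Single-repeat no-plasticity session for calibration checks."""
        kw = dict(
            n_channels=16, n_repeats=1, baseline_s=60.0, conditioning_s=60.0,
            final_measurement=True, network_seed=42, eta=0.0,
            options=AnalysisOptions(n_boot=50, fmax=16.0),
        )
        kw.update(overrides)
        return cls(seed=seed, **kw)

    @classmethod
    def cohort_study(cls, seed: int, control: bool = False,
                     eta: float | None = None, **overrides) -> "RunConfig":
        """Cohort-member session with the full band grid (to 60 Hz)."""
        from ecogplast.synthetic import DEFAULT_ETA

        kw = dict(
            n_channels=16, n_repeats=2, baseline_s=120.0, conditioning_s=60.0,
            final_measurement=True, network_seed=42, control=control,
            eta=0.0 if control else (DEFAULT_ETA if eta is None else eta),
            options=AnalysisOptions(n_boot=50, fmax=60.0),
        )
        kw.update(overrides)
        return cls(seed=seed, **kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        opts = AnalysisOptions(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("options", {}) or {}).items()
        })
        return cls(options=opts, **raw)


def build_protocol(cfg: RunConfig, config: NetworkConfig) -> SessionProtocol:
    half = cfg.n_channels // 2
    sites = [(0, 0)]  # laser 0 on the first M1 channel
    if cfg.two_lasers:
        sites.append((1, half))  # laser 1 on the first S1 channel
    return SessionProtocol.standard(
        laser_sites=sites,
        baseline_s=cfg.baseline_s,
        test_pulses=cfg.test_pulses,
        conditioning_s=cfg.conditioning_s,
        cond_rate=cfg.cond_rate,
        inter_laser_latency=cfg.inter_laser_latency,
        n_repeats=cfg.n_repeats,
        final_measurement=cfg.final_measurement,
    )


def synthesize(cfg: RunConfig) -> tuple[SessionData, GroundTruth]:
    w_seed = cfg.seed if cfg.network_seed is None else cfg.network_seed
    config = NetworkConfig.default(n_channels=cfg.n_channels, seed=w_seed,
                                   eta=cfg.eta)
    protocol = build_protocol(cfg, config)
    sim = simulate_control_session if cfg.control else simulate_session
    return sim(config, protocol, cfg.seed)


def save_figures(report: SessionReport, out_dir) -> list[str]:
    """Optional PNG outputs: connectivity heatmap, SERR-coherence scatter,
    and the block time courses."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(report.baseline_theta[0], vmin=0, vmax=1, cmap="viridis")
    ax.set_xlabel("channel")
    ax.set_ylabel("channel")
    ax.set_title("baseline theta coherence")
    fig.colorbar(im, ax=ax)
    p = out / "theta_coherence.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(str(p))

    theta_fit = report.serr_coh_fits.get(THETA)
    if theta_fit is not None and report.serr_per_channel:
        si = report.channel_ids.index(report.stim_sites[min(report.stim_sites)])
        coh = report.baseline_theta[0][si]
        fig, ax = plt.subplots(figsize=(4.5, 4))
        xs, ys = [], []
        for j, cid in enumerate(report.channel_ids):
            if cid in report.serr_per_channel[0] and j != si:
                xs.append(coh[j])
                ys.append(report.serr_per_channel[0][cid])
        ax.scatter(xs, ys, s=18)
        grid = np.linspace(min(xs), max(xs), 10)
        ax.plot(grid, theta_fit.intercept + theta_fit.slope * grid, "k-")
        ax.set_xlabel("theta coherence with stimulation site")
        ax.set_ylabel("SERR")
        ax.set_title(f"slope={theta_fit.slope:.2f}, r$^2$={theta_fit.r2:.2f}")
        p = out / "serr_vs_coherence.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(str(p))

    if report.block_series is not None:
        bs = report.block_series
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(bs.serr_deltas, "o-", label="SERR change")
        ax.plot(bs.coherence_deltas, "s-", label="theta coherence change")
        ax.axhline(0, color="0.6", lw=0.8)
        ax.set_xlabel("measurement block")
        ax.set_ylabel("change from baseline")
        ax.legend(frameon=False)
        p = out / "dynamics.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(str(p))
    return written


def _result_to_jsonable(obj):
    if isinstance(obj, (RegressionResult, ChangeResult, BlockSeries)):
        return _result_to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _result_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_result_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(cfg: RunConfig) -> dict:
    """Synthesize (or load), preprocess, analyze and write the report bundle.

    Identical config + seed gives identical numeric outputs.
    """
    if cfg.input_path:
        session = read_session(cfg.input_path)
        gt = None
    else:
        session, gt = synthesize(cfg)
    fs0 = session.segments[0].fs
    if fs0 > 1000:
        session = SessionData(
            protocol=session.protocol,
            segments={i: downsample_to_1khz(r) for i, r in session.segments.items()},
        )
    report = analyze_session(session, cfg.options, seed=cfg.seed)
    bundle = {
        "manifest": {
            "package_version": __version__,
            "numpy": np.__version__,
            "seed": cfg.seed,
            "config": _result_to_jsonable(
                {**dataclasses.asdict(cfg), "options": dataclasses.asdict(cfg.options)}
            ),
        },
        "stimulation_vs_control": (
            "applicable" if report.conditioned else "not-applicable (control session)"
        ),
        "delay_threshold_ms": report.delay_threshold * 1e3,
        "n_secondary": sum(1 for v in report.labels.values() if v == "secondary"),
        "test_serr": report.test_serr,
        "serr_change": _result_to_jsonable(report.serr_change),
        "coherence_change": _result_to_jsonable(report.coherence_change),
        "theta_power_change": _result_to_jsonable(report.theta_power_change),
        "hebbian": _result_to_jsonable(report.hebbian),
        "hebbian_naive": _result_to_jsonable(report.hebbian_naive),
        "serr_coherence_fits": _result_to_jsonable(report.serr_coh_fits),
        "band_deltas": _result_to_jsonable(report.band_deltas),
        "dynamics": _result_to_jsonable(report.block_series),
    }
    if gt is not None:
        bundle["ground_truth_mean_dW"] = float(np.mean(gt.W_post - gt.W_pre))
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
        rows = []
        for b, per in enumerate(report.serr_per_channel):
            for ch, v in sorted(per.items()):
                rows.append(("session", b, ch, "serr", v))
        pd.DataFrame(
            rows, columns=["session", "block", "channel", "measure", "value"]
        ).to_csv(out / "serr.csv", index=False)
        if cfg.figures:
            save_figures(report, out / "figures")
        if cfg.input_path is None:
            write_session_path = out / "session.h5"
            write_session(session, write_session_path)
    return bundle


def run_cohort(reports: list[SessionReport], bands=None) -> dict:
    """Cohort-level aggregation and stimulation-vs-control comparisons."""
    if len(reports) < 2:
        raise ValidationError("cohort needs >= 2 sessions")
    band_grids = {tuple(sorted(r.band_deltas)) for r in reports}
    if len(band_grids) != 1:
        raise ValidationError("heterogeneous band grids across sessions")
    bands = bands or sorted(reports[0].band_deltas)
    stim = [r for r in reports if r.conditioned]
    ctrl = [r for r in reports if not r.conditioned]
    out: dict = {
        "n_stim": len(stim), "n_control": len(ctrl),
        "session_theta_delta": {
            "stim": [r.band_deltas.get(THETA) for r in stim],
            "control": [r.band_deltas.get(THETA) for r in ctrl],
        },
    }
    if len(stim) >= 2 and len(ctrl) >= 2:
        sd = np.array([[r.band_deltas[b] for b in bands] for r in stim])
        cd = np.array([[r.band_deltas[b] for b in bands] for r in ctrl])
        out["band_comparison"] = band_change_comparison(sd, cd, list(bands))
        from scipy import stats as sstats

        t = sstats.ttest_ind(sd[:, bands.index(THETA)], cd[:, bands.index(THETA)])
        out["theta_group_test"] = {"t": float(t.statistic), "p": float(t.pvalue)}
    else:
        out["band_comparison"] = None
    return out
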