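"""Cross-channel and cross-block statistics for connectivity plasticity.

Centrepiece: the split-window Hebbian regression.  Stimulus-evoked
coherence (conditioning-block coherence minus baseline coherence) is the
correlation structure injected by stimulation; under a Hebbian account it
should predict the pre-to-post change in baseline coherence.  Because the
same baseline estimate on both sides of that regression induces a spurious
(regression-to-the-mean) correlation, baseline blocks are split into
odd (alpha) / even (beta) 5 s windows and the regression uses independent
estimates on the two sides:

    response  = C_post,alpha - C_pre,beta   (baseline-coherence change)
    predictor = C_cond - C_pre,alpha        (stimulus-evoked coherence)

fit by ordinary least squares across channel pairs (upper triangle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from ecogplast.core_io import ValidationError

logger = logging.getLogger(__name__)


class DegenerateVarianceError(ValidationError):
    """Predictor (or response) has no variance; the fit is undefined."""


@dataclass
class RegressionResult:
    """OLS slope/intercept with fit quality, for any cross-channel regression.

    ``df`` is the degrees of freedom behind ``stderr``/``p``: n-2 for
    ordinary per-channel regressions, but the number of channels minus one
    for pair-level (dyadic) regressions, whose standard error comes from a
    delete-one-channel jackknife.
    """

    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    stderr: float = float("nan")
    df: float | None = None

    def ci95(self) -> tuple[float, float]:
        """95% confidence interval for the slope."""
        df = self.df if self.df is not None else self.n - 2
        tcrit = sstats.t.ppf(0.975, df)
        return (self.slope - tcrit * self.stderr, self.slope + tcrit * self.stderr)


@dataclass
class ChangeResult:
    """Pre-to-post change of a per-channel connectivity measure."""

    measure: str
    per_channel_delta: np.ndarray
    mean_delta: float
    p_paired: float
    zero_variance: bool = False


@dataclass
class BlockSeries:
    """Connectivity time courses across the block protocol.

    ``serr_deltas``/``coherence_deltas`` are changes from the first
    measurement; ``cond_segment_serr`` holds the mean SERR of consecutive
    100-pulse conditioning segments per conditioning block.
    """

    serr_deltas: list[float] = field(default_factory=list)
    coherence_deltas: list[float] = field(default_factory=list)
    cond_segment_serr: list[list[float]] = field(default_factory=list)
    within_block_fits: list[RegressionResult | None] = field(default_factory=list)
    pearson_r: float = float("nan")
    pearson_p: float = float("nan")
    unlearning_deltas: list[float] = field(default_factory=list)


def linear_fit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares y on x with two-sided slope test."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValidationError(f"regression needs >= 3 matched points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateVarianceError("predictor has zero variance")
    res = sstats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2), p=float(res.pvalue), n=int(x.size),
        stderr=float(res.stderr),
    )


def connectivity_change(
    pre: np.ndarray, post: np.ndarray, measure: str = "serr"
) -> ChangeResult:
    """Per-channel deltas with a paired two-sided t-test across channels.

    A zero-variance delta vector cannot support a t-test: an all-zero
    delta is reported as no change (p = 1); a constant non-zero shift is
    flagged ``zero_variance`` with p = NaN.
    """
    pre = np.asarray(pre, dtype=np.float64)
    post = np.asarray(post, dtype=np.float64)
    if pre.shape != post.shape:
        raise ValidationError("pre/post channel sets do not match")
    if pre.size < 3:
        raise ValidationError("need >= 3 matched channels")
    delta = post - pre
    if np.ptp(delta) <= 1e-12 * max(1.0, np.abs(delta).max()):
        if delta[0] == 0:
            return ChangeResult(measure, delta, 0.0, 1.0, zero_variance=True)
        return ChangeResult(measure, delta, float(delta.mean()), float("nan"),
                            zero_variance=True)
    t = sstats.ttest_rel(post, pre)
    return ChangeResult(measure, delta, float(delta.mean()), float(t.pvalue))


def serr_coherence_regression(
    serr: dict[int, float],
    coherence_with_stim: dict[tuple[float, float], dict[int, float]],
) -> dict[tuple[float, float], RegressionResult]:
    """Per-band OLS of SERR on coherence-with-the-stimulation-site.

    ``coherence_with_stim`` maps band -> {channel_id: coherence with the
    stimulation site}.  Supports delta-vs-delta regressions by passing
    changes for both arguments.
    """
    out = {}
    for band, coh in coherence_with_stim.items():
        keys = sorted(set(serr) & set(coh))
        if len(keys) < 3:
            raise ValidationError(f"band {band}: fewer than 3 matched secondary channels")
        x = np.array([coh[k] for k in keys])
        y = np.array([serr[k] for k in keys])
        out[band] = linear_fit(x, y)
    return out


def stimulus_evoked_coherence(C_cond: np.ndarray, C_pre_alpha: np.ndarray) -> np.ndarray:
    """Coherence injected by stimulation: conditioning minus baseline (may be < 0)."""
    C_cond = np.asarray(C_cond, dtype=np.float64)
    C_pre_alpha = np.asarray(C_pre_alpha, dtype=np.float64)
    if C_cond.shape != C_pre_alpha.shape:
        raise ValidationError("coherence matrices have mismatched shapes")
    return C_cond - C_pre_alpha


def _upper(mat: np.ndarray, good: np.ndarray | None) -> np.ndarray:
    if good is not None:
        mat = mat[np.ix_(good, good)]
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def _dyadic_fit(
    xs: list[np.ndarray], ys: list[np.ndarray],
    nodes_i: np.ndarray, nodes_j: np.ndarray,
    n_nodes: int, block_center: bool,
) -> RegressionResult:
    """Pooled OLS over channel pairs with delete-one-channel jackknife SE.

    Coherence estimates of pairs sharing a channel are not independent, so
    the usual per-point OLS standard error is anticonservative; the
    jackknife over channels (the exchangeable units of a dyadic design)
    restores calibrated inference.
    """
    def pooled_slope(keep: np.ndarray) -> float:
        xcat, ycat = [], []
        for xb, yb in zip(xs, ys):
            xk, yk = xb[keep], yb[keep]
            if block_center and len(xs) > 1:
                xk = xk - xk.mean()
                yk = yk - yk.mean()
            xcat.append(xk)
            ycat.append(yk)
        return _ols_slope(np.concatenate(xcat), np.concatenate(ycat))

    all_keep = np.ones(len(nodes_i), dtype=bool)
    slope = pooled_slope(all_keep)
    thetas = np.empty(n_nodes)
    for c in range(n_nodes):
        keep = (nodes_i != c) & (nodes_j != c)
        thetas[c] = pooled_slope(keep)
    se = float(np.sqrt((n_nodes - 1) / n_nodes * ((thetas - thetas.mean()) ** 2).sum()))
    # jackknife SEs are mildly conservative in dyadic designs at these node
    # counts; normal reference quantiles give near-nominal coverage
    df = float("inf")
    if se > 0:
        t = slope / se
        p = float(2 * sstats.norm.sf(abs(t)))
    else:
        p = float("nan")
    # descriptive intercept/r2 from the pooled (centred) fit
    xcat, ycat = [], []
    for xb, yb in zip(xs, ys):
        xk, yk = xb, yb
        if block_center and len(xs) > 1:
            xk = xk - xk.mean()
            yk = yk - yk.mean()
        xcat.append(xk)
        ycat.append(yk)
    x = np.concatenate(xcat)
    y = np.concatenate(ycat)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return RegressionResult(slope=slope, intercept=intercept, r2=r2, p=p,
                            n=int(x.size) * 1, stderr=se, df=df)


def hebbian_regression(
    C_cond,
    C_pre_alpha,
    C_pre_beta,
    C_post_alpha,
    good: np.ndarray | None = None,
    naive: bool = False,
    transpose: bool = False,
    block_center: bool = True,
) -> RegressionResult:
    """Split-window regression of baseline-coherence change on evoked drive.

    Each argument is a channels x channels matrix for one band, or a list
    of such matrices (one per conditioning block) pooled into a single
    fit.  When pooling several blocks, predictor and response are centred
    within each block (block fixed effects), so the slope measures the
    across-pair relationship and is not confounded by block-level drifts
    of either quantity; disable with ``block_center=False``.

    ``naive=True`` deliberately reuses the alpha baseline estimate
    on both sides (response = C_post_alpha - C_pre_alpha), reproducing the
    regression-to-the-mean bias the split design removes — for
    demonstration and testing only.  ``transpose=True`` swaps predictor
    and response (fits evoked drive on baseline change).
    """
    def as_list(m):
        return list(m) if isinstance(m, (list, tuple)) else [m]

    conds, pas, pbs, poas = map(as_list, (C_cond, C_pre_alpha, C_pre_beta, C_post_alpha))
    if not len(conds) == len(pas) == len(pbs) == len(poas):
        raise ValidationError("mismatched numbers of per-block matrices")
    xs, ys = [], []
    n_nodes = None
    for cc, pa, pb, poa in zip(conds, pas, pbs, poas):
        cc, pa, pb, poa = (np.asarray(m, dtype=np.float64) for m in (cc, pa, pb, poa))
        if not (cc.shape == pa.shape == pb.shape == poa.shape):
            raise ValidationError("coherence matrices have mismatched shapes")
        xb = _upper(cc - pa, good)
        base_pre = pa if naive else pb
        yb = _upper(poa - base_pre, good)
        if n_nodes is None:
            n_nodes = cc.shape[0] if good is None else int(np.asarray(good).sum())
        xs.append(xb)
        ys.append(yb)
    if np.ptp(np.concatenate(xs)) == 0 or np.ptp(np.concatenate(ys)) == 0:
        raise DegenerateVarianceError("degenerate variance in Hebbian regression inputs")
    if transpose:
        xs, ys = ys, xs
    nodes_i, nodes_j = np.triu_indices(n_nodes, k=1)
    return _dyadic_fit(xs, ys, nodes_i, nodes_j, n_nodes, block_center)


def band_change_comparison(
    stim_deltas: np.ndarray,
    control_deltas: np.ndarray,
    bands: list[tuple[float, float]],
    alpha: float = 0.05,
) -> dict[tuple[float, float], dict]:
    """Per-band stimulation-vs-control comparison with Bonferroni correction.

    ``stim_deltas``/``control_deltas`` are sessions x bands arrays of
    session-level coherence changes.  Each band gets an unpaired two-sided
    t-test; a band is flagged when p < alpha / n_bands.
    """
    stim_deltas = np.atleast_2d(np.asarray(stim_deltas, dtype=np.float64))
    control_deltas = np.atleast_2d(np.asarray(control_deltas, dtype=np.float64))
    if stim_deltas.shape[1] != len(bands) or control_deltas.shape[1] != len(bands):
        raise ValidationError("delta arrays do not match the band grid")
    if stim_deltas.shape[0] < 2 or control_deltas.shape[0] < 2:
        raise ValidationError("need >= 2 sessions per group")
    thresh = alpha / len(bands)
    out = {}
    for b, band in enumerate(bands):
        t = sstats.ttest_ind(stim_deltas[:, b], control_deltas[:, b])
        out[band] = {
            "t": float(t.statistic), "p": float(t.pvalue),
            "significant": bool(t.pvalue < thresh), "threshold": thresh,
        }
    return out


def dynamics(
    test_serr: list[float],
    cond_segment_serr: list[list[float]],
    baseline_coherence: list[float],
) -> BlockSeries:
    """Connectivity time courses and their coupling across the protocol.

    ``test_serr``: mean SERR per test block; ``cond_segment_serr``: mean
    SERR of consecutive 100-pulse segments for each conditioning block;
    ``baseline_coherence``: mean theta coherence per baseline block.

    Produces deltas from the initial measurement, a linear fit of segment
    SERR against segment index within each conditioning block, the
    Pearson correlation between the SERR and coherence delta series
    (aligned per repeat), and the unlearning contrast — the drop from the
    last 100-pulse conditioning segment to the following test block.
    """
    if len(test_serr) < 2 or len(baseline_coherence) < 2:
        raise ValidationError("dynamics needs >= 2 completed repeats")
    serr0, coh0 = test_serr[0], baseline_coherence[0]
    serr_d = [s - serr0 for s in test_serr]
    coh_d = [c - coh0 for c in baseline_coherence]
    fits: list[RegressionResult | None] = []
    for segs in cond_segment_serr:
        if len(segs) >= 3 and np.ptp(segs) > 0:
            fits.append(linear_fit(np.arange(len(segs)), np.asarray(segs)))
        else:
            fits.append(None)
            logger.info("dynamics: conditioning block too short/flat for a within-block fit")
    n = min(len(serr_d), len(coh_d))
    if np.ptp(serr_d[:n]) == 0 or np.ptp(coh_d[:n]) == 0:
        r = p = float("nan")  # constant series: correlation undefined
    else:
        pr = sstats.pearsonr(serr_d[:n], coh_d[:n])
        r, p = float(pr.statistic), float(pr.pvalue)
    unlearning = [
        segs[-1] - nxt
        for segs, nxt in zip(cond_segment_serr, test_serr[1:])
        if segs
    ]
    return BlockSeries(
        serr_deltas=serr_d, coherence_deltas=coh_d,
        cond_segment_serr=[list(s) for s in cond_segment_serr],
        within_block_fits=fits, pearson_r=r, pearson_p=p,
        unlearning_deltas=unlearning,
    )
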