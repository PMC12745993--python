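"""The five-stage staging cascade and the orchestrating pipeline.

Stages are carved out of the 2-D embedding in order: open-eye Wake (gamma
power), the N2N3 super-stage (personalized spindle power), N3 (slow-
oscillation percentage, with reassignment of density candidates between N3
and Wake), closed-eye Wake (oscillatory strength), and finally the remaining
Unknown epochs are resolved into N1 vs REM by temporal smoothing. Each step
converts Unknown epochs only, except the documented N3 candidate
reassignment.

Note on the density rule: the selection region is where the density reaches
at least ``density_fraction`` of its global maximum (the high-density
region); ``literal_sign=True`` inverts the comparison for strict
reproduction of an alternative reading.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from aisleep import features as feat
from aisleep import kde
from aisleep.embedding import Embedding2D, embed_psd
from aisleep.signal_io import (
    N1,
    N2,
    N3,
    REM,
    UNKNOWN,
    WAKE,
    EEGRecording,
    Hypnogram,
    segment_epochs,
)
from aisleep.spectral import irasa_decompose, smooth_psd_osc, welch_psd_db

logger = logging.getLogger("aisleep")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class WelchConfig:
    segment_s: float = 5.0
    overlap: float = 0.5
    window: str = "hamming"


@dataclass
class IrasaConfig:
    h_min: float = 1.1
    h_max: float = 1.9
    h_step: float = 0.05

    def h_set(self) -> np.ndarray:
        return np.arange(self.h_min, self.h_max + self.h_step / 2, self.h_step)


@dataclass
class SmoothConfig:
    sigma_time: float = 1.0  # epochs
    sigma_freq: float = 0.5  # Hz


@dataclass
class UmapConfig:
    n_neighbors: int = 15
    min_dist: float = 0.1
    seed: int = 42
    standardize: bool = False
    fmin: float = 0.2
    fmax: float = 30.0


@dataclass
class StagingConfig:
    gamma_band: tuple[float, float] = (25.0, 50.0)
    density_fraction: float = 0.1
    spindle_search: tuple[float, float] = (5.0, 20.0)
    spindle_target: float = 14.0
    so_weight_floor: float = 0.10
    kernel_size: int = 20  # epochs; a 10-minute smoothing window
    min_rem_duration_min: float = 10.0
    otsu_bins: int = 256
    psp_source: str = "psd_osc"  # {"psd_osc", "psd"}
    literal_sign: bool = False
    raw_bandwidth: bool = False
    distance_method: str = "nearest"  # {"nearest", "centroid", "median"}
    resmooth: str = "per_run"  # {"per_run", "per_epoch"}
    artifact_amplitude_uv: float = 500.0
    welch: WelchConfig = field(default_factory=WelchConfig)
    irasa: IrasaConfig = field(default_factory=IrasaConfig)
    smooth: SmoothConfig = field(default_factory=SmoothConfig)
    umap: UmapConfig = field(default_factory=UmapConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "StagingConfig":
        data = dict(data or {})
        kwargs = {}
        for sub, subcls in (
            ("welch", WelchConfig),
            ("irasa", IrasaConfig),
            ("smooth", SmoothConfig),
            ("umap", UmapConfig),
        ):
            if sub in data:
                kwargs[sub] = subcls(**data.pop(sub))
        for key in ("gamma_band", "spindle_search"):
            if key in data:
                data[key] = tuple(data[key])
        kwargs.update(data)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StageDensities:
    """Per-step densities and intermediates, kept for interpretability."""

    p_wake: np.ndarray | None = None
    p_n2n3: np.ndarray | None = None
    p_non_n2n3: np.ndarray | None = None
    p_n3: np.ndarray | None = None
    p_osc: np.ndarray | None = None
    p_nonosc: np.ndarray | None = None
    gamma_threshold: float | None = None
    gamma_mu_high: float | None = None
    s_smoothed: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _weighted_density(
    emb: Embedding2D, weights: np.ndarray, cfg: StagingConfig
) -> np.ndarray:
    model = kde.fit_density(emb.coords, weights, raw_bandwidth=cfg.raw_bandwidth)
    return kde.evaluate_density(model, emb.coords)


def _density_select(p: np.ndarray, cfg: StagingConfig) -> np.ndarray:
    cut = cfg.density_fraction * p.max()
    return p < cut if cfg.literal_sign else p >= cut


def _set_distance(point: np.ndarray, points: np.ndarray, method: str) -> float:
    """Distance from a point to a point set; the set may not contain the point."""
    if points.shape[0] == 0:
        return np.inf
    if method == "nearest":
        return float(np.linalg.norm(points - point, axis=1).min())
    if method == "centroid":
        return float(np.linalg.norm(point - points.mean(axis=0)))
    if method == "median":
        return float(np.median(np.linalg.norm(points - point, axis=1)))
    raise ValueError(f"unknown distance method {method!r}")


def _percentile_rank(subset_sorted: np.ndarray, value: float) -> float:
    """Fraction of the subset <= value, in [0, 1]."""
    return float(np.searchsorted(subset_sorted, value, side="right")) / subset_sorted.size


# ---------------------------------------------------------------------------
# Algorithm 1: open-eye Wake
# ---------------------------------------------------------------------------


def stage_wake_open(
    emb: Embedding2D,
    gamma: feat.FeatureSeries,
    S: Hypnogram,
    cfg: StagingConfig,
    densities: StageDensities | None = None,
) -> Hypnogram:
    """Label high-gamma-density epochs as Wake (code 0).

    Weights: 1 above the mean of the high-gamma class, 0 below the Otsu
    threshold, otherwise twice the percentile rank within the high class.
    A degenerate gamma distribution skips the step with a warning.
    """
    S = S.copy()
    g = gamma.values
    try:
        th = feat.otsu_threshold(g, n_bins=cfg.otsu_bins)
    except feat.DegenerateDistributionError:
        logger.warning("wake_open: degenerate gamma distribution, step skipped")
        return S
    high = g > th
    if not high.any():
        logger.warning("wake_open: no epochs above the Otsu threshold, step skipped")
        return S
    mu_high = float(g[high].mean())
    subset_sorted = np.sort(g[high])
    w = np.zeros_like(g)
    w[g > mu_high] = 1.0
    mid = (g >= th) & (g <= mu_high)
    w[mid] = [2.0 * _percentile_rank(subset_sorted, v) for v in g[mid]]
    p = _weighted_density(emb, w, cfg)
    sel = _density_select(p, cfg) & (S.stages == UNKNOWN)
    S.stages[sel] = WAKE
    if densities is not None:
        densities.p_wake = p
        densities.gamma_threshold = th
        densities.gamma_mu_high = mu_high
    logger.info("wake_open: labeled %d epochs as Wake", int(sel.sum()))
    return S


# ---------------------------------------------------------------------------
# Algorithm 2: N2N3 super-stage
# ---------------------------------------------------------------------------


def stage_n2n3(
    emb: Embedding2D,
    psp: feat.FeatureSeries,
    S: Hypnogram,
    cfg: StagingConfig,
    densities: StageDensities | None = None,
) -> Hypnogram:
    """Label spindle-rich epochs as the N2N3 super-stage (working code 2).

    The spindle-power series is split at zero; Gaussian CDF weights from the
    two sub-populations drive two competing densities. If one side of the
    split is (near) empty, falls back to a single-population Otsu split.
    """
    S = S.copy()
    v = psp.values
    pos = v >= 0
    neg = ~pos
    if pos.sum() < 2 or neg.sum() < 2:
        logger.warning("n2n3: one-sided spindle power split, Otsu fallback")
        try:
            th = feat.otsu_threshold(v, n_bins=cfg.otsu_bins)
        except feat.DegenerateDistributionError:
            logger.warning("n2n3: degenerate spindle power, step skipped")
            return S
        sel = (v > th) & (S.stages == UNKNOWN)
        S.stages[sel] = N2
        logger.info("n2n3 (fallback): labeled %d epochs", int(sel.sum()))
        return S
    fit_pos = kde.gaussian_fit(v[pos])
    fit_neg = kde.gaussian_fit(v[neg])
    w_n2n3 = kde.gaussian_cdf(v, fit_pos)
    w_non = 1.0 - kde.gaussian_cdf(v, fit_neg)
    p_n2n3 = _weighted_density(emb, w_n2n3, cfg)
    p_non = _weighted_density(emb, w_non, cfg)
    sel = (p_n2n3 > p_non) & (S.stages == UNKNOWN)
    S.stages[sel] = N2
    if densities is not None:
        densities.p_n2n3 = p_n2n3
        densities.p_non_n2n3 = p_non
    logger.info("n2n3: labeled %d epochs as N2N3", int(sel.sum()))
    return S


# ---------------------------------------------------------------------------
# Algorithm 3: N3
# ---------------------------------------------------------------------------


def stage_n3(
    emb: Embedding2D,
    sopct: feat.FeatureSeries,
    S: Hypnogram,
    cfg: StagingConfig,
    exclude: np.ndarray | None = None,
    densities: StageDensities | None = None,
) -> Hypnogram:
    """Split N3 out of the N2N3 region using slow-oscillation percentages.

    Weights are max(SO% - floor, 0), zeroed for already-labeled Wake epochs
    and for excluded (artifact) epochs. Density candidates are reassigned to
    N3 or Wake by proximity to the N2N3 vs Wake point sets; remaining N2N3
    epochs become N2.
    """
    S = S.copy()
    w = np.maximum(sopct.values - cfg.so_weight_floor, 0.0)
    w[S.stages == WAKE] = 0.0
    if exclude is not None:
        w[exclude] = 0.0
    if not np.any(w > 0):
        logger.warning("n3: no SO percentage above the floor, no N3 assigned")
        return S
    p = _weighted_density(emb, w, cfg)
    candidates = np.flatnonzero(_density_select(p, cfg))
    wake_idx = np.flatnonzero(S.stages == WAKE)
    n2n3_idx = np.flatnonzero(S.stages == N2)
    n_n3 = 0
    for i in candidates:
        d_n2n3 = _set_distance(
            emb.coords[i], emb.coords[n2n3_idx[n2n3_idx != i]], cfg.distance_method
        )
        d_wake = _set_distance(
            emb.coords[i], emb.coords[wake_idx[wake_idx != i]], cfg.distance_method
        )
        if d_n2n3 < d_wake:
            S.stages[i] = N3
            n_n3 += 1
        elif np.isfinite(d_wake):
            S.stages[i] = WAKE
    if densities is not None:
        densities.p_n3 = p
    logger.info(
        "n3: %d candidates, %d labeled N3, %d reassigned to Wake",
        candidates.size,
        n_n3,
        candidates.size - n_n3,
    )
    return S


# ---------------------------------------------------------------------------
# Algorithm 4: closed-eye Wake
# ---------------------------------------------------------------------------


def stage_wake_close(
    emb: Embedding2D,
    stdosc: feat.FeatureSeries,
    std_overall: float,
    S: Hypnogram,
    cfg: StagingConfig,
    densities: StageDensities | None = None,
) -> Hypnogram:
    """Label Unknown oscillatory epochs (alpha-rich) as Wake.

    The oscillatory-strength series is split at its whole-matrix std;
    Gaussian CDF weights drive two competing densities, and Unknown epochs
    where the oscillatory density wins become Wake. Previously assigned
    labels are never overwritten.
    """
    S = S.copy()
    v = stdosc.values
    hi = v >= std_overall
    lo = ~hi
    if hi.sum() < 2 or lo.sum() < 2:
        logger.warning("wake_close: degenerate oscillatory split, step skipped")
        return S
    fit_hi = kde.gaussian_fit(v[hi])
    fit_lo = kde.gaussian_fit(v[lo])
    w_osc = kde.gaussian_cdf(v, fit_hi)
    w_non = 1.0 - kde.gaussian_cdf(v, fit_lo)
    p_osc = _weighted_density(emb, w_osc, cfg)
    p_non = _weighted_density(emb, w_non, cfg)
    sel = (p_osc > p_non) & (S.stages == UNKNOWN)
    S.stages[sel] = WAKE
    if densities is not None:
        densities.p_osc = p_osc
        densities.p_nonosc = p_non
    logger.info("wake_close: labeled %d epochs as Wake", int(sel.sum()))
    return S


# ---------------------------------------------------------------------------
# Algorithm 5: N1 vs REM
# ---------------------------------------------------------------------------


def _uniform_smooth(codes: np.ndarray, kernel_size: int) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(codes.astype(np.float64), size=kernel_size, mode="nearest")


def _rem_runs(stages: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    n = stages.size
    t = 0
    while t < n:
        if stages[t] == REM:
            start = t
            while t < n and stages[t] == REM:
                t += 1
            runs.append((start, t))
        else:
            t += 1
    return runs


def resolve_n1_rem(S: Hypnogram, cfg: StagingConfig) -> Hypnogram:
    """Resolve remaining Unknown epochs into N1 vs REM.

    Unknowns become hypothesized REM; a moving average of the code sequence
    (uniform kernel, edge-replicated boundaries) is scanned in temporal
    order, and epochs of REM runs shorter than the minimum REM duration whose
    smoothed value sits strictly closer to N1 than to REM are flipped to N1,
    re-smoothing after each modified run.
    """
    S = S.copy()
    S.stages[S.stages == UNKNOWN] = REM
    min_run = int(round(cfg.min_rem_duration_min * 60.0 / 30.0))  # epochs
    sm = _uniform_smooth(S.stages, cfg.kernel_size)
    for start, end in _rem_runs(S.stages):
        if end - start >= min_run:
            continue
        modified = False
        for t in range(start, end):
            if (sm[t] - 1.0) < (REM - sm[t]):  # strict: ties stay REM
                S.stages[t] = N1
                modified = True
                if cfg.resmooth == "per_epoch":
                    sm = _uniform_smooth(S.stages, cfg.kernel_size)
        if modified and cfg.resmooth == "per_run":
            sm = _uniform_smooth(S.stages, cfg.kernel_size)
    return S


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_aisleep(
    rec: EEGRecording, cfg: StagingConfig | None = None
) -> tuple[Hypnogram, StageDensities, dict]:
    """Run the full staging pipeline on a 100 Hz single-channel recording.

    Returns the final hypnogram (codes 0-4), the per-step densities, and a
    dict of intermediates (PSD, decomposition, embedding, feature series).
    """
    cfg = cfg or StagingConfig()
    if rec.duration_s < 600:
        raise ValueError("recording shorter than 10 minutes")

    ep = segment_epochs(rec)
    psd = welch_psd_db(
        ep, segment_s=cfg.welch.segment_s, overlap=cfg.welch.overlap, window=cfg.welch.window
    )
    dec = irasa_decompose(
        ep,
        h_set=cfg.irasa.h_set(),
        segment_s=cfg.welch.segment_s,
        overlap=cfg.welch.overlap,
        window=cfg.welch.window,
    )
    dec_s = smooth_psd_osc(dec, cfg.smooth.sigma_time, cfg.smooth.sigma_freq)
    emb = embed_psd(
        psd,
        fmin=cfg.umap.fmin,
        fmax=cfg.umap.fmax,
        seed=cfg.umap.seed,
        n_neighbors=cfg.umap.n_neighbors,
        min_dist=cfg.umap.min_dist,
        standardize=cfg.umap.standardize,
    )

    densities = StageDensities()
    S = Hypnogram(np.full(ep.n_epochs, UNKNOWN, dtype=np.int64))

    gamma = feat.gamma_power(psd, cfg.gamma_band)
    S = stage_wake_open(emb, gamma, S, cfg, densities)
    wake_open_mask = S.stages == WAKE

    band = feat.personalized_spindle_band(
        dec_s, search=cfg.spindle_search, target=cfg.spindle_target
    )
    psp = feat.spindle_power(dec_s, band, psd=psd, source=cfg.psp_source)
    S = stage_n2n3(emb, psp, S, cfg, densities)

    events = feat.detect_slow_oscillations(rec)
    sopct = feat.so_percentage(events, ep)
    artifacts = feat.artifact_epochs(ep, cfg.artifact_amplitude_uv)
    S = stage_n3(emb, sopct, S, cfg, exclude=artifacts, densities=densities)

    before_close = S.stages == WAKE
    stdosc = feat.std_osc(dec_s, cfg.spindle_search)
    S = stage_wake_close(emb, stdosc, feat.std_overall(dec_s), S, cfg, densities)
    wake_close_mask = (S.stages == WAKE) & ~before_close

    S = resolve_n1_rem(S, cfg)
    densities.s_smoothed = _uniform_smooth(S.stages, cfg.kernel_size)

    intermediates = {
        "psd": psd,
        "decomposition": dec_s,
        "embedding": emb,
        "gamma_power": gamma,
        "spindle_band": band,
        "spindle_power": psp,
        "so_events": events,
        "so_percentage": sopct,
        "std_osc": stdosc,
        "artifact_epochs": artifacts,
        "wake_open_mask": wake_open_mask,
        "wake_close_mask": wake_close_mask,
    }
    return S, densities, intermediates
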