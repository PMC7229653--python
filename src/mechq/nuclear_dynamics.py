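"""Pearson-decorrelation statistics of nuclear pixel intensities.

For each nucleus a Pearson correlation coefficient (PCC) is computed
between the ordered pixel-intensity lists of two frames a given time
lag apart; plotting PCC against lag gives a decay curve whose shape
reflects how fast the nuclear texture reorganizes.  The per-condition
mean curve is fitted with the three-parameter model

    y(t) = (1 - alpha) + alpha * exp(-t / tau) - eta

where ``alpha`` (drop rate) is the fraction of correlation ultimately
lost, ``tau`` (minutes) the decay time constant, and ``eta`` a
lag-independent offset absorbing measurement noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.optimize import least_squares

from .cli_io import ImageFrameSeries

__all__ = [
    "PCCCurve",
    "DecorrelationFit",
    "nucleus_pixel_series",
    "compute_pcc_curve",
    "mean_curve_with_ci",
    "fit_decorrelation",
    "decay_model",
]


@dataclass
class PCCCurve:
    """A PCC-vs-lag curve for one nucleus (or a condition mean).

    Lag 0 is excluded by construction — it is identically 1.
    """

    lags_min: np.ndarray
    pcc: np.ndarray
    n_pairs_per_lag: np.ndarray

    def __post_init__(self) -> None:
        self.lags_min = np.asarray(self.lags_min, dtype=float)
        self.pcc = np.asarray(self.pcc, dtype=float)
        self.n_pairs_per_lag = np.asarray(self.n_pairs_per_lag, dtype=int)
        if not (len(self.lags_min) == len(self.pcc) == len(self.n_pairs_per_lag)):
            raise ValueError("curve arrays must share length")
        if np.any(self.lags_min <= 0) or np.any(np.diff(self.lags_min) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        finite = self.pcc[np.isfinite(self.pcc)]
        if np.any(finite < -1 - 1e-9) or np.any(finite > 1 + 1e-9):
            raise ValueError("PCC values must lie in [-1, 1]")


@dataclass
class DecorrelationFit:
    """Fitted decay-model parameters with diagnostics."""

    alpha: float
    tau_min: float
    eta: float
    rss: float
    converged: bool


def decay_model(
    t: np.ndarray, alpha: float, tau: float, eta: float
) -> np.ndarray:
    """The PCC decay model ``(1 - alpha) + alpha exp(-t/tau) - eta``."""
    return (1.0 - alpha) + alpha * np.exp(-np.asarray(t, dtype=float) / tau) - eta


def nucleus_pixel_series(
    frames: ImageFrameSeries | np.ndarray,
    mask: np.ndarray,
    register: bool = True,
) -> np.ndarray:
    """Extract per-frame ordered intensity lists for one nucleus.

    The mask (from the first frame) is applied to every frame in fixed
    raster order.  With ``register=True`` each frame is first rigidly
    aligned to frame 0 by phase cross-correlation, so whole-nucleus
    translation does not masquerade as internal reorganization; a high
    intensity gradient at the mask edge after registration is flagged
    with a warning because residual motion then biases the PCC drop.

    Returns an ``(n_frames, n_mask_pixels)`` array.
    """
    stack = frames.frames if isinstance(frames, ImageFrameSeries) else np.asarray(frames)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if mask.shape != stack.shape[1:]:
        raise ValueError("mask shape must match the frame shape")

    if register and len(stack) > 1:
        from skimage.registration import phase_cross_correlation

        aligned = [stack[0].astype(float)]
        for frame in stack[1:]:
            shift, _, _ = phase_cross_correlation(
                stack[0], frame, upsample_factor=10
            )
            aligned.append(ndimage.shift(frame.astype(float), shift, order=1))
        stack = np.stack(aligned)

        edge = mask ^ ndimage.binary_erosion(mask)
        if edge.any():
            grad = np.hypot(*np.gradient(stack[0]))
            interior_scale = np.abs(np.diff(stack[0][mask])).mean() + 1e-12
            if grad[edge].mean() > 5 * interior_scale:
                warnings.warn(
                    "high intensity gradient at the mask edge; residual "
                    "nucleus motion may bias the PCC drop",
                    stacklevel=2,
                )

    return np.stack([frame[mask] for frame in stack]).astype(float)


def compute_pcc_curve(
    series: np.ndarray,
    max_lag_frames: int,
    frame_interval_min: float = 1.0,
) -> PCCCurve:
    """PCC at each lag, averaged over all frame pairs at that lag.

    For lag ``L`` the curve value is the mean over all pairs
    ``(t, t + L)`` of the Pearson correlation between the two pixel
    lists.  Zero-variance frames are skipped (their pairs carry no
    correlation information); a lag that loses all pairs is dropped
    with a warning.
    """
    series = np.asarray(series, dtype=float)
    n_frames = series.shape[0]
    if n_frames < max_lag_frames + 1:
        raise ValueError("need at least max_lag_frames + 1 frames")

    sd = series.std(axis=1)
    usable = sd > 0
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} zero-variance frame(s) skipped",
            stacklevel=2,
        )

    # normalize once; Pearson between frames is then a dot product
    z = np.zeros_like(series)
    n_px = series.shape[1]
    z[usable] = (
        series[usable] - series[usable].mean(axis=1, keepdims=True)
    ) / (sd[usable, None] * np.sqrt(n_px))

    lags, pccs, n_pairs = [], [], []
    for lag in range(1, max_lag_frames + 1):
        vals = [
            float(np.dot(z[t], z[t + lag]))
            for t in range(n_frames - lag)
            if usable[t] and usable[t + lag]
        ]
        if not vals:
            warnings.warn(f"lag {lag} lost all pairs; dropped", stacklevel=2)
            continue
        lags.append(lag * frame_interval_min)
        pccs.append(float(np.clip(np.mean(vals), -1.0, 1.0)))
        n_pairs.append(len(vals))
    return PCCCurve(np.array(lags), np.array(pccs), np.array(n_pairs))


def mean_curve_with_ci(
    curves: list[PCCCurve], confidence: float = 0.95
) -> tuple[PCCCurve, np.ndarray]:
    """Across-cell mean curve with a t-distribution CI of the mean.

    Curves with mismatched lag grids are intersected (with a warning).
    Returns ``(mean_curve, ci_half_width_per_lag)``.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves")
    common = curves[0].lags_min
    for c in curves[1:]:
        inter = np.intersect1d(common, c.lags_min)
        if len(inter) < len(common):
            warnings.warn("mismatched lag grids; intersecting", stacklevel=2)
        common = inter
    if len(common) == 0:
        raise ValueError("curves share no lags")

    matrix = np.stack([
        c.pcc[np.isin(c.lags_min, common)] for c in curves
    ])
    mean = matrix.mean(axis=0)
    sem = matrix.std(axis=0, ddof=1) / np.sqrt(len(curves))
    t_crit = stats.t.ppf(0.5 + confidence / 2, df=len(curves) - 1)
    n_pairs = np.full(len(common), len(curves))
    return PCCCurve(common, np.clip(mean, -1, 1), n_pairs), t_crit * sem


def fit_decorrelation(curve: PCCCurve) -> DecorrelationFit:
    """Bounded nonlinear least-squares fit of the decay model.

    Bounds: ``alpha`` in [0, 1], ``tau`` in (0, 10 * max lag],
    ``eta`` in [0, 0.5].  Three perturbed initializations are tried
    and the best residual kept; ``converged`` reflects the optimizer
    status of the winning start.
    """
    y = curve.pcc
    t = curve.lags_min
    if len(t) < 4:
        raise ValueError("need at least 4 lags to fit 3 parameters")
    if not np.all(np.isfinite(y)):
        raise ValueError("PCC values must be finite")

    tau_max = 10.0 * float(t.max())
    alpha0 = float(np.clip(1.0 - y.min(), 0.0, 1.0))
    tau0 = float(t.max()) / 3.0
    eta0 = float(np.clip(1.0 - y[0], 0.0, 0.5))
    starts = [
        (alpha0, tau0, eta0),
        (min(1.0, alpha0 + 0.2), tau0 / 3.0, 0.0),
        (max(0.0, alpha0 - 0.2), min(tau_max, tau0 * 3.0), min(0.5, eta0 + 0.1)),
    ]

    def residuals(p: np.ndarray) -> np.ndarray:
        return decay_model(t, *p) - y

    best = None
    tiny = 1e-12
    for p0 in starts:
        p0 = (
            float(np.clip(p0[0], 0.0, 1.0)),
            float(np.clip(p0[1], tiny, tau_max)),
            float(np.clip(p0[2], 0.0, 0.5)),
        )
        sol = least_squares(
            residuals,
            p0,
            bounds=([0.0, tiny, 0.0], [1.0, tau_max, 0.5]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    rss, sol = best
    alpha, tau, eta = sol.x
    return DecorrelationFit(
        float(alpha), float(tau), float(eta), rss, bool(sol.success)
    )
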