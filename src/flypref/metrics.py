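"""Behavioural read-outs of the two-choice assay.

Preference index (PI) per frame, pooled PI over the scoring window
(30-60 s by default, after the introduction transient has settled),
pooled velocity summaries, the proboscis-extension (PER) response
fraction, and sigmoid dose-response fits used throughout the assay
(PI vs starvation time or sucrose concentration, PER vs concentration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .arena import ArenaConfig

__all__ = [
    "preference_index",
    "counts_from_detections",
    "pi_series",
    "pooled_pi",
    "velocity_summary",
    "SigmoidFit",
    "fit_sigmoid",
    "per_fraction",
]


def preference_index(n_sugar, n_water):
    """PI = (n_sugar - n_water) / (n_sugar + n_water), in [-1, 1].

    Vectorized; frames with zero total flies are undefined and return NaN
    with a warning (they are excluded from pooled statistics).
    """
    ns = np.asarray(n_sugar, dtype=float)
    nw = np.asarray(n_water, dtype=float)
    if (ns < 0).any() or (nw < 0).any():
        raise ValueError("fly counts must be non-negative")
    total = ns + nw
    zero = total == 0
    if zero.any():
        warnings.warn("PI undefined for frames with zero total flies; returning NaN", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(zero, np.nan, (ns - nw) / np.where(zero, 1.0, total))
    if np.isscalar(n_sugar) and np.isscalar(n_water):
        return float(pi)
    return pi


def counts_from_detections(detections: pd.DataFrame, arena: ArenaConfig) -> pd.DataFrame:
    """Per-frame sugar/water fly counts from tracker detections.

    A fly counts for the side its centroid lies strictly on; a centroid
    exactly on the boundary line counts for neither side.
    Returns columns ``frame, time_s, n_sugar, n_water``.
    """
    side = arena.side_of(detections["x_mm"].to_numpy())
    df = pd.DataFrame({"frame": detections["frame"].to_numpy(), "side": side})
    counts = (
        df.groupby("frame")["side"]
        .agg(n_sugar=lambda s: int((s == 1).sum()), n_water=lambda s: int((s == -1).sum()))
        .reset_index()
    )
    counts["time_s"] = counts["frame"] / arena.frames_per_second
    return counts[["frame", "time_s", "n_sugar", "n_water"]]


def pi_series(counts: pd.DataFrame) -> pd.Series:
    """PI per frame, indexed by time (s); undefined frames are NaN."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pi = preference_index(counts["n_sugar"].to_numpy(), counts["n_water"].to_numpy())
    return pd.Series(pi, index=pd.Index(counts["time_s"].to_numpy(), name="time_s"), name="pi")


def pooled_pi(series: pd.Series, window: tuple[float, float] = (30.0, 60.0)) -> float:
    """Mean of defined per-frame PIs within the pooling window [start, end] s."""
    start, end = window
    if end < start:
        raise ValueError(f"invalid window {window}")
    t = np.asarray(series.index, dtype=float)
    sel = series[(t >= start) & (t <= end)].dropna()
    if len(sel) == 0:
        raise ValueError(f"no defined PI values inside window {window}")
    return float(sel.mean())


def velocity_summary(
    steps: pd.DataFrame,
    fps: float,
    window: tuple[float, float] = (30.0, 60.0),
) -> dict[str, float]:
    """Pooled mean linear velocity (mm/s) and mean absolute angular
    velocity (deg/s) over all flies and frame pairs in the window."""
    start, end = window
    if end < start:
        raise ValueError(f"invalid window {window}")
    t = steps["frame_t"].to_numpy() / fps
    sel = steps[(t >= start) & (t <= end)]
    if len(sel) == 0:
        raise ValueError(f"no track steps inside window {window}")
    return {
        "mean_linear_velocity": float(sel["linear_velocity"].mean()),
        "mean_abs_angular_velocity": float(sel["abs_angular_velocity"].mean()),
    }


def _sigmoid(x, slope, threshold, floor, ceiling):
    return floor + (ceiling - floor) / (1.0 + np.exp(-slope * (x - threshold)))


@dataclass
class SigmoidFit:
    """Fitted monotone sigmoid ``y = floor + (ceiling-floor) * logistic(slope*(x-threshold))``.

    ``threshold`` is the predictor value at the half-maximal response.  For
    PER dose-response fits the floor/ceiling are fixed at 0/1 and the
    threshold is the half-maximal concentration (thrd_PER).  ``degenerate``
    flags data with no usable response range (slope unidentifiable).
    """

    slope: float
    threshold: float
    floor: float
    ceiling: float
    residuals: np.ndarray
    degenerate: bool = False
    extrapolated_threshold: bool = False

    def predict(self, x):
        return _sigmoid(np.asarray(x, dtype=float), self.slope, self.threshold, self.floor, self.ceiling)

    def __call__(self, x):
        return self.predict(x)


def fit_sigmoid(
    x,
    y,
    floor: float | None = None,
    ceiling: float | None = None,
) -> SigmoidFit:
    """Least-squares fit of the assay's sigmoid dose-response curve.

    Fix ``floor``/``ceiling`` to fit the two-parameter form (e.g. 0 and 1
    for PER fractions) or leave them free for PI curves.  Requires at least
    4 distinct predictor values.  Flat responses yield a degenerate fit
    (slope 0) flagged rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct predictor values to fit a sigmoid")
    if np.ptp(y) < 1e-12:
        return SigmoidFit(
            slope=0.0,
            threshold=float(np.median(x)),
            floor=float(y[0]) if floor is None else floor,
            ceiling=float(y[0]) if ceiling is None else ceiling,
            residuals=y - y.mean(),
            degenerate=True,
        )
    lo = float(y.min()) if floor is None else floor
    hi = float(y.max()) if ceiling is None else ceiling
    increasing = np.polyfit(x, y, 1)[0] >= 0
    slope0 = (4.0 / max(np.ptp(x), 1e-9)) * (1 if increasing else -1)
    thr0 = float(np.median(x))

    if floor is None and ceiling is None:
        span = max(np.ptp(y), 1e-9)

        def f(x, slope, threshold, flo, cei):
            return _sigmoid(x, slope, threshold, flo, cei)

        p0 = [slope0, thr0, lo, hi]
        bounds = (
            [-np.inf, x.min() - 10 * np.ptp(x), lo - span, lo - span],
            [np.inf, x.max() + 10 * np.ptp(x), hi + span, hi + span],
        )
    else:
        flo = 0.0 if floor is None else floor
        cei = 1.0 if ceiling is None else ceiling

        def f(x, slope, threshold):
            return _sigmoid(x, slope, threshold, flo, cei)

        p0 = [slope0, thr0]
        bounds = (
            [-np.inf, x.min() - 10 * np.ptp(x)],
            [np.inf, x.max() + 10 * np.ptp(x)],
        )

    try:
        popt, _ = curve_fit(f, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"sigmoid fit failed to converge: {exc}") from exc
    if floor is None and ceiling is None:
        slope, threshold, flo, cei = popt
    else:
        slope, threshold = popt
    resid = y - _sigmoid(x, slope, threshold, flo, cei)
    out_of_range = not (x.min() <= threshold <= x.max())
    return SigmoidFit(
        slope=float(slope),
        threshold=float(threshold),
        floor=float(flo),
        ceiling=float(cei),
        residuals=resid,
        extrapolated_threshold=bool(out_of_range),
    )


def per_fraction(scores: pd.DataFrame) -> pd.Series:
    """PER response fraction per concentration.

    ``scores`` has one row per presentation with columns ``fly_id,
    concentration, score`` (score 0/1; presentations are typically
    triplicate per fly).  Returns the mean across presentations and flies,
    indexed by concentration.
    """
    s = scores["score"].to_numpy()
    if not np.isin(s, (0, 1)).all():
        raise ValueError("PER scores must be 0 or 1")
    return scores.groupby("concentration")["score"].mean().rename("per_fraction")
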