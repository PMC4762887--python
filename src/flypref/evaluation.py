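"""Tracker benchmarking against synthetic ground truth.

Utilities to score tracker output on videos produced by the synthetic
arena generator: per-detection centroid and body-axis orientation errors,
and the identity-assignment error rate over consecutive-frame pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tracker import signed_angle_diff

__all__ = ["annotate_detections", "identity_error_rate"]


def annotate_detections(
    detections: pd.DataFrame,
    truth: pd.DataFrame,
    max_match_distance: float = 2.0,
) -> pd.DataFrame:
    """Assign each detection to its nearest ground-truth fly.

    Adds columns ``gt_id`` (-1 if no fly within ``max_match_distance`` mm),
    ``centroid_error_mm`` and ``orientation_error_deg`` (absolute minimal
    mod-180 difference).
    """
    by_frame = {int(f): g for f, g in truth.groupby("frame")}
    gt_id = np.full(len(detections), -1, dtype=int)
    cent_err = np.full(len(detections), np.nan)
    orient_err = np.full(len(detections), np.nan)
    for i, row in enumerate(detections.itertuples()):
        g = by_frame.get(int(row.frame))
        if g is None or len(g) == 0:
            continue
        d = np.hypot(g["x_mm"].to_numpy() - row.x_mm, g["y_mm"].to_numpy() - row.y_mm)
        j = int(d.argmin())
        if d[j] <= max_match_distance:
            gt_id[i] = int(g["id"].to_numpy()[j])
            cent_err[i] = d[j]
            orient_err[i] = abs(
                signed_angle_diff(g["orientation_deg"].to_numpy()[j], row.orientation_deg)
            )
    out = detections.copy()
    out["gt_id"] = gt_id
    out["centroid_error_mm"] = cent_err
    out["orientation_error_deg"] = orient_err
    return out


def identity_error_rate(steps: pd.DataFrame, annotated: pd.DataFrame) -> tuple[float, int]:
    """Fraction of matched consecutive-frame pairs whose two detections
    belong to different ground-truth flies.

    Pairs whose endpoints could not be assigned to any ground-truth fly are
    dropped.  Returns (error_rate, n_pairs_scored).
    """
    key = annotated.set_index(["frame", "det_index"])["gt_id"]
    i0 = key.loc[list(zip(steps["frame_t"], steps["index_t"]))].to_numpy()
    i1 = key.loc[list(zip(steps["frame_t1"], steps["index_t1"]))].to_numpy()
    ok = (i0 >= 0) & (i1 >= 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no scoreable pairs (no detections matched ground truth)")
    return float((i0[ok] != i1[ok]).mean()), n
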