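"""On-disk formats: numbered PNG frame directories and CSV tables."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "write_frames",
    "read_frames",
    "write_ground_truth",
    "read_ground_truth",
]


def write_frames(frames: np.ndarray, background: np.ndarray, out_dir: str | Path) -> Path:
    """Write a frame stack as ``frame_00000.png`` ... plus ``background.png``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(frames):
        iio.imwrite(out / f"frame_{i:05d}.png", np.asarray(f, dtype=np.uint8))
    iio.imwrite(out / "background.png", np.asarray(background, dtype=np.uint8))
    return out


def read_frames(frames_dir: str | Path, background: str | Path | None = None):
    """Read a numbered PNG frame directory (and its background frame).

    Returns (frames, background) with frames shaped (n, H, W).  If
    ``background`` is None, ``background.png`` inside the directory is used.
    """
    d = Path(frames_dir)
    paths = sorted(d.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {d}")
    frames = np.stack([iio.imread(p) for p in paths])
    bg_path = Path(background) if background is not None else d / "background.png"
    bg = iio.imread(bg_path)
    return frames, bg


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    truth.to_csv(path, index=False)
    return path


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"state": "category", "side": "category"})
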