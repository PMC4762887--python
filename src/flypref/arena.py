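"""Arena geometry and calibration.

The assay arena is a circular dish (76 mm diameter by default) whose floor is
split into two half-discs by a straight boundary through the centre: one half
carries dried sucrose ("sugar side"), the other dried water ("water side").
Coordinates are expressed in millimetres with the origin at the arena centre,
x to the right and y up.  By convention the sugar side is the half-plane
``sign * x > 0`` where ``sign`` is +1 for ``sugar_side="right"`` and -1 for
``sugar_side="left"``; the boundary line ``x == 0`` has zero width and belongs
to neither side.

Image (pixel) coordinates relate to arena coordinates through
``mm_per_pixel`` and the image centre: column increases with x, row decreases
with y (images are stored row-down).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArenaConfig"]


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry, calibration and timing of one arena recording.

    Parameters
    ----------
    diameter : float
        Arena diameter in mm.  Default 76 mm.
    mm_per_pixel : float
        Image calibration.  Default 0.12 mm/px.
    frames_per_second : float
        Acquisition rate.  The camera rate is a free parameter of the assay;
        default 10 fps.
    sugar_side : str
        Which half-plane is the sugar side, ``"right"`` (x > 0) or
        ``"left"`` (x < 0).
    duration : float
        Recording duration in seconds.  Default 60 s (the assay scores the
        first minute after introduction).
    margin_px : int
        Blank border around the arena disc in the rendered image.
    """

    diameter: float = 76.0
    mm_per_pixel: float = 0.12
    frames_per_second: float = 10.0
    sugar_side: str = "right"
    duration: float = 60.0
    margin_px: int = 8

    def __post_init__(self) -> None:
        if not (self.diameter > 0 and np.isfinite(self.diameter)):
            raise ValueError(f"diameter must be positive, got {self.diameter}")
        if not (self.mm_per_pixel > 0 and np.isfinite(self.mm_per_pixel)):
            raise ValueError(f"mm_per_pixel must be positive, got {self.mm_per_pixel}")
        if not (self.frames_per_second > 0 and np.isfinite(self.frames_per_second)):
            raise ValueError(
                f"frames_per_second must be positive, got {self.frames_per_second}"
            )
        if self.sugar_side not in ("right", "left"):
            raise ValueError(f"sugar_side must be 'right' or 'left', got {self.sugar_side!r}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def n_frames(self) -> int:
        return max(int(round(self.duration * self.frames_per_second)), 0)

    @property
    def dt(self) -> float:
        return 1.0 / self.frames_per_second

    @property
    def sugar_sign(self) -> int:
        return 1 if self.sugar_side == "right" else -1

    @property
    def image_shape(self) -> tuple[int, int]:
        side = int(np.ceil(self.diameter / self.mm_per_pixel)) + 2 * self.margin_px
        return (side, side)

    def side_of(self, x: np.ndarray) -> np.ndarray:
        """Side label per x coordinate: +1 sugar, -1 water, 0 on the boundary."""
        return (np.sign(x) * self.sugar_sign).astype(int)

    def mm_to_pixel(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Arena mm coordinates -> image (row, col), float-valued."""
        h, w = self.image_shape
        cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
        col = cc + np.asarray(x) / self.mm_per_pixel
        row = cr - np.asarray(y) / self.mm_per_pixel
        return row, col

    def pixel_to_mm(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Image (row, col) -> arena mm coordinates (x, y)."""
        h, w = self.image_shape
        cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
        x = (np.asarray(col) - cc) * self.mm_per_pixel
        y = (cr - np.asarray(row)) * self.mm_per_pixel
        return x, y
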