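"""Ground-truthed synthetic arena: agent simulation and frame rendering.

The generator stands in for the assay's overhead video recordings.  Agents
follow the same four-state transition structure as the preference model:
a fly is either *free to walk* or *feeding*, on the sugar or water half of
the arena.  Free flies perform a correlated random walk whose mean speed
depends on the side they are on (sugar-induced locomotion suppression);
feeding flies are stationary, so side changes can only happen while walking.
Entry into and exit from feeding are sampled per time step from the
exponential-rate probabilities ``1 - exp(-k dt)`` with side-specific rates.

Because the stationary density of a walker with position-dependent speed
v(x) is proportional to 1/v(x), the emergent ratio of side-crossing rates
equals the ratio of walking speeds — the agent population therefore
converges to the same equilibrium occupancy as the well-mixed rate model
with speed ratio B = speed_sugar / speed_water, which is what makes the
generator a cross-check for the closed-form preference index.

Rendering draws each agent as a filled dark ellipse at its ground-truth
pose on a light empty-arena background, adds Gaussian sensor noise, and
returns the matching clean background frame.  Flies closer than a body
width merge into a single connected blob purely by overlap, as in real
video.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import ArenaConfig

__all__ = ["AgentDynamics", "simulate_agents", "render_frames"]

_STATE_NAMES = ("free_walk", "feeding")
_SIDE_NAMES = {1: "sugar", -1: "water", 0: "boundary"}


@dataclass(frozen=True)
class AgentDynamics:
    """Rates and kinematic parameters of the simulated flies.

    Parameters
    ----------
    k_sin, k_sout : float
        Feeding entry/exit rates (1/s) on the sugar side.  Their ratio is
        the sugar affinity A.
    k_win, k_wout : float
        Feeding entry/exit rates (1/s) on the water side (water affinity D).
    speed_sugar, speed_water : float
        Mean walking speed (mm/s) per side; their ratio is the speed
        ratio B.
    turn_sd : float
        Per-step heading diffusion (degrees).
    seed : int
        RNG seed; with the seed fixed the simulation is bit-reproducible.
    startle_multiplier, startle_window : float
        Optional initial-activity transient: walking speed is multiplied by
        a factor decaying linearly from ``startle_multiplier`` to 1 over
        ``startle_window`` seconds.  Default off (multiplier 1).
    """

    k_sin: float = 0.1
    k_sout: float = 0.05
    k_win: float = 0.0001
    k_wout: float = 0.1
    speed_sugar: float = 3.0
    speed_water: float = 8.0
    turn_sd: float = 30.0
    seed: int = 0
    startle_multiplier: float = 1.0
    startle_window: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_sin", "k_sout", "k_win", "k_wout", "speed_sugar", "speed_water"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.turn_sd) or self.turn_sd < 0:
            raise ValueError(f"turn_sd must be finite and >= 0, got {self.turn_sd}")


def _reflect_into_disc(pos: np.ndarray, new: np.ndarray, radius: float) -> np.ndarray:
    """Reflect steps that would leave the disc off the circular wall.

    The outgoing segment is mirrored about the tangent at the wall crossing,
    preserving step length.  Rare pathological cases (still outside after two
    reflections) are radially projected just inside the wall.
    """
    out = new.copy()
    for _ in range(2):
        r2 = np.einsum("ij,ij->i", out, out)
        bad = r2 > radius**2
        if not bad.any():
            return out
        p0, p1 = pos[bad], out[bad]
        d = p1 - p0
        # solve |p0 + t d|^2 = R^2 for the exit point, t in (0, 1]
        a = np.einsum("ij,ij->i", d, d)
        b = 2 * np.einsum("ij,ij->i", p0, d)
        c = np.einsum("ij,ij->i", p0, p0) - radius**2
        disc = np.maximum(b * b - 4 * a * c, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (-b + np.sqrt(disc)) / (2 * a)
        t = np.clip(np.nan_to_num(t, nan=0.0), 0.0, 1.0)
        q = p0 + t[:, None] * d
        n = q / radius  # outward unit normal
        rem = p1 - q
        rem -= 2 * np.einsum("ij,ij->i", rem, n)[:, None] * n
        out[bad] = q + rem
    r = np.sqrt(np.einsum("ij,ij->i", out, out))
    far = r > radius
    if far.any():
        out[far] *= (radius * (1 - 1e-9) / r[far])[:, None]
    return out


def simulate_agents(
    dynamics: AgentDynamics,
    config: ArenaConfig,
    n_flies: int,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate fly trajectories under the four-state transition dynamics.

    Returns a complete ground-truth table with one row per frame and fly:
    columns ``frame, id, x_mm, y_mm, orientation_deg, state, side``.
    Orientation is the heading reduced mod 180 (a body axis, not a
    direction).  Frame 0 records the initial condition.
    """
    if n_flies < 0:
        raise ValueError(f"n_flies must be >= 0, got {n_flies}")
    n_frames = config.n_frames
    if n_flies == 0 or n_frames == 0:
        return pd.DataFrame(
            {
                "frame": pd.Series([], dtype=int),
                "id": pd.Series([], dtype=int),
                "x_mm": pd.Series([], dtype=float),
                "y_mm": pd.Series([], dtype=float),
                "orientation_deg": pd.Series([], dtype=float),
                "state": pd.Series([], dtype="category"),
                "side": pd.Series([], dtype="category"),
            }
        )
    if rng is None:
        rng = np.random.default_rng(dynamics.seed)
    dt = config.dt
    radius = config.radius

    # initial condition: uniform in the disc, uniform headings, all walking
    rr = radius * np.sqrt(rng.uniform(0, 1, n_flies)) * 0.999
    th = rng.uniform(0, 2 * np.pi, n_flies)
    pos = np.column_stack([rr * np.cos(th), rr * np.sin(th)])
    heading = rng.uniform(0, 360, n_flies)
    feeding = np.zeros(n_flies, dtype=bool)

    p_in = {
        1: 1.0 - np.exp(-dynamics.k_sin * dt),
        -1: 1.0 - np.exp(-dynamics.k_win * dt),
    }
    p_out = {
        1: 1.0 - np.exp(-dynamics.k_sout * dt),
        -1: 1.0 - np.exp(-dynamics.k_wout * dt),
    }
    speed = {1: dynamics.speed_sugar, -1: dynamics.speed_water}

    xs = np.empty((n_frames, n_flies), dtype=np.float64)
    ys = np.empty_like(xs)
    heads = np.empty_like(xs)
    states = np.empty((n_frames, n_flies), dtype=np.int8)

    def record(i: int) -> None:
        xs[i] = pos[:, 0]
        ys[i] = pos[:, 1]
        heads[i] = heading
        states[i] = feeding

    record(0)
    for i in range(1, n_frames):
        side = config.side_of(pos[:, 0])
        side = np.where(side == 0, -config.sugar_sign, side)  # boundary -> water
        on_sugar = side == 1
        u = rng.uniform(size=n_flies)
        # state switches sampled from the side-appropriate rates
        enter = ~feeding & (u < np.where(on_sugar, p_in[1], p_in[-1]))
        leave = feeding & (u < np.where(on_sugar, p_out[1], p_out[-1]))
        feeding = (feeding | enter) & ~leave

        walk = ~feeding
        heading = np.where(
            walk, (heading + rng.normal(0, dynamics.turn_sd, n_flies)) % 360.0, heading
        )
        step_len = np.where(on_sugar, speed[1], speed[-1]) * dt
        if dynamics.startle_window > 0 and dynamics.startle_multiplier != 1.0:
            t = (i - 1) * dt
            decay = max(0.0, 1.0 - t / dynamics.startle_window)
            step_len = step_len * (1.0 + (dynamics.startle_multiplier - 1.0) * decay)
        rad = np.deg2rad(heading)
        delta = np.column_stack([np.cos(rad), np.sin(rad)]) * step_len[:, None]
        delta[feeding] = 0.0
        new = _reflect_into_disc(pos, pos + delta, radius)
        moved = new - pos
        mlen = np.hypot(moved[:, 0], moved[:, 1])
        reflected = walk & (mlen > 1e-12)
        heading = np.where(
            reflected, np.rad2deg(np.arctan2(moved[:, 1], moved[:, 0])) % 360.0, heading
        )
        pos = new
        record(i)

    frames = np.repeat(np.arange(n_frames), n_flies)
    ids = np.tile(np.arange(n_flies), n_frames)
    side_codes = np.sign(xs.ravel()) * config.sugar_sign
    side_cat = pd.Categorical.from_codes(
        (side_codes + 1).astype(int),  # -1,0,1 -> 0,1,2
        categories=["water", "boundary", "sugar"],
    )
    state_cat = pd.Categorical.from_codes(
        states.ravel().astype(int), categories=list(_STATE_NAMES)
    )
    return pd.DataFrame(
        {
            "frame": frames,
            "id": ids,
            "x_mm": xs.ravel(),
            "y_mm": ys.ravel(),
            "orientation_deg": heads.ravel() % 180.0,
            "state": state_cat,
            "side": side_cat,
        }
    )


def _draw_ellipse(
    img: np.ndarray,
    row0: float,
    col0: float,
    semi_major_px: float,
    semi_minor_px: float,
    orientation_deg: float,
    value_edge: float,
    value_core: float,
) -> None:
    """Fill an oriented ellipse into ``img`` (in place), subpixel-centred.

    ``orientation_deg`` is the body-axis angle in arena convention (x right,
    y up); rows run downward, so the axis direction in image coordinates is
    (-sin, cos).  Intensity grades from ``value_core`` at the centre to
    ``value_edge`` at the rim (fly bodies are darkest at the core, which is
    what lets stricter thresholds split merged blobs); overlapping flies
    keep the darker value per pixel.
    """
    phi = np.deg2rad(orientation_deg)
    u = np.array([-np.sin(phi), np.cos(phi)])  # (drow, dcol) along major axis
    v = np.array([-np.cos(phi), -np.sin(phi)])  # perpendicular
    ext = int(np.ceil(semi_major_px)) + 2
    r_lo = max(int(np.floor(row0)) - ext, 0)
    r_hi = min(int(np.ceil(row0)) + ext + 1, img.shape[0])
    c_lo = max(int(np.floor(col0)) - ext, 0)
    c_hi = min(int(np.ceil(col0)) + ext + 1, img.shape[1])
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr, cc = np.meshgrid(
        np.arange(r_lo, r_hi, dtype=float), np.arange(c_lo, c_hi, dtype=float), indexing="ij"
    )
    dr, dc = rr - row0, cc - col0
    a = (dr * u[0] + dc * u[1]) / semi_major_px
    b = (dr * v[0] + dc * v[1]) / semi_minor_px
    q = a * a + b * b
    mask = q <= 1.0
    value = value_core + (value_edge - value_core) * q[mask]
    view = img[r_lo:r_hi, c_lo:c_hi]
    view[mask] = np.minimum(view[mask], value)


def render_frames(
    truth: pd.DataFrame,
    config: ArenaConfig,
    *,
    fly_axes: tuple[float, float] = (2.2, 0.9),
    noise_sd: float = 4.0,
    seed: int = 0,
    fly_intensity: float = 70.0,
    fly_core_intensity: float = 30.0,
    background_intensity: float = 200.0,
    outside_intensity: float = 120.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render ground-truth trajectories as grayscale frames.

    Parameters
    ----------
    truth : DataFrame
        Output of :func:`simulate_agents`.
    fly_axes : (major, minor)
        Full axis lengths of the rendered fly ellipse in mm.  Default
        (2.2, 0.9), a typical starved fly body seen from above.
    noise_sd : float
        Additive Gaussian sensor noise (intensity units on the 0-255 scale).

    Returns
    -------
    frames : uint8 array, shape (n_frames, H, W)
    background : uint8 array, shape (H, W)
        The clean empty-arena frame (arena disc on darker surround).
    """
    major, minor = fly_axes
    if not (major > 0 and minor > 0):
        raise ValueError("fly axes must be positive")
    if major < minor:
        raise ValueError("major axis must be >= minor axis")
    h, w = config.image_shape
    rows, cols = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    x, y = config.pixel_to_mm(rows, cols)
    inside = x * x + y * y <= config.radius**2
    background = np.full((h, w), outside_intensity, dtype=float)
    background[inside] = background_intensity
    background_u8 = np.clip(background, 0, 255).astype(np.uint8)

    if len(truth):
        n_frames = int(truth["frame"].max()) + 1
    else:
        n_frames = config.n_frames
    rng = np.random.default_rng(seed)
    a_px = major / 2.0 / config.mm_per_pixel
    b_px = minor / 2.0 / config.mm_per_pixel

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    grouped = truth.groupby("frame") if len(truth) else {}
    by_frame = {int(k): g for k, g in grouped} if len(truth) else {}
    for i in range(n_frames):
        img = background.copy()
        g = by_frame.get(i)
        if g is not None:
            r0, c0 = config.mm_to_pixel(g["x_mm"].to_numpy(), g["y_mm"].to_numpy())
            if (r0 < -1).any() or (r0 > h).any() or (c0 < -1).any() or (c0 > w).any():
                raise ValueError("agent position outside image bounds; calibration mismatch")
            for rr0, cc0, ang in zip(r0, c0, g["orientation_deg"].to_numpy()):
                _draw_ellipse(img, rr0, cc0, a_px, b_px, ang, fly_intensity, fly_core_intensity)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    return frames, background_u8
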