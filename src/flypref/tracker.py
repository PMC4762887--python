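"""Multi-fly blob tracker.

Detection follows the classic dark-blob pipeline for overhead arena video:
threshold the grayscale frame, subtract the binarized empty-arena
background, clean with one erosion + dilation, and label clusters of
contacting pixels as particles.  Each particle is summarised by its area,
centroid, bounding-box diagonal and the eccentricity of the ellipse with the
same second moments.

Particles whose (bounding-box diagonal, eccentricity) are unlikely under the
session's single-fly reference distribution are flagged: they are either
poorly thresholded flies or several flies merged by proximity.  The number
of flies in such a blob is estimated from its area relative to the mean
single-fly area, and the blob's local region is re-thresholded iteratively
(progressively stricter, up to a fixed iteration cap, 40 by default) until
it splits into the estimated count; blobs that never split are excluded
from that frame.

Identity across consecutive frames uses greedy closest-neighbour
association: repeatedly pair the globally closest pair of ellipses and
remove both, gating pairs at a maximum displacement (~7 mm) and maximum
body-axis rotation (90 deg, on the mod-180 axis convention).  Per-pair
kinematics (linear velocity, signed and absolute angular velocity) follow
from the displacement and the minimal mod-180 angle change times the frame
rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure, morphology

from .arena import ArenaConfig

__all__ = [
    "TrackerConfig",
    "ParticleMeasurement",
    "binarize_and_clean",
    "measure_particles",
    "score_likelihood",
    "resolve_merged",
    "fit_ellipses",
    "match_frames",
    "compute_kinematics",
    "track_frames",
    "signed_angle_diff",
]


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable parameters of the detection and association pipeline."""

    initial_threshold: float = 128.0
    max_iterations: int = 40
    max_pair_distance: float = 7.0  # mm
    max_pair_angle: float = 90.0  # degrees, mod-180 minimal difference
    likelihood_quantile: float = 0.01
    morphology_radius: int = 1
    min_particle_area: int = 3  # px; smaller components are noise

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.max_pair_distance <= 0 or self.max_pair_angle <= 0:
            raise ValueError("pairing gates must be positive")


@dataclass
class ParticleMeasurement:
    """One connected component and its shape summary (pixel units)."""

    label: int
    area: int
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    bbox_diagonal: float
    eccentricity: float
    orientation_deg: float  # arena convention (x right, y up), [0, 180)
    major_axis_px: float
    minor_axis_px: float
    mask: np.ndarray  # boolean, shape of bbox
    likelihood: float = float("nan")
    cls: str = "high"


def binarize_and_clean(
    frame: np.ndarray,
    background: np.ndarray,
    threshold: float,
    morphology_radius: int = 1,
) -> np.ndarray:
    """Segment dark flies and return the connected-component label image.

    Pixels darker than ``threshold`` are foreground; the binarized
    background is subtracted (logical AND NOT) so only objects absent from
    the empty arena remain; one erosion followed by one dilation with a disc
    of ``morphology_radius`` removes single-pixel noise.  Contacting pixels
    (8-connectivity) form one particle.
    """
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError(f"frame shape {frame.shape} != background shape {background.shape}")
    fg = (frame < threshold) & ~(background < threshold)
    if morphology_radius > 0:
        selem = morphology.disk(morphology_radius)
        fg = morphology.dilation(morphology.erosion(fg, selem), selem)
    return measure.label(fg, connectivity=2)


def _shape_from_moments(mu: np.ndarray) -> tuple[float, float, float, float]:
    """Orientation (deg, [0,180), x-y up convention), axis lengths (px) and
    eccentricity from central moments ``mu[i, j] = sum (r-rbar)^i (c-cbar)^j``."""
    m00 = mu[0, 0]
    var_x = mu[0, 2] / m00
    var_y = mu[2, 0] / m00
    cov_xy = -mu[1, 1] / m00  # row axis points down; y = -row
    phi = 0.5 * np.degrees(np.arctan2(2 * cov_xy, var_x - var_y)) % 180.0
    half_tr = (var_x + var_y) / 2.0
    delta = np.sqrt(((var_x - var_y) / 2.0) ** 2 + cov_xy**2)
    lam1, lam2 = half_tr + delta, max(half_tr - delta, 0.0)
    major = 4.0 * np.sqrt(lam1)
    minor = 4.0 * np.sqrt(lam2)
    ecc = np.sqrt(1.0 - lam2 / lam1) if lam1 > 0 else 0.0
    return phi, major, minor, ecc


def measure_particles(labels: np.ndarray, min_area: int = 1) -> list[ParticleMeasurement]:
    """Measure every labelled particle: area, centroid, bbox diagonal and
    second-moment ellipse shape.  Returns an empty list for an empty image."""
    out: list[ParticleMeasurement] = []
    for prop in measure.regionprops(labels):
        if prop.area < min_area:
            continue
        mu = prop.moments_central
        phi, major, minor, ecc = _shape_from_moments(mu)
        mr, mc, xr, xc = prop.bbox
        out.append(
            ParticleMeasurement(
                label=int(prop.label),
                area=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                bbox=(mr, mc, xr, xc),
                bbox_diagonal=float(np.hypot(xr - mr, xc - mc)),
                eccentricity=float(ecc),
                orientation_deg=float(phi),
                major_axis_px=float(major),
                minor_axis_px=float(minor),
                mask=prop.image.copy(),
            )
        )
    return out


def score_likelihood(
    particles: list[ParticleMeasurement],
    likelihood_quantile: float = 0.01,
) -> list[ParticleMeasurement]:
    """Score each particle's likelihood of being a single fly.

    A robust Gaussian reference (median / scaled MAD per feature) is fitted
    to the (bbox_diagonal, eccentricity) of the input particles; the
    likelihood is the product of the two marginal densities.  Particles
    outside the reference contour containing ``1 - likelihood_quantile`` of
    the fitted mass are classed ``low`` (poorly thresholded or merged
    flies).  With a degenerate reference (zero spread) all particles are
    classed ``high`` with a warning.
    """
    if not particles:
        return particles
    feats = np.array([[p.bbox_diagonal, p.eccentricity] for p in particles])
    if len(particles) == 1:
        particles[0].likelihood = 1.0
        particles[0].cls = "high"
        return particles
    loc = np.median(feats, axis=0)
    scale = 1.4826 * np.median(np.abs(feats - loc), axis=0)
    if np.any(scale <= 0):
        warnings.warn(
            "degenerate single-fly reference (zero spread); classifying all particles high",
            stacklevel=2,
        )
        for p in particles:
            p.likelihood = 1.0
            p.cls = "high"
        return particles
    z = (feats - loc) / scale
    r2 = np.sum(z * z, axis=1)
    dens = np.exp(-r2 / 2.0) / (2 * np.pi * scale[0] * scale[1])
    cut = stats.chi2.ppf(1.0 - likelihood_quantile, df=2)
    for p, lk, d2 in zip(particles, dens, r2):
        p.likelihood = float(lk)
        p.cls = "low" if d2 > cut else "high"
    return particles


def resolve_merged(
    frame: np.ndarray,
    background: np.ndarray,
    particle: ParticleMeasurement,
    mean_single_area: float,
    config: TrackerConfig,
) -> list[ParticleMeasurement] | None:
    """Split a low-likelihood particle by local iterative re-thresholding.

    The expected fly count is ``round(area / mean_single_area)`` (at least
    1).  The particle's bounding region is re-binarized at progressively
    stricter (darker) thresholds, stepping down by 1/max_iterations of the
    local intensity range per iteration, until the local component count
    equals the estimate.  Returns the split particles in image coordinates,
    or ``None`` (exclusion) if the count is never matched within
    ``config.max_iterations`` iterations.
    """
    if mean_single_area <= 0:
        raise ValueError("mean_single_area must be positive")
    estimated = max(int(round(particle.area / mean_single_area)), 1)
    mr, mc, xr, xc = particle.bbox
    local = np.asarray(frame, dtype=float)[mr:xr, mc:xc]
    mask = particle.mask  # restrict to this particle's own pixels
    lo = float(local[mask].min())
    span = config.initial_threshold - lo
    if span <= 0:
        span = max(float(local.max()) - lo, 1.0)
    step = span / config.max_iterations

    for it in range(config.max_iterations + 1):
        thr = config.initial_threshold - it * step
        fg = (local < thr) & mask
        labels = measure.label(fg, connectivity=2)
        parts = measure_particles(labels, min_area=config.min_particle_area)
        if len(parts) == estimated:
            for p in parts:
                r, c = p.centroid
                p.centroid = (r + mr, c + mc)
                pmr, pmc, pxr, pxc = p.bbox
                p.bbox = (pmr + mr, pmc + mc, pxr + mr, pxc + mc)
            return parts
        if it > 0 and thr <= lo:
            break
    return None


def fit_ellipses(
    particles: list[ParticleMeasurement],
    arena: ArenaConfig,
    frame_index: int = 0,
) -> pd.DataFrame:
    """Convert particle second-moment ellipses to calibrated detections.

    Returns a DataFrame with columns ``frame, x_mm, y_mm, orientation_deg,
    major_mm, minor_mm, source_label``; orientation is the body axis in
    [0, 180).  Particles smaller than 3 px are skipped with a warning.
    """
    rows = []
    for p in particles:
        if p.area < 3:
            warnings.warn(f"skipping particle {p.label} with area {p.area} < 3 px", stacklevel=2)
            continue
        x, y = arena.pixel_to_mm(p.centroid[0], p.centroid[1])
        rows.append(
            {
                "frame": frame_index,
                "x_mm": float(x),
                "y_mm": float(y),
                "orientation_deg": p.orientation_deg % 180.0,
                "major_mm": p.major_axis_px * arena.mm_per_pixel,
                "minor_mm": p.minor_axis_px * arena.mm_per_pixel,
                "source_label": p.label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["frame", "x_mm", "y_mm", "orientation_deg", "major_mm", "minor_mm", "source_label"],
    )


def signed_angle_diff(a0: np.ndarray, a1: np.ndarray) -> np.ndarray:
    """Minimal signed rotation (degrees) taking axis angle ``a0`` to ``a1``.

    Body-axis orientations are 180-degree periodic, so the difference is
    reduced to (-90, 90]: e.g. 178 deg -> 2 deg is a +4 deg rotation.
    """
    return (np.asarray(a1) - np.asarray(a0) + 90.0) % 180.0 - 90.0


def match_frames(
    detections_t: pd.DataFrame,
    detections_t1: pd.DataFrame,
    config: TrackerConfig | None = None,
) -> tuple[pd.DataFrame, list[int], list[int]]:
    """Greedy closest-neighbour association between two frames.

    All cross pairs form the candidate set; the globally smallest centroid
    distance is paired and both ellipses are removed, repeating until the
    set is empty.  A selected pair whose displacement exceeds the distance
    gate or whose minimal mod-180 angle change exceeds the angle gate is
    rejected and both members are reported unmatched.  Exact distance ties
    break toward the lower detection index.

    Returns (pairs, unmatched_t, unmatched_t1); pairs has columns
    ``index_t, index_t1, delta_position_mm, delta_angle_deg``.
    """
    if config is None:
        config = TrackerConfig()
    n0, n1 = len(detections_t), len(detections_t1)
    cols = ["index_t", "index_t1", "delta_position_mm", "delta_angle_deg"]
    if n0 == 0 or n1 == 0:
        return pd.DataFrame(columns=cols), list(range(n0)), list(range(n1))
    p0 = detections_t[["x_mm", "y_mm"]].to_numpy(float)
    p1 = detections_t1[["x_mm", "y_mm"]].to_numpy(float)
    a0 = detections_t["orientation_deg"].to_numpy(float)
    a1 = detections_t1["orientation_deg"].to_numpy(float)
    dist = np.hypot(p0[:, 0:1] - p1[None, :, 0], p0[:, 1:2] - p1[None, :, 1])
    dang = signed_angle_diff(a0[:, None], a1[None, :])

    active = dist.copy()
    pairs = []
    unmatched_t: list[int] = []
    unmatched_t1: list[int] = []
    remaining0 = set(range(n0))
    remaining1 = set(range(n1))
    while remaining0 and remaining1:
        i, j = np.unravel_index(np.argmin(active), active.shape)
        d = active[i, j]
        if not np.isfinite(d):
            break
        if d > config.max_pair_distance or abs(dang[i, j]) > config.max_pair_angle:
            # gate violation: reject the pair, both members go unmatched
            if d > config.max_pair_distance:
                break  # greedy min is monotone; nothing closer remains
            unmatched_t.append(int(i))
            unmatched_t1.append(int(j))
        else:
            pairs.append(
                {
                    "index_t": int(i),
                    "index_t1": int(j),
                    "delta_position_mm": float(d),
                    "delta_angle_deg": float(dang[i, j]),
                }
            )
        active[i, :] = np.inf
        active[:, j] = np.inf
        remaining0.discard(int(i))
        remaining1.discard(int(j))
    unmatched_t.extend(sorted(remaining0))
    unmatched_t1.extend(sorted(remaining1))
    return pd.DataFrame(pairs, columns=cols), sorted(unmatched_t), sorted(unmatched_t1)


def compute_kinematics(steps: pd.DataFrame, fps: float) -> pd.DataFrame:
    """Add per-pair velocities: linear (mm/s), signed and absolute angular
    (deg/s) from the displacement and minimal mod-180 angle change."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    out = steps.copy()
    out["linear_velocity"] = out["delta_position_mm"] * fps
    out["angular_velocity"] = out["delta_angle_deg"] * fps
    out["abs_angular_velocity"] = out["angular_velocity"].abs()
    return out


def track_frames(
    frames: np.ndarray,
    background: np.ndarray,
    arena: ArenaConfig,
    config: TrackerConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[int, int]]]:
    """Run the full pipeline on a frame stack.

    Segments every frame, scores particle likelihood against the pooled
    session reference, resolves or excludes merged blobs, fits calibrated
    ellipses, and associates consecutive frames.

    Returns
    -------
    detections : DataFrame
        One row per detection (frame, x_mm, y_mm, orientation_deg,
        major_mm, minor_mm, source_label, det_index).
    steps : DataFrame
        One row per matched consecutive pair, with kinematics; ``index_t``
        and ``index_t1`` refer to ``det_index`` within each frame.
    exclusions : list of (frame, label)
        Low-likelihood particles that could not be split within the
        iteration cap and contribute no detections.
    """
    if config is None:
        config = TrackerConfig()
    per_frame: list[list[ParticleMeasurement]] = []
    for f in frames:
        labels = binarize_and_clean(
            f, background, config.initial_threshold, config.morphology_radius
        )
        per_frame.append(measure_particles(labels, min_area=config.min_particle_area))

    pooled = [p for ps in per_frame for p in ps]
    score_likelihood(pooled, config.likelihood_quantile)
    high_areas = [p.area for p in pooled if p.cls == "high"]
    mean_single_area = float(np.mean(high_areas)) if high_areas else float("nan")

    det_frames = []
    exclusions: list[tuple[int, int]] = []
    for fi, particles in enumerate(per_frame):
        keep: list[ParticleMeasurement] = []
        for p in particles:
            if p.cls == "high" or not np.isfinite(mean_single_area):
                keep.append(p)
                continue
            split = resolve_merged(frames[fi], background, p, mean_single_area, config)
            if split is None:
                exclusions.append((fi, p.label))
            else:
                keep.extend(split)
        det = fit_ellipses(keep, arena, frame_index=fi)
        det["det_index"] = np.arange(len(det))
        det_frames.append(det)
    detections = pd.concat(det_frames, ignore_index=True) if det_frames else pd.DataFrame()

    steps_all = []
    for fi in range(len(per_frame) - 1):
        d0 = det_frames[fi]
        d1 = det_frames[fi + 1]
        pairs, _, _ = match_frames(d0, d1, config)
        if len(pairs):
            pairs = compute_kinematics(pairs, arena.frames_per_second)
            pairs.insert(0, "frame_t", fi)
            pairs.insert(1, "frame_t1", fi + 1)
            steps_all.append(pairs)
    steps = (
        pd.concat(steps_all, ignore_index=True)
        if steps_all
        else pd.DataFrame(
            columns=[
                "frame_t",
                "frame_t1",
                "index_t",
                "index_t1",
                "delta_position_mm",
                "delta_angle_deg",
                "linear_velocity",
                "angular_velocity",
                "abs_angular_velocity",
            ]
        )
    )
    return detections, steps, exclusions
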