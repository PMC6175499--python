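"""Polar transformation of loop-plane samples and angle-time correlation.

When a phase-shifted gene pair traces a loop, a sample's angle about the
loop's center recapitulates its time.  The center is the point minimizing the
variance of sample radii (searched on a grid over the bounding box after
normalizing both axes to [0, 1]); angles are measured counterclockwise from
the positive x-axis and re-zeroed so that the baseline (time-0) samples sit
at 0 degrees.  Unwrapping the angles in time order and correlating with the
ordinal time rank scores how faithfully the loop encodes time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

logger = logging.getLogger("phaseloop")


@dataclass
class PolarLoop:
    """A fitted loop: gene pair, center, per-sample polar coordinates, score."""

    lead_gene: str
    lag_gene: str
    center: tuple[float, float]
    points: list[tuple[str, float, float, float]]  # (individual, time, angle_deg, radius)
    angle_time_rho: float

    def __post_init__(self) -> None:
        for _, _, angle, radius in self.points:
            if radius < 0:
                raise ValueError("radii must be nonnegative")
            if not 0 <= angle < 360:
                raise ValueError("angles must lie in [0, 360)")
        if not -1 <= self.angle_time_rho <= 1:
            raise ValueError("angle_time_rho must lie in [-1, 1]")


def normalize_ranges(points: np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Scale each dimension of an (n, 2) point cloud to the [0, 1] range.

    Returns the scaled points and the ``(mins, spans)`` needed to invert.
    """
    pts = np.asarray(points, dtype=float)
    mins = pts.min(axis=0)
    spans = pts.max(axis=0) - mins
    spans = np.where(spans <= 0, 1.0, spans)
    return (pts - mins) / spans, (mins, spans)


def _radius_variances(pts: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d = np.sqrt(
        (pts[None, :, 0] - centers[:, 0, None]) ** 2
        + (pts[None, :, 1] - centers[:, 1, None]) ** 2
    )
    return d.var(axis=1)  # population convention


def _grid(x0: float, x1: float, y0: float, y1: float, g: int) -> np.ndarray:
    xs = np.linspace(x0, x1, g)
    ys = np.linspace(y0, y1, g)
    # x-major order so np.argmin's first-hit tie-break prefers smallest (x, y)
    return np.column_stack([np.repeat(xs, g), np.tile(ys, g)])


def find_center(points: np.ndarray, grid_resolution: int = 101, refine: bool = True) -> tuple[float, float]:
    """Locate the loop center as the grid point minimizing radius variance.

    A ``grid_resolution`` x ``grid_resolution`` grid over the points' bounding
    box is scanned; ties go to the smallest (x, then y).  A 10x finer pass
    around the best coarse cell stabilises the answer.  Points are expected
    to be range-normalized already (see :func:`normalize_ranges`).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional points")
    span = pts.max(axis=0) - pts.min(axis=0)
    if np.all(span <= 1e-12):
        raise ValueError("all points identical; center undefined")
    centered = pts - pts.mean(axis=0)
    # collinear clouds have no loop: smallest singular value ~ 0
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] <= 1e-9 * max(sv[0], 1e-30):
        raise ValueError("points are collinear; center undefined")

    (x0, y0), (x1, y1) = pts.min(axis=0), pts.max(axis=0)
    centers = _grid(x0, x1, y0, y1, grid_resolution)
    variances = _radius_variances(pts, centers)
    best = centers[int(np.argmin(variances))]
    if refine and grid_resolution > 1:
        dx = (x1 - x0) / (grid_resolution - 1)
        dy = (y1 - y0) / (grid_resolution - 1)
        fine = _grid(best[0] - dx, best[0] + dx, best[1] - dy, best[1] + dy, 21)
        fine = np.vstack([best, fine])
        fine_var = _radius_variances(pts, fine)
        # keep the coarse winner unless a fine cell is strictly better
        order = np.lexsort((fine[:, 1], fine[:, 0]))
        ranked = fine[order]
        ranked_var = fine_var[order]
        if ranked_var.min() < fine_var[0]:
            best = ranked[int(np.argmin(ranked_var))]
    return float(best[0]), float(best[1])


def to_polar(
    points: np.ndarray,
    center: tuple[float, float],
    zero_angle: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Map points to (angle in degrees [0, 360), radius) about a center.

    Angles are counterclockwise from the positive x-axis, minus
    ``zero_angle`` (use :func:`baseline_zero_angle` to anchor the baseline
    samples at 0 degrees).  A point exactly at the center gets radius 0 and
    inherits the previous point's angle (with a warning).
    """
    pts = np.asarray(points, dtype=float)
    dx = pts[:, 0] - center[0]
    dy = pts[:, 1] - center[1]
    radii = np.hypot(dx, dy)
    angles = (np.degrees(np.arctan2(dy, dx)) - zero_angle) % 360.0
    at_center = radii <= 0
    if np.any(at_center):
        logger.warning(
            "%d point(s) coincide with the loop center; assigning the "
            "previous point's angle",
            int(at_center.sum()),
        )
        for i in np.flatnonzero(at_center):
            angles[i] = angles[i - 1] if i > 0 else 0.0
    return angles, radii


def from_polar(
    angles: np.ndarray,
    radii: np.ndarray,
    center: tuple[float, float],
    zero_angle: float = 0.0,
) -> np.ndarray:
    """Invert :func:`to_polar`."""
    theta = np.radians(np.asarray(angles, float) + zero_angle)
    r = np.asarray(radii, float)
    return np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
    )


def baseline_zero_angle(points: np.ndarray, center: tuple[float, float], baseline_mask) -> float:
    """Circular mean angle (degrees) of the baseline samples about the center."""
    pts = np.asarray(points, dtype=float)
    mask = np.asarray(baseline_mask, dtype=bool)
    if not mask.any():
        raise ValueError("no baseline samples to anchor 0 degrees")
    theta = np.arctan2(pts[mask, 1] - center[1], pts[mask, 0] - center[0])
    return float(np.degrees(np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())))


def unwrap_angles(angles: np.ndarray, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unwrap angles monotonically along the time axis.

    Working through the time ranks in order, each angle is shifted by a
    multiple of 360 degrees so it lies within 180 degrees of the previous
    rank's mean unwrapped angle (first rank: within (-180, 180]).  Returns
    the unwrapped angles and the integer time rank of every sample.
    """
    ang = np.asarray(angles, dtype=float)
    t = np.asarray(times, dtype=float)
    if ang.shape != t.shape:
        raise ValueError("angles and times must have equal length")
    uniq, ranks = np.unique(t, return_inverse=True)
    unwrapped = np.empty_like(ang)
    prev_mean = 0.0
    for r in range(len(uniq)):
        sel = ranks == r
        a = ang[sel]
        k = np.ceil((prev_mean - 180.0 - a) / 360.0)
        u = a + 360.0 * k
        unwrapped[sel] = u
        prev_mean = float(u.mean())
    return unwrapped, ranks


def unwrap_and_correlate(angles: np.ndarray, times: np.ndarray) -> float:
    """Pearson correlation of unwrapped angle versus ordinal time rank.

    Time enters on an ordinal scale (rank of the time point) because
    longitudinal grids are typically uneven and a late sample would otherwise
    dominate the fit.
    """
    ang = np.asarray(angles, dtype=float)
    t = np.asarray(times, dtype=float)
    if ang.size < 3:
        raise ValueError("need at least 3 samples")
    if np.unique(t).size < 2:
        raise ValueError("all samples share one time; correlation undefined")
    unwrapped, ranks = unwrap_angles(ang, t)
    return float(pearsonr(unwrapped, ranks.astype(float))[0])


def fit_polar_loop(ds, lead_gene: str, lag_gene: str, grid_resolution: int = 101) -> PolarLoop:
    """Fit the polar geometry of a gene pair's loop on a dataset.

    The two genes' expression values form the loop plane; both axes are
    range-normalized, the minimum-radius-variance center is fitted, angles
    are re-zeroed to the centroid of the earliest-time samples, and the
    angle-time correlation is computed on the ordinal time scale.
    """
    raw = np.column_stack([ds.gene_values(lead_gene), ds.gene_values(lag_gene)])
    pts, _ = normalize_ranges(raw)
    center = find_center(pts, grid_resolution=grid_resolution)
    times = np.array([t for _, t in ds.samples])
    zero = baseline_zero_angle(pts, center, times == times.min())
    angles, radii = to_polar(pts, center, zero_angle=zero)
    rho = unwrap_and_correlate(angles, times)
    points = [
        (ind, float(t), float(a), float(r))
        for (ind, t), a, r in zip(ds.samples, angles, radii)
    ]
    return PolarLoop(
        lead_gene=lead_gene,
        lag_gene=lag_gene,
        center=(float(center[0]), float(center[1])),
        points=points,
        angle_time_rho=rho,
    )
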