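"""Contour tracking, pole/growth-axis extraction, and kymographs.

The tube outline is represented by points regularly spaced in arc length
along a cubic spline.  Tracking moves each point along its local normal
to the position of maximum intensity-gradient magnitude (sub-pixel by
parabolic refinement of the gradient profile), then re-splines.  The
growth axis is the longest of the orthogonal paths leading from the last
outline back to the first by successive minimal-distance projections;
its intersection with each outline is the pole.  The tip velocity is the
along-axis displacement of a five-point neighbourhood around the pole.
Kymographs reslice the stack along a 1-pixel-wide line on the growth
axis, one row per frame.

Coordinate convention: pixel centres at integer coordinates, origin at
the top-left, x = column, y = row; used everywhere including kymograph
sampling.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import splev, splprep
from scipy.ndimage import map_coordinates

from .records import VelocityTimeSeries

__all__ = [
    "Outline",
    "GrowthAxis",
    "Kymograph",
    "TrackingError",
    "spline_contour",
    "track_outline",
    "growth_axis_and_pole",
    "tip_velocity_series",
    "tube_width",
    "build_kymograph",
    "kymograph_cycle_measurements",
    "auto_initial_outline",
]


class TrackingError(RuntimeError):
    """Raised when the edge is lost for too many contour points."""


@dataclass
class Outline:
    """Contour points (x, y) in pixel coordinates, uniform in arc length."""

    points: np.ndarray
    frame: int = -1
    spacing: float = 0.0
    closed: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")


@dataclass
class GrowthAxis:
    """Growth axis line, pole trajectory (one point per frame) and path length."""

    poles: np.ndarray
    length: float
    non_growing: bool = False
    direction_vec: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    @property
    def direction(self) -> np.ndarray:
        return self.direction_vec


@dataclass
class Kymograph:
    """Space-time reslice: rows = frames, columns = position along the axis."""

    image: np.ndarray
    row_interval_s: float
    col_scale_um: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.image = np.asarray(self.image)


# ---------------------------------------------------------------------------
# splining
# ---------------------------------------------------------------------------

def spline_contour(rough_points, n_points: int, closed: bool = False,
                   smoothing: float = 0.0) -> Outline:
    """Cubic-spline the rough points and resample to equal arc length.

    Closed contours use a periodic spline; open (tip-spanning) curves a
    clamped one.  Raises on degenerate (collinear) input, for which no
    area-enclosing contour exists.
    """
    pts = np.asarray(rough_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise ValueError("need at least 4 (x, y) rough points")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if closed and sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("rough points are collinear; no contour")

    work = np.vstack([pts, pts[:1]]) if closed else pts
    chord = np.linalg.norm(np.diff(work, axis=0), axis=1)
    if np.any(chord == 0):
        keep = np.concatenate([[True], chord > 0])
        work = work[keep]
        if len(work) < 4:
            raise ValueError("too many duplicate points")
    u = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(work, axis=0), axis=1))])
    u /= u[-1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if closed:
            tck, _ = splprep([work[:, 0], work[:, 1]], u=u, s=smoothing, per=1, k=3)
        else:
            tck, _ = splprep([work[:, 0], work[:, 1]], u=u, s=smoothing, k=3)

    n_dense = 20 * max(n_points, len(work)) + 1
    ud = np.linspace(0.0, 1.0, n_dense)
    xd, yd = splev(ud, tck)
    dense = np.column_stack([xd, yd])
    arc = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    total = arc[-1]
    if closed:
        targets = np.arange(n_points) * total / n_points
        spacing = total / n_points
    else:
        targets = np.linspace(0.0, total, n_points)
        spacing = total / (n_points - 1)
    ut = np.interp(targets, arc, ud)
    xs, ys = splev(ut, tck)
    return Outline(np.column_stack([xs, ys]), spacing=spacing, closed=closed)


def _normals(pts: np.ndarray, closed: bool) -> np.ndarray:
    """Unit normals from central-difference tangents (one-sided at open ends)."""
    if closed:
        tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    else:
        tang = np.empty_like(pts)
        tang[1:-1] = pts[2:] - pts[:-2]
        tang[0] = pts[1] - pts[0]
        tang[-1] = pts[-1] - pts[-2]
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tang /= norms
    return np.column_stack([-tang[:, 1], tang[:, 0]])


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def _edge_displacements(img: np.ndarray, pts: np.ndarray, normals: np.ndarray,
                        search_radius: float, step: float,
                        min_gradient: float):
    """Per-point normal displacement to the maximum-gradient position."""
    offsets = np.arange(-search_radius, search_radius + step / 2, step)
    coords = pts[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    vals = map_coordinates(img, [coords[..., 1].ravel(), coords[..., 0].ravel()],
                           order=1, mode="nearest").reshape(offsets.size, len(pts))
    grad = np.abs(np.gradient(vals, step, axis=0))
    j = np.argmax(grad, axis=0)
    peak = grad[j, np.arange(len(pts))]
    lost = peak < min_gradient
    j = np.clip(j, 1, offsets.size - 2)
    gm1 = grad[j - 1, np.arange(len(pts))]
    g0 = grad[j, np.arange(len(pts))]
    gp1 = grad[j + 1, np.arange(len(pts))]
    denom = gm1 - 2.0 * g0 + gp1
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom < 0, 0.5 * (gm1 - gp1) / denom, 0.0)
    delta = np.clip(delta, -1.0, 1.0)
    disp = offsets[j] + delta * step
    disp[lost] = 0.0
    return disp, lost


def track_outline(stack: np.ndarray, initial: Outline,
                  search_radius: float = 5.0, step: float = 0.25,
                  min_gradient_frac: float = 0.05,
                  max_lost_frac: float = 0.10,
                  clamp_ends: bool = True,
                  smoothing_per_point: float = 0.2) -> list:
    """Track the outline across all frames of the stack.

    Each contour point moves along its local normal to the
    maximum-gradient position within ±``search_radius`` pixels, then the
    contour is re-splined to uniform arc length.  The initial outline is
    refined twice on frame 0 before tracking proceeds.  Open contours
    keep their endpoints clamped (the distal, grain-side end of the tube
    does not move).  If the edge is lost (no sufficient gradient peak)
    for more than ``max_lost_frac`` of the points in a frame, tracking
    fails with :class:`TrackingError`.

    ``smoothing_per_point`` is the spline smoothing allowance per contour
    point (squared pixels); a small positive value irons out creases that
    otherwise self-amplify at the high-curvature tip during growth bursts.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    n = len(initial.points)
    closed = initial.closed
    pts = initial.points.copy()
    ends = (initial.points[0].copy(), initial.points[-1].copy())
    outlines = []
    for f in range(stack.shape[0]):
        img = stack[f].astype(float)
        # absolute floor so a featureless frame counts as a lost edge
        thresh = max(min_gradient_frac * float(img.max() - img.min()), 1e-6)
        for _ in range(2 if f == 0 else 1):
            normals = _normals(pts, closed)
            disp, lost = _edge_displacements(img, pts, normals,
                                             search_radius, step, thresh)
            if lost.mean() > max_lost_frac:
                raise TrackingError(
                    f"edge lost for {lost.mean():.0%} of points at frame {f}")
            pts = pts + disp[:, None] * normals
            if clamp_ends and not closed:
                pts[0], pts[-1] = ends
            pts = spline_contour(pts, n, closed=closed,
                                 smoothing=smoothing_per_point * n).points
            if clamp_ends and not closed:
                pts[0], pts[-1] = ends
        outlines.append(Outline(pts.copy(), frame=f, closed=closed,
                                spacing=float(np.linalg.norm(
                                    pts[1] - pts[0]))))
    return outlines


# ---------------------------------------------------------------------------
# pole, growth axis, velocity, width
# ---------------------------------------------------------------------------

def _nearest_on_polyline(poly: np.ndarray, p: np.ndarray,
                         closed: bool = False) -> np.ndarray:
    """Closest point to p on the polyline (with segment interpolation)."""
    a = poly
    b = np.roll(poly, -1, axis=0) if closed else poly[1:]
    a = a if closed else poly[:-1]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", proj - p, proj - p)
    return proj[np.argmin(d2)]


def growth_axis_and_pole(outlines, min_length: float = 1.0) -> GrowthAxis:
    """Growth axis: the longest orthogonal path from last outline to first.

    From each point of the last outline a path is traced backwards by
    projecting onto the nearest point of each preceding outline; the
    longest such path defines the growth axis, and its intersection with
    each outline is the pole at that frame.  A net tip displacement below
    ``min_length`` pixels is reported as non-growing (contour jitter sums
    along a path but does not displace it).
    """
    if len(outlines) < 2:
        raise ValueError("need at least 2 outlines")
    paths, lengths = [], []
    for p in outlines[-1].points:
        path = [p]
        total = 0.0
        for ol in outlines[-2::-1]:
            q = _nearest_on_polyline(ol.points, path[-1], ol.closed)
            total += float(np.linalg.norm(q - path[-1]))
            path.append(q)
        paths.append(path)
        lengths.append(total)
    lengths = np.asarray(lengths)
    best_len = float(lengths.max())
    best = np.asarray(paths[int(np.argmax(lengths))][::-1])
    net = float(np.linalg.norm(best[-1] - best[0]))
    if net < min_length:
        return GrowthAxis(poles=best, length=net, non_growing=True)

    # On a blunt tip the trajectory length is nearly flat over an arc of
    # starting points around the apex, so the single longest path is
    # laterally arbitrary; averaging the near-longest paths (which
    # straddle the apex symmetrically) recovers the central trajectory.
    near = lengths >= 0.98 * best_len
    path = np.mean(np.asarray([paths[i] for i in np.where(near)[0]]),
                   axis=0)[::-1]

    # axis line: total-least-squares fit through the averaged path
    center = path.mean(axis=0)
    _, _, vt = np.linalg.svd(path - center)
    u = vt[0]
    if u @ (path[-1] - path[0]) < 0:
        u = -u
    poles = np.array([_line_outline_intersection(ol.points, center, u)
                      for ol in outlines])
    return GrowthAxis(poles=poles, length=best_len, direction_vec=u)


def _line_outline_intersection(pts: np.ndarray, origin: np.ndarray,
                               direction: np.ndarray) -> np.ndarray:
    """Apical intersection of the axis line with a contour polyline."""
    rel = pts - origin
    eta = rel[:, 0] * direction[1] - rel[:, 1] * direction[0]  # cross product
    xi = rel @ direction
    best_xi, best_pt = -np.inf, None
    for i in range(len(pts) - 1):
        e0, e1 = eta[i], eta[i + 1]
        if e0 == 0.0 and e1 == 0.0:
            continue
        if e0 == 0.0 or e0 * e1 < 0:
            w = e0 / (e0 - e1) if e0 != e1 else 0.0
            x = xi[i] + w * (xi[i + 1] - xi[i])
            if x > best_xi:
                best_xi = x
                best_pt = pts[i] + w * (pts[i + 1] - pts[i])
    if best_pt is None:
        # no crossing (contour entirely on one side): fall back to the
        # contour point furthest along the axis
        best_pt = pts[int(np.argmax(xi))]
    return np.asarray(best_pt, dtype=float)


def tip_velocity_series(outlines, axis: GrowthAxis, pixel_scale: float,
                        frame_interval: float, neighborhood: int = 2,
                        cell_id: str = "cell") -> VelocityTimeSeries:
    """Tip velocity from pole displacement, in μm/s.

    Per frame, the pole's (2·``neighborhood`` + 1)-point contour
    neighbourhood is averaged; the velocity is the frame-to-frame
    displacement of that average projected on the growth-axis direction,
    one sample per frame interval (placed at mid-interval times).  A
    non-growing axis has no elongation direction, so the series is zero.
    """
    if axis.non_growing:
        n = len(outlines) - 1
        t = (np.arange(n) + 0.5) * frame_interval
        return VelocityTimeSeries(t, np.zeros(n), frame_interval, cell_id)
    direction = axis.direction
    centers = []
    for ol, pole in zip(outlines, axis.poles):
        d2 = np.einsum("ij,ij->i", ol.points - pole, ol.points - pole)
        i = int(np.argmin(d2))
        lo, hi = max(i - neighborhood, 0), min(i + neighborhood + 1, len(ol.points))
        centers.append(ol.points[lo:hi].mean(axis=0))
    centers = np.asarray(centers)
    disp = (centers[1:] - centers[:-1]) @ direction
    v = disp * pixel_scale / frame_interval
    t = (np.arange(v.size) + 0.5) * frame_interval
    return VelocityTimeSeries(t, v, frame_interval, cell_id)


def tube_width(outline: Outline, axis: GrowthAxis, positions,
               pixel_scale: float = 1.0) -> np.ndarray:
    """Tube width at fixed distances behind the pole, in μm.

    For each distance the contour is intersected with the normal plane of
    the growth axis and the chord between the opposing flanks measured.
    Positions beyond the outline's extent are skipped with a warning
    (NaN in the result).
    """
    direction = axis.direction
    normal = np.array([-direction[1], direction[0]])
    pole = axis.poles[-1] if outline.frame < 0 or \
        outline.frame >= len(axis.poles) else axis.poles[outline.frame]
    xi = (outline.points - pole) @ direction
    eta = (outline.points - pole) @ normal
    widths = []
    for dist in np.atleast_1d(positions):
        target = -float(dist) / pixel_scale
        f = xi - target
        crossings = []
        for i in range(len(f) - 1):
            if f[i] == 0:
                crossings.append(eta[i])
            elif f[i] * f[i + 1] < 0:
                w = f[i] / (f[i] - f[i + 1])
                crossings.append(eta[i] + w * (eta[i + 1] - eta[i]))
        if len(crossings) < 2:
            warnings.warn(f"position {dist} beyond outline extent; skipped")
            widths.append(float("nan"))
        else:
            widths.append((max(crossings) - min(crossings)) * pixel_scale)
    return np.asarray(widths)


# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------

def build_kymograph(stack: np.ndarray, axis_line, pixel_scale: float,
                    frame_interval: float, edges: bool = False) -> Kymograph:
    """Reslice the stack along a 1-pixel-wide line into a space-time image.

    ``axis_line`` is ((x0, y0), (x1, y1)) in pixel coordinates; intensities
    are sampled at 1-pixel spacing by nearest-pixel lookup, one row per
    frame.  With ``edges=True`` each row is replaced by its
    gradient-magnitude profile with inverted histogram, enhancing the
    cell-edge trace.
    """
    stack = np.asarray(stack)
    (x0, y0), (x1, y1) = axis_line
    p0 = np.array([x0, y0], dtype=float)
    p1 = np.array([x1, y1], dtype=float)
    length = np.linalg.norm(p1 - p0)
    if length == 0:
        raise ValueError("axis line has zero length")
    n_cols = int(np.floor(length)) + 1
    unit = (p1 - p0) / length
    samples = p0[None, :] + np.arange(n_cols)[:, None] * unit[None, :]
    cols = np.rint(samples[:, 0]).astype(int)
    rows = np.rint(samples[:, 1]).astype(int)
    h, w = stack.shape[1:]
    if cols.min() < 0 or cols.max() >= w or rows.min() < 0 or rows.max() >= h:
        raise ValueError("axis line outside the image")
    image = stack[:, rows, cols].astype(float)
    if edges:
        grad = np.abs(np.gradient(image, axis=1))
        image = grad.max() - grad
    return Kymograph(image=image, row_interval_s=frame_interval,
                     col_scale_um=pixel_scale, origin=p0)


def _tip_trace(kymo: Kymograph) -> np.ndarray:
    """Sub-pixel tip-edge column per row (maximum-gradient localisation)."""
    img = kymo.image.astype(float)
    grad = np.abs(np.gradient(img, axis=1))
    j = np.argmax(grad, axis=1)
    j = np.clip(j, 1, img.shape[1] - 2)
    rows = np.arange(img.shape[0])
    gm1, g0, gp1 = grad[rows, j - 1], grad[rows, j], grad[rows, j + 1]
    denom = gm1 - 2.0 * g0 + gp1
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom < 0, 0.5 * (gm1 - gp1) / denom, 0.0)
    return j + np.clip(delta, -0.5, 0.5)


def kymograph_cycle_measurements(kymo: Kymograph,
                                 prominence_frac: float = 0.2,
                                 min_amplitude_frac: float = 0.1,
                                 integer_pixels: bool = False) -> pd.DataFrame:
    """Per-cycle wavelength and period read from the kymograph tip edge.

    The tip edge is traced row by row (maximum gradient, sub-pixel), its
    row-to-row displacement gives a velocity record, and the standard
    smoothing + maxima segmentation yields cycles.  Results are reported
    both in physical units and in kymograph pixels (columns for λ, rows
    for τ); ``integer_pixels=True`` rounds the pixel values to the
    reading convention of a manual kymograph measurement.
    """
    from .kinematics import detect_cycle_boundaries, segment_cycles, smooth_velocity

    tip = _tip_trace(kymo)
    if tip.size < 8:
        raise ValueError("kymograph too short to trace cycles")
    v_um_s = np.diff(tip) * kymo.col_scale_um / kymo.row_interval_s
    t = (np.arange(v_um_s.size) + 0.5) * kymo.row_interval_s
    series = VelocityTimeSeries(t, v_um_s, kymo.row_interval_s, "kymograph")
    smoothed = smooth_velocity(series)
    # quantisation wiggle on a steady edge is not an oscillation
    amp = float(smoothed.v.max() - smoothed.v.min())
    if amp < min_amplitude_frac * abs(float(np.mean(smoothed.v))):
        boundaries = np.array([])
    else:
        boundaries = detect_cycle_boundaries(smoothed, prominence_frac)
    cycles = segment_cycles(series, boundaries)
    if not cycles:
        return pd.DataFrame(columns=["cycle_index", "t_start_s", "tau_s",
                                     "lambda_um", "tau_rows", "lambda_cols"])
    df = pd.DataFrame({
        "cycle_index": [c.index for c in cycles],
        "t_start_s": [c.t_start for c in cycles],
        "tau_s": [c.tau for c in cycles],
        "lambda_um": [c.lam for c in cycles],
    })
    df["tau_rows"] = df["tau_s"] / kymo.row_interval_s
    df["lambda_cols"] = df["lambda_um"] / kymo.col_scale_um
    if integer_pixels:
        df["tau_rows"] = df["tau_rows"].round().astype(int)
        df["lambda_cols"] = df["lambda_cols"].round().astype(int)
    return df


# ---------------------------------------------------------------------------
# initialisation helper
# ---------------------------------------------------------------------------

def auto_initial_outline(frame: np.ndarray, n_points: int = 200,
                         dark_tube: bool = True) -> Outline:
    """Rough open outline of a horizontally growing tube from one frame.

    Thresholds the frame at the mid-intensity, estimates the tube's
    centreline row, radius and tip column from the mask, and returns the
    splined capped-tube outline.  Intended for synthetic or high-contrast
    stacks where the tube is the single dominant object.
    """
    from .synthetic import rough_outline_points

    img = np.asarray(frame, dtype=float)
    thresh = 0.5 * (img.max() + img.min())
    mask = img < thresh if dark_tube else img > thresh
    if not mask.any():
        raise ValueError("no object found at the mid-intensity threshold")
    cols = np.where(mask.any(axis=0))[0]
    tip_x = float(cols.max())
    heights = mask[:, cols].sum(axis=0)
    radius = 0.5 * float(np.median(heights))
    rows = np.where(mask.any(axis=1))[0]
    yc = 0.5 * (rows.min() + rows.max())
    rough = rough_outline_points(tip_x, yc, radius)
    return spline_contour(rough, n_points, closed=False)
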