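"""Star-shot analysis: an independent isocenter estimate from strip films.

A star shot exposes narrow collimator slits at several gantry (or
collimator) angles onto one film; every strip centerline passes through
the rotation's isocenter.  This module reconstructs that point from the
image alone: strips are detected on two concentric circular profiles, each
strip's centerline is fitted through the opposing-edge midpoints, and the
isocenter estimate is the center of the minimum enclosing circle of all
pairwise centerline intersections (the conventional "circle touching all
lines" report).  It serves as the cross-validation oracle for the
EPID-based method; the two share no measurement code.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import ROOM_AXES


class StarshotError(ValueError):
    pass


@dataclass
class StarshotResult:
    """isocenter_estimate_mm is relative to the reference (laser) point."""

    isocenter_estimate_mm: tuple[float, float]
    max_line_distance_mm: float
    n_strips: int
    laser_offset_mm: tuple[float, float] | None = None


def _angular_profile(image, cx_px, cy_px, radius_px, n=2160):
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    cols = cx_px + radius_px * np.cos(theta)
    rows = cy_px + radius_px * np.sin(theta)
    vals = ndimage.map_coordinates(image, [rows, cols], order=1, mode="nearest")
    return theta, vals


def _run_centers(theta, vals):
    """Angular centers of above-half-maximum runs, with wraparound."""
    lo = float(np.percentile(vals, 20))
    hi = float(np.percentile(vals, 99.5))
    if hi - lo <= 0:
        raise StarshotError("no strips visible on the circular profile")
    mask = vals > (lo + hi) / 2.0
    if mask.all() or not mask.any():
        raise StarshotError("strips indistinguishable on the circular profile")
    # rotate so the profile starts outside a run, then split into runs
    start = int(np.argmin(mask))
    m = np.roll(mask, -start)
    t = np.roll(theta, -start)
    step = np.diff(m.astype(int))
    rises = np.flatnonzero(step == 1)
    falls = np.flatnonzero(step == -1)
    centers = []
    for r, f in zip(rises, falls):
        seg = t[r + 1 : f + 1]
        # circular mean of the run's angles
        centers.append(float(np.arctan2(np.sin(seg).mean(), np.cos(seg).mean()) % (2 * np.pi)))
    return centers


def _ang_dist(a, b):
    return abs(float(np.angle(np.exp(1j * (a - b)))))


def _fit_line(points):
    """Total-least-squares line through points: (point_on_line, direction)."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[0]


def _line_intersection(p1, d1, p2, d2):
    a = np.array([[d1[0], -d2[0]], [d1[1], -d2[1]]])
    b = p2 - p1
    det = np.linalg.det(a)
    if abs(det) < 1e-9:
        return None
    t = np.linalg.solve(a, b)
    return p1 + t[0] * d1


def _min_enclosing_circle(points):
    """Exact minimum enclosing circle by brute force over pairs/triples."""
    pts = [np.asarray(p, dtype=float) for p in points]
    if len(pts) == 1:
        return pts[0], 0.0
    best = None
    for a, b in combinations(pts, 2):
        c = (a + b) / 2.0
        r = float(np.linalg.norm(a - c))
        if all(np.linalg.norm(p - c) <= r + 1e-9 for p in pts):
            if best is None or r < best[1]:
                best = (c, r)
    for a, b, c3 in combinations(pts, 3):
        # circumcenter
        d = 2 * (a[0] * (b[1] - c3[1]) + b[0] * (c3[1] - a[1]) + c3[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            continue
        ux = (
            (a @ a) * (b[1] - c3[1]) + (b @ b) * (c3[1] - a[1]) + (c3 @ c3) * (a[1] - b[1])
        ) / d
        uy = (
            (a @ a) * (c3[0] - b[0]) + (b @ b) * (a[0] - c3[0]) + (c3 @ c3) * (b[0] - a[0])
        ) / d
        c = np.array([ux, uy])
        r = float(np.linalg.norm(a - c))
        if all(np.linalg.norm(p - c) <= r + 1e-9 for p in pts):
            if best is None or r < best[1]:
                best = (c, r)
    if best is None:  # collinear degenerate fallback
        c = np.mean(pts, axis=0)
        best = (c, max(float(np.linalg.norm(p - c)) for p in pts))
    return best


def analyze_starshot(
    image: np.ndarray,
    pixel_mm: float,
    reference_point_mm: tuple[float, float] = (0.0, 0.0),
    min_strips: int = 3,
    radii_mm: tuple[float, float] = (20.0, 32.0),
) -> StarshotResult:
    """Locate the star-shot isocenter on a film/EPID strip image.

    ``image`` is a 2-D intensity array whose center pixel is the film
    center; x (columns) and y (rows) are converted to mm via ``pixel_mm``.
    The estimate is reported relative to ``reference_point_mm`` (the
    laser-marked reference), in the same (x, y) frame.
    """
    img = ndimage.gaussian_filter(np.asarray(image, dtype=float), 1.0)
    n_rows, n_cols = img.shape
    cy, cx = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0

    # rough intersection: the strips overlap there, so a heavy blur peaks on
    # it; profiling circles around that point keeps opposing crossings of
    # one strip nearly diametral, which makes the run pairing unambiguous
    heavy = ndimage.gaussian_filter(img, 3.0 / pixel_mm)
    ry, rx = np.unravel_index(int(np.argmax(heavy)), heavy.shape)
    rough_mm = np.array([(rx - cx) * pixel_mm, (ry - cy) * pixel_mm])

    lines = []  # (point_mm, direction), relative to the rough center
    per_radius_centers = []
    for r_mm in radii_mm:
        theta, vals = _angular_profile(img, rx, ry, r_mm / pixel_mm)
        centers = _run_centers(theta, vals)
        per_radius_centers.append(centers)
    n_runs = len(per_radius_centers[0])
    if n_runs % 2 or any(len(c) != n_runs for c in per_radius_centers):
        raise StarshotError("strips indistinguishable (inconsistent crossings)")
    n_strips = n_runs // 2
    if n_strips < min_strips:
        raise StarshotError(f"need at least {min_strips} strips, found {n_strips}")

    # group the runs of each radius into strips: each strip crosses every
    # circle twice, roughly 180 deg apart
    ref_angles = sorted(per_radius_centers[0])
    unused = list(ref_angles)
    strip_angle_pairs = []
    while unused:
        a = unused.pop(0)
        partner = min(unused, key=lambda b: abs(_ang_dist(a, b) - np.pi))
        if abs(_ang_dist(a, partner) - np.pi) > np.deg2rad(20):
            raise StarshotError("strips indistinguishable (no opposing crossing)")
        unused.remove(partner)
        strip_angle_pairs.append((a, partner))
    for a, partner in strip_angle_pairs:
        pts = []
        for r_mm, centers in zip(radii_mm, per_radius_centers):
            for target in (a, partner):
                b = min(centers, key=lambda c: _ang_dist(c, target))
                pts.append((r_mm * np.cos(b), r_mm * np.sin(b)))
        lines.append(_fit_line(pts))

    intersections = []
    for (p1, d1), (p2, d2) in combinations(lines, 2):
        x = _line_intersection(p1, d1, p2, d2)
        if x is not None:
            intersections.append(x)
    if not intersections:
        raise StarshotError("strip centerlines do not intersect")
    center, _ = _min_enclosing_circle(intersections)
    max_dist = max(
        abs(d[0] * (center - p)[1] - d[1] * (center - p)[0]) / float(np.linalg.norm(d))
        for p, d in lines
    )
    ref = np.asarray(reference_point_mm, dtype=float)
    est = rough_mm + center - ref
    return StarshotResult(
        isocenter_estimate_mm=(float(est[0]), float(est[1])),
        max_line_distance_mm=max_dist,
        n_strips=len(lines),
        laser_offset_mm=(float(est[0]), float(est[1])),
    )


def cross_validate(truth, vendor: str = "varian", **render_kwargs) -> dict:
    """EPID method vs star shot on one shared simulated ground truth.

    Renders a full EPID session plus an axial star shot (lateral/vertical)
    and a coronal two-strip star shot (longitudinal), analyses each with
    its own pipeline and returns the per-dimension estimates and
    ``disagreement_mm`` (the maximum absolute difference).
    """
    from .pipeline import analyze_images
    from .solver import plan_acquisition
    from .synthetic import render_coronal_starshot, render_session, render_starshot

    plan = plan_acquisition(vendor, "full")
    epid = analyze_images(render_session(truth, plan, **render_kwargs))

    pixel_mm = 0.2
    axial = analyze_starshot(render_starshot(truth, pixel_mm=pixel_mm), pixel_mm)
    coronal = analyze_starshot(
        render_coronal_starshot(truth, pixel_mm=pixel_mm), pixel_mm, min_strips=2
    )
    star = {
        "lateral": axial.isocenter_estimate_mm[0],
        "vertical": axial.isocenter_estimate_mm[1],
        "longitudinal": coronal.isocenter_estimate_mm[1],
    }
    diffs = {d: abs(epid.S_bar_mm[d] - star[d]) for d in ROOM_AXES}
    return {
        "epid_mm": dict(epid.S_bar_mm),
        "starshot_mm": star,
        "per_dimension_mm": diffs,
        "disagreement_mm": max(diffs.values()),
    }


def read_film(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read a 16-bit grayscale TIFF/PNG star-shot image.

    Returns (image, pixel_mm or None if the file carries no resolution).
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            img = page.asarray().astype(float)
            pixel_mm = None
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is not None and unit is not None and unit.value == 3:  # cm
                num, den = res.value
                pixel_mm = 10.0 / (num / den)
        return img, pixel_mm
    from PIL import Image

    return np.asarray(Image.open(path), dtype=float), None
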