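"""Physically motivated renderer for synthetic portal images and star shots.

The renderer emulates what a megavoltage portal image of the cuboidal QA
phantom looks like: an open-field plateau bounded by four jaw edges with
error-function penumbra, the diverging projection of a hollow cuboid
phantom (solid ABS walls, less dense interior, a denser central crosshair
plane pair), Gaussian pixel noise, and SID/SAD magnification.  Every image
derives from a :class:`SimulationTruth` carrying the ground-truth phantom
offset and per-jaw calibration errors, so downstream modules can be tested
closed-loop without a linac.

The attenuation model is deliberately simple -- exponential attenuation of
ray-box chord lengths at a single effective energy, no scatter or beam
hardening -- because edge localization only needs realistic gradients, not
dosimetric fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import ndtr  # standard normal CDF

from .dicom_io import PortalImage, write_portal_image
from .geometry import JAWS, normalize_angle, panel_basis, pixel_grid_iso, source_position

# phantom geometry (mm): a hollow cube of stacked blocks
PHANTOM_HALF_WIDTH_MM = 40.0
PHANTOM_WALL_MM = 6.0
PHANTOM_INTERIOR_FILL = 0.25
CROSSHAIR_HALF_MM = 0.75

# effective linear attenuation of solid ABS at megavoltage energy (1/mm)
MU_SOLID = 0.0047
MU_CROSSHAIR = 0.0040

PLATEAU = 4000.0  # open-field signal level (arbitrary detector units)
JAW_LEAK = 0.02  # transmission through a closed jaw
FOCAL_BLUR_MM = 0.7  # effective source-size blur at the panel, mm
MLC_LEAF_WIDTH_MM = 10.0  # projected leaf width at the isocenter plane


class RenderError(ValueError):
    pass


def _default_jaw_offsets() -> dict[str, float]:
    return {j: 0.0 for j in JAWS}


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth behind a rendered session.

    phantom_offset_mm : (lateral, longitudinal, vertical) displacement of
        the phantom center from the radiation isocenter, mm.
    jaw_offsets_mm : per-jaw calibration error; positive opens the field on
        that side (the jaw edge moves outward by the given amount).
    collimator_walkout_mm : amplitude of collimator-rotation runout; the
        field center traces a circle of this radius as the collimator turns.
    penumbra_sigma_mm : field-edge softness (Gaussian sigma) at the
        isocenter plane.
    noise_sd : additive Gaussian noise as a fraction of the open-field
        plateau.
    seed : base seed; a fixed seed gives bitwise-identical renders.
    """

    phantom_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    jaw_offsets_mm: dict[str, float] = field(default_factory=_default_jaw_offsets)
    collimator_walkout_mm: float = 0.0
    penumbra_sigma_mm: float = 1.5
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if max(abs(c) for c in self.phantom_offset_mm) > 5.0:
            raise RenderError("phantom offset components must stay within +-5 mm")
        offsets = dict(_default_jaw_offsets(), **self.jaw_offsets_mm)
        unknown = set(offsets) - set(JAWS)
        if unknown:
            raise RenderError(f"unknown jaw labels {sorted(unknown)}")
        object.__setattr__(self, "jaw_offsets_mm", offsets)
        if self.collimator_walkout_mm < 0 or self.collimator_walkout_mm > 1.0:
            raise RenderError("collimator walkout amplitude must be in [0, 1] mm")
        if self.penumbra_sigma_mm <= 0:
            raise RenderError("penumbra sigma must be > 0")
        if self.noise_sd < 0:
            raise RenderError("noise_sd must be >= 0")

    def mlc_leaf_jitter(self, n_leaves: int = 40, max_dev_mm: float = 1.0) -> np.ndarray:
        """Per-leaf edge deviations for a jagged MLC-defined edge.

        Deviations are uniform within +-max_dev_mm (adjacent-leaf steps of
        up to ~1 mm are common on older MLCs) and are a fixed property of
        the simulated machine: they depend only on the seed, not the view.
        """
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 777]))
        return rng.uniform(-max_dev_mm, max_dev_mm, n_leaves)


def _ray_box_chords(
    src: np.ndarray, dirs: list, center: np.ndarray, half: np.ndarray
) -> np.ndarray:
    """Chord length of each pixel ray through an axis-aligned box (mm).

    ``dirs`` holds the three room-axis components of the (unnormalised)
    ray direction source->pixel as mutually broadcastable arrays.  Uses the
    standard slab method with t=0 at the source and t=1 at the pixel.
    """
    d_norm_sq = 0.0
    tmin = None
    tmax = None
    for k in range(3):
        dk = np.asarray(dirs[k], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (center[k] - half[k] - src[k]) / dk
            t2 = (center[k] + half[k] - src[k]) / dk
        lo = np.minimum(t1, t2)
        hi = np.maximum(t1, t2)
        # rays parallel to a slab pair: inside -> (-inf, inf), outside -> empty
        parallel = np.isclose(dk, 0.0)
        if np.any(parallel):
            inside = np.abs(src[k] - center[k]) <= half[k]
            lo = np.where(parallel, -np.inf if inside else np.inf, lo)
            hi = np.where(parallel, np.inf if inside else -np.inf, hi)
        tmin = lo if tmin is None else np.maximum(tmin, lo)
        tmax = hi if tmax is None else np.minimum(tmax, hi)
        d_norm_sq = d_norm_sq + dk * dk
    span = np.clip(tmax - tmin, 0.0, None)
    return span * np.sqrt(d_norm_sq)


def _phantom_transmission(
    gantry_deg: float,
    offset_room: np.ndarray,
    u_panel: np.ndarray,
    v_panel: np.ndarray,
    sad_mm: float,
    sid_mm: float,
) -> np.ndarray:
    """Transmission map of the hollow cuboid phantom plus crosshair planes."""
    src = source_position(gantry_deg, sad_mm)
    u0, v0 = panel_basis(gantry_deg)
    beam = -src / sad_mm
    base = src + sid_mm * beam  # panel center, room coords

    h = PHANTOM_HALF_WIDTH_MM
    hw_inner = h - PHANTOM_WALL_MM
    boxes = [
        (np.array([h, h, h]), 1.0, MU_SOLID),
        (np.array([hw_inner, hw_inner, hw_inner]), -(1.0 - PHANTOM_INTERIOR_FILL), MU_SOLID),
        (np.array([CROSSHAIR_HALF_MM, h, h]), 1.0, MU_CROSSHAIR),
        (np.array([h, CROSSHAIR_HALF_MM, h]), 1.0, MU_CROSSHAIR),
        (np.array([h, h, CROSSHAIR_HALF_MM]), 1.0, MU_CROSSHAIR),
    ]
    path = 0.0
    dirs = [
        base[k] - src[k] + u_panel[np.newaxis, :] * u0[k] + v_panel[:, np.newaxis] * v0[k]
        for k in range(3)
    ]
    center = np.asarray(offset_room, dtype=float)
    for half, weight, mu in boxes:
        chord = _ray_box_chords(src, dirs, center, half)
        path = path + weight * mu * chord
    return np.exp(-path)


def render_view(
    truth: SimulationTruth,
    gantry_deg: float,
    collimator_deg: float,
    vendor: str = "varian",
    field_size_mm: float = 100.0,
    sid_mm: float = 1460.0,
    sad_mm: float = 1000.0,
    pixel_spacing_mm: float = 0.4,
    panel_px: int | None = None,
    mlc_x1: bool | None = None,
    include_phantom: bool = True,
) -> PortalImage:
    """Render one portal image for the given machine geometry.

    ``mlc_x1`` replaces the X1 jaw edge with a jagged MLC-defined edge; it
    defaults to True for the Siemens vendor (whose X jaws are MLC-formed).
    ``include_phantom=False`` renders the bare open field.
    """
    gantry_deg = normalize_angle(gantry_deg)
    collimator_deg = normalize_angle(collimator_deg)
    if mlc_x1 is None:
        mlc_x1 = vendor == "siemens"
    mag = sid_mm / sad_mm
    if panel_px is None:
        extent = field_size_mm * mag + 60.0  # 30 mm margin each side
        panel_px = int(np.ceil(extent / pixel_spacing_mm / 2.0)) * 2
    panel_mm = panel_px * pixel_spacing_mm
    if field_size_mm * mag + 10.0 > panel_mm:
        raise RenderError("field larger than the panel")

    shape = (panel_px, panel_px)
    x_iso, y_iso = pixel_grid_iso(shape, (pixel_spacing_mm,) * 2, sad_mm, sid_mm)
    X = x_iso[np.newaxis, :]
    Y = y_iso[:, np.newaxis]

    # collimator runout displaces the whole jaw assembly on a circle
    c = np.deg2rad(collimator_deg)
    wx = truth.collimator_walkout_mm * np.cos(c)
    wy = truth.collimator_walkout_mm * np.sin(c)
    xc = (X - wx) * np.cos(c) + (Y - wy) * np.sin(c)
    yc = -(X - wx) * np.sin(c) + (Y - wy) * np.cos(c)

    half_f = field_size_mm / 2.0
    sig = truth.penumbra_sigma_mm
    off = truth.jaw_offsets_mm
    e_x1 = half_f + off["X1"]
    if mlc_x1:
        jitter = truth.mlc_leaf_jitter()
        leaf = np.clip(
            np.floor((yc + MLC_LEAF_WIDTH_MM * len(jitter) / 2.0) / MLC_LEAF_WIDTH_MM),
            0,
            len(jitter) - 1,
        ).astype(int)
        e_x1 = e_x1 + jitter[leaf]
    t_field = (
        ndtr((xc + e_x1) / sig)
        * ndtr((half_f + off["X2"] - xc) / sig)
        * ndtr((yc + half_f + off["Y1"]) / sig)
        * ndtr((half_f + off["Y2"] - yc) / sig)
    )
    field_term = JAW_LEAK + (1.0 - JAW_LEAK) * t_field

    if include_phantom:
        u_panel = x_iso * mag
        v_panel = y_iso * mag
        t_phantom = _phantom_transmission(
            gantry_deg, np.asarray(truth.phantom_offset_mm), u_panel, v_panel, sad_mm, sid_mm
        )
        # effective source-size blur softens the geometric phantom silhouette
        t_phantom = ndimage.gaussian_filter(
            t_phantom, FOCAL_BLUR_MM / pixel_spacing_mm, mode="nearest"
        )
    else:
        t_phantom = 1.0

    image = PLATEAU * field_term * t_phantom
    if truth.noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [int(truth.seed), int(round(gantry_deg * 100)), int(round(collimator_deg * 100))]
            )
        )
        image = image + rng.normal(0.0, truth.noise_sd * PLATEAU, shape)
    image = np.round(np.clip(image, 0.0, 65535.0))

    return PortalImage(
        pixels=image,
        pixel_spacing_mm=(pixel_spacing_mm, pixel_spacing_mm),
        sid_mm=sid_mm,
        sad_mm=sad_mm,
        gantry_deg=gantry_deg,
        collimator_deg=collimator_deg,
        vendor=vendor,
        field_size_mm=field_size_mm,
        source_id=f"synthetic:G{gantry_deg:05.1f}_C{collimator_deg:05.1f}",
    )


def render_session(
    truth: SimulationTruth,
    plan,
    out_dir: str | Path | None = None,
    **render_kwargs,
) -> list[PortalImage]:
    """Render one portal image per view of an acquisition plan.

    When ``out_dir`` is given the images are also written as DICOM RT Image
    files named ``G<ggg>_C<ccc>.dcm``; Elekta sessions are written with
    empty angle tags to emulate the iView GT export quirk.
    """
    images = []
    for view in plan.views:
        img = render_view(
            truth, view.gantry_deg, view.collimator_deg, vendor=plan.vendor, **render_kwargs
        )
        images.append(img)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for img in images:
            name = f"G{int(round(img.gantry_deg)):03d}_C{int(round(img.collimator_deg)):03d}.dcm"
            write_portal_image(
                img, out_dir / name, empty_angle_tags=(plan.vendor == "elekta")
            )
    return images


def _render_film(
    strip_normals: list[tuple[float, float]],
    strip_centers: list[float],
    slit_width_mm: float,
    size_mm: float,
    pixel_mm: float,
    noise_sd: float,
    seed: int,
    edge_sigma_mm: float = 0.3,
) -> np.ndarray:
    n = int(np.ceil(size_mm / pixel_mm / 2.0)) * 2
    coords = (np.arange(n) - (n - 1) / 2.0) * pixel_mm
    Xf = coords[np.newaxis, :]
    Yf = coords[:, np.newaxis]
    image = np.zeros((n, n))
    for (nx, ny), c0 in zip(strip_normals, strip_centers):
        dist = Xf * nx + Yf * ny - c0
        image += PLATEAU * ndtr((slit_width_mm / 2.0 - np.abs(dist)) / edge_sigma_mm)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 424242]))
        image = image + rng.normal(0.0, noise_sd * PLATEAU, image.shape)
    return np.round(np.clip(image, 0.0, 65535.0))


def render_starshot(
    truth: SimulationTruth,
    gantry_angles: tuple[float, ...] = (0.0, 30.0, 150.0, 240.0, 300.0),
    collimator_slit_width_mm: float = 2.0,
    size_mm: float = 120.0,
    pixel_mm: float = 0.2,
) -> np.ndarray:
    """Render an axial star shot: one strip per gantry angle.

    The film lies in the lateral-vertical plane with its center at the
    laser-marked reference point (the phantom position); image x maps to
    +lateral and image y to +vertical.  Every strip centerline passes
    through the radiation isocenter, displaced from the film center by
    minus the phantom offset.  Requires at least three gantry angles.
    """
    if len(gantry_angles) < 3:
        raise RenderError("an axial star shot needs at least 3 gantry angles")
    o_lat, _, o_vert = truth.phantom_offset_mm
    normals, centers = [], []
    for g in gantry_angles:
        gr = np.deg2rad(normalize_angle(g))
        # strip narrow direction = panel u axis projected into the film plane
        nx, ny = np.cos(gr), -np.sin(gr)
        walk = truth.collimator_walkout_mm  # slit at collimator 0
        centers.append(nx * (-o_lat) + ny * (-o_vert) + walk)
        normals.append((nx, ny))
    return _render_film(
        normals, centers, collimator_slit_width_mm, size_mm, pixel_mm, truth.noise_sd, truth.seed
    )


def render_coronal_starshot(
    truth: SimulationTruth,
    collimator_deg: float = 10.0,
    gantry_angles: tuple[float, float] = (0.0, 180.0),
    collimator_slit_width_mm: float = 2.0,
    size_mm: float = 120.0,
    pixel_mm: float = 0.2,
) -> np.ndarray:
    """Render the coronal two-strip star shot used for the longitudinal axis.

    The film lies flat in the lateral-longitudinal plane; exposures at
    gantry 0 and 180 with the collimator rotated off-axis produce two
    strips crossing at the projection of the isocenter.  Image x maps to
    +lateral, image y to +longitudinal.
    """
    o_lat, o_long, _ = truth.phantom_offset_mm
    c = np.deg2rad(collimator_deg)
    normals, centers = [], []
    for g in gantry_angles:
        flip = -1.0 if abs(normalize_angle(g) - 180.0) < 45.0 else 1.0
        # narrow (X-jaw) coordinate of a film point: xc = u*cos c + v*sin c,
        # with u = flip*(lat), v = long relative to the beam axis
        nx, ny = flip * np.cos(c), np.sin(c)
        centers.append(nx * (-o_lat) + ny * (-o_long) + truth.collimator_walkout_mm * np.cos(c))
        normals.append((nx, ny))
    return _render_film(
        normals, centers, collimator_slit_width_mm, size_mm, pixel_mm, truth.noise_sd, truth.seed
    )
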