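"""Shared projection geometry in the IEC 61217 machine coordinate system.

Room frame (right-handed, fixed):

* ``lateral``      -- couch left/right axis; +lateral is the +X room axis.
* ``longitudinal`` -- couch long axis; +longitudinal points toward the gantry.
* ``vertical``     -- +vertical points up.

The gantry rotates about the longitudinal axis.  At gantry 0 the source is
above the isocenter and the beam points straight down; at gantry 90 the
source sits on the +lateral side.

Panel frame: the EPID is mounted opposite the source, perpendicular to the
beam axis at source-to-imager distance (SID).  Pixel (0, 0) is the top-left
corner; the column axis ``u`` maps to the room direction
``u0(g) = (cos g, 0, -sin g)`` and the row axis ``v`` to ``v0 = (0, 1, 0)``
(toward the gantry) for every gantry angle.  The panel does not rotate with
the collimator; the collimator jaws rotate within the panel frame.

All "isocenter-plane" coordinates are panel millimetres divided by the
SID/SAD magnification, i.e. distances as they would be measured in the
plane through the isocenter perpendicular to the beam.
"""

from __future__ import annotations

import numpy as np

ROOM_AXES = ("lateral", "longitudinal", "vertical")
JAWS = ("X1", "X2", "Y1", "Y2")


def normalize_angle(deg: float) -> float:
    """Map an angle in degrees onto [0, 360)."""
    a = float(deg) % 360.0
    return a + 360.0 if a < 0 else a


def source_position(gantry_deg: float, sad_mm: float) -> np.ndarray:
    """Room coordinates of the radiation source."""
    g = np.deg2rad(gantry_deg)
    return sad_mm * np.array([np.sin(g), 0.0, np.cos(g)])


def panel_basis(gantry_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Room directions (u0, v0) of the panel column and row axes."""
    g = np.deg2rad(gantry_deg)
    u0 = np.array([np.cos(g), 0.0, -np.sin(g)])
    v0 = np.array([0.0, 1.0, 0.0])
    return u0, v0


def collimator_axes(collimator_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Panel-frame travel axes of the X and Y jaw pairs at a collimator angle.

    Returns unit 2-vectors ``(ax, ay)`` in (u, v) panel coordinates.  At
    collimator 0 the X jaws travel along +u and the Y jaws along +v.
    """
    c = np.deg2rad(collimator_deg)
    ax = np.array([np.cos(c), np.sin(c)])
    ay = np.array([-np.sin(c), np.cos(c)])
    return ax, ay


def jaw_outward_panel(jaw: str, collimator_deg: float) -> np.ndarray:
    """Panel-frame unit vector pointing from field center toward ``jaw``.

    Per IEC 1217 the X1/Y1 jaws sit on the negative side of their travel
    axis and X2/Y2 on the positive side, so every jaw edge lies at
    +field/2 along its own outward direction.
    """
    if jaw not in JAWS:
        raise ValueError(f"unknown jaw label {jaw!r}")
    ax, ay = collimator_axes(collimator_deg)
    axis = ax if jaw[0] == "X" else ay
    return -axis if jaw[1] == "1" else axis


def jaw_outward_room(jaw: str, gantry_deg: float, collimator_deg: float) -> np.ndarray:
    """Room-frame direction of :func:`jaw_outward_panel`."""
    u0, v0 = panel_basis(gantry_deg)
    pu, pv = jaw_outward_panel(jaw, collimator_deg)
    return pu * u0 + pv * v0


def project_point(
    point_room: np.ndarray, gantry_deg: float, sad_mm: float, sid_mm: float
) -> tuple[float, float]:
    """Project a room point through the source onto the panel.

    Exact pinhole projection; the result is returned at isocenter-plane
    scale (panel mm divided by SID/SAD), as a (u, v) pair relative to the
    beam axis.
    """
    p = np.asarray(point_room, dtype=float)
    src = source_position(gantry_deg, sad_mm)
    u0, v0 = panel_basis(gantry_deg)
    beam = -src / sad_mm  # unit vector source -> isocenter
    denom = float(np.dot(p - src, beam))
    if denom <= 0:
        raise ValueError("point behind the source")
    t = sid_mm / denom
    hit = src + t * (p - src)
    panel_center = src + sid_mm * beam
    scale = sad_mm / sid_mm
    return (
        float(np.dot(hit - panel_center, u0)) * scale,
        float(np.dot(hit - panel_center, v0)) * scale,
    )


def pixel_grid_iso(
    shape: tuple[int, int],
    pixel_spacing_mm: tuple[float, float],
    sad_mm: float,
    sid_mm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Isocenter-plane (u, v) coordinates of every pixel column and row.

    Returns ``(x_iso, y_iso)``: 1-D arrays over columns and rows.  The grid
    is centered on the beam axis (panel center).
    """
    n_rows, n_cols = shape
    scale = sad_mm / sid_mm
    row_pitch, col_pitch = pixel_spacing_mm
    x_iso = (np.arange(n_cols) - (n_cols - 1) / 2.0) * col_pitch * scale
    y_iso = (np.arange(n_rows) - (n_rows - 1) / 2.0) * row_pitch * scale
    return x_iso, y_iso
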