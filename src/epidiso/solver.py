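"""Acquisition planning, collimator-rotation pairing, and shift arithmetic.

The defining trick of the method: every room-axis position of the
radiation field center is derived from a *single jaw* imaged twice with
the collimator rotated 180 deg between exposures.  A constant jaw
calibration error then adds equally to both distances d1 and d2 and
cancels exactly in the pair shift

    s = (d1 - d2) / 2,

so the result is independent of jaw calibration (jaw position indicators
are only held to +-2 mm).  Pair shifts are averaged per room dimension
over the gantry angles that can see it,

    S_r = sum_i s_{r,i} / n,

which also averages out gantry sag and rotational imperfections.  The
couch shift equals S_r in magnitude with signs mapped per the machine's
couch coordinate convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import ROOM_AXES, jaw_outward_room, normalize_angle
from .measurement import JawMeasurement

CARDINAL_GANTRY = (0.0, 90.0, 180.0, 270.0)


class SolverError(ValueError):
    pass


@dataclass(frozen=True)
class View:
    gantry_deg: float
    collimator_deg: float
    jaws: tuple[str, ...]


@dataclass(frozen=True)
class AcquisitionPlan:
    vendor: str
    mode: str
    views: tuple[View, ...]

    def __len__(self) -> int:
        return len(self.views)


@dataclass(frozen=True)
class PairShift:
    """One Eq.-(1) evaluation: a single jaw seen at collimator c and c+180.

    ``s_mm`` is (d1 - d2)/2 with d1 taken at the collimator angle in
    [0, 180); ``sign`` maps it onto the canonical positive room direction
    of its dimension, so ``s_mm * sign`` is the required couch shift along
    +lateral / +longitudinal / +vertical.
    """

    dimension: str
    gantry_deg: float
    jaw: str
    collimator_ref_deg: float
    d1_mm: float
    d2_mm: float
    s_mm: float
    sign: int

    @property
    def s_room_mm(self) -> float:
        return self.s_mm * self.sign


@dataclass
class IsocenterResult:
    pair_shifts: list[PairShift]
    S_bar_mm: dict[str, float]
    n_per_dimension: dict[str, int]
    couch_shift_mm: dict[str, float]
    measurements: list[JawMeasurement] = field(default_factory=list)
    report_path: str | None = None


# (jaw, gantry, collimator of d1) -> (room dimension, sign of the jaw's
# outward direction along that dimension).  Forced by IEC 1217 geometry;
# validated against geometry.jaw_outward_room and the synthetic renderer.
DIMENSION_TABLE: dict[tuple[str, float, float], tuple[str, int]] = {}
for _g, (_cross, _sign_u) in {
    0.0: ("lateral", +1),
    90.0: ("vertical", -1),
    180.0: ("lateral", -1),
    270.0: ("vertical", +1),
}.items():
    # X jaws travel along the panel u axis at collimator 0, Y jaws at 90
    DIMENSION_TABLE[("X2", _g, 0.0)] = (_cross, _sign_u)
    DIMENSION_TABLE[("X1", _g, 0.0)] = (_cross, -_sign_u)
    DIMENSION_TABLE[("Y2", _g, 90.0)] = (_cross, -_sign_u)
    DIMENSION_TABLE[("Y1", _g, 90.0)] = (_cross, _sign_u)
    DIMENSION_TABLE[("X2", _g, 90.0)] = ("longitudinal", +1)
    DIMENSION_TABLE[("X1", _g, 90.0)] = ("longitudinal", -1)
    DIMENSION_TABLE[("Y2", _g, 0.0)] = ("longitudinal", +1)
    DIMENSION_TABLE[("Y1", _g, 0.0)] = ("longitudinal", -1)


def pair_dimension(jaw: str, gantry_deg: float, collimator_ref_deg: float) -> tuple[str, int]:
    """Room dimension and sign measured by a jaw pair (table lookup)."""
    key = (jaw, normalize_angle(gantry_deg), normalize_angle(collimator_ref_deg))
    try:
        return DIMENSION_TABLE[key]
    except KeyError:
        # fall back to the analytic IEC geometry for non-cardinal angles
        d = jaw_outward_room(jaw, gantry_deg, collimator_ref_deg)
        k = int(np.argmax(np.abs(d)))
        if abs(d[k]) < 0.999:
            raise SolverError(
                f"jaw {jaw} at gantry {gantry_deg}, collimator {collimator_ref_deg} "
                "does not align with a room axis"
            ) from None
        return ROOM_AXES[k], int(np.sign(d[k]))


def plan_acquisition(vendor: str, mode: str = "full") -> AcquisitionPlan:
    """Build the image-acquisition plan for a vendor.

    Single-jaw machines (Siemens, whose X jaws are MLC-formed) need two
    images per dimension: minimal = 6 images, full = 16 (four collimator
    angles at each cardinal gantry angle).  Dual-jaw machines get two
    measurements per image: minimal = 4, full = 8 (collimator 90/270 at
    each cardinal gantry angle).
    """
    if mode not in ("minimal", "full"):
        raise SolverError(f"unknown mode {mode!r}")
    if vendor == "siemens":
        jaws = ("Y2",)
        if mode == "full":
            views = [
                View(g, c, jaws) for g in CARDINAL_GANTRY for c in (0.0, 90.0, 180.0, 270.0)
            ]
        else:
            views = [
                View(0.0, 0.0, jaws),
                View(0.0, 180.0, jaws),
                View(0.0, 90.0, jaws),
                View(0.0, 270.0, jaws),
                View(90.0, 90.0, jaws),
                View(90.0, 270.0, jaws),
            ]
    elif vendor in ("varian", "elekta", "generic"):
        jaws = ("X2", "Y2")
        if mode == "full":
            views = [View(g, c, jaws) for g in CARDINAL_GANTRY for c in (90.0, 270.0)]
        else:
            views = [
                View(0.0, 90.0, jaws),
                View(0.0, 270.0, jaws),
                View(90.0, 90.0, jaws),
                View(90.0, 270.0, jaws),
            ]
    else:
        raise SolverError(f"unknown vendor {vendor!r}")
    return AcquisitionPlan(vendor=vendor, mode=mode, views=tuple(views))


def pair_shift(d1_mm: float, d2_mm: float) -> float:
    """Eq.-(1) pair shift (d1 - d2)/2."""
    if not (np.isfinite(d1_mm) and np.isfinite(d2_mm)):
        raise SolverError("pair distances must be finite")
    return (d1_mm - d2_mm) / 2.0


def pair_measurements(
    measurements: Iterable[JawMeasurement], strict: bool = True
) -> list[PairShift]:
    """Pair measurements across 180 deg collimator rotations.

    Each measurement is matched by (gantry, jaw, collimator +- 180); d1 is
    the distance at the collimator angle in [0, 180).  In strict mode any
    unpaired measurement aborts with the list of missing partner views.
    """
    buckets: dict[tuple[float, str, float], dict[float, JawMeasurement]] = {}
    for m in measurements:
        g = normalize_angle(m.gantry_deg)
        c = normalize_angle(m.collimator_deg)
        key = (g, m.jaw, c % 180.0)
        slot = buckets.setdefault(key, {})
        if c in slot:
            raise SolverError(
                f"duplicate measurement for gantry {g}, collimator {c}, jaw {m.jaw}"
            )
        slot[c] = m
    pairs: list[PairShift] = []
    missing: list[str] = []
    for (g, jaw, c_ref), slot in sorted(buckets.items()):
        if len(slot) != 2:
            (c_have,) = slot
            missing.append(f"gantry {g:g}, collimator {normalize_angle(c_have + 180):g}, jaw {jaw}")
            continue
        m1 = slot[c_ref]
        m2 = slot[normalize_angle(c_ref + 180.0)]
        dim, sign = pair_dimension(jaw, g, c_ref)
        pairs.append(
            PairShift(
                dimension=dim,
                gantry_deg=g,
                jaw=jaw,
                collimator_ref_deg=c_ref,
                d1_mm=m1.d_mm,
                d2_mm=m2.d_mm,
                s_mm=pair_shift(m1.d_mm, m2.d_mm),
                sign=sign,
            )
        )
    if missing and strict:
        raise SolverError("session incomplete; missing views: " + "; ".join(missing))
    return pairs


def aggregate(
    pair_shifts: Sequence[PairShift],
    couch_signs: tuple[int, int, int] = (1, 1, 1),
) -> IsocenterResult:
    """Eq.-(2) averaging over gantry angles plus the couch sign mapping.

    Pair shifts are first averaged within each gantry angle, then across
    the n gantry angles that can see the dimension.  ``couch_signs``
    re-signs (lateral, longitudinal, vertical) for the machine's couch
    coordinate convention; with the identity mapping, positive shifts mean
    toward +lateral (couch left viewed from the gantry), toward the gantry,
    and up.
    """
    S_bar: dict[str, float] = {}
    n_per_dim: dict[str, int] = {}
    for dim in ROOM_AXES:
        per_gantry: dict[float, list[float]] = {}
        for p in pair_shifts:
            if p.dimension == dim:
                per_gantry.setdefault(p.gantry_deg, []).append(p.s_room_mm)
        if not per_gantry:
            raise SolverError(f"no measurement pairs for dimension {dim!r}")
        gantry_means = [float(np.mean(v)) for v in per_gantry.values()]
        S_bar[dim] = float(np.mean(gantry_means))
        n_per_dim[dim] = len(per_gantry)
    couch = {
        dim: sign * S_bar[dim] for dim, sign in zip(ROOM_AXES, couch_signs)
    }
    return IsocenterResult(
        pair_shifts=list(pair_shifts),
        S_bar_mm=S_bar,
        n_per_dimension=n_per_dim,
        couch_shift_mm=couch,
    )


def jaw_error_invariance_check(
    truth_a,
    truth_b,
    vendor: str = "varian",
    mode: str = "full",
    **render_kwargs,
) -> float:
    """Max |S_r(A) - S_r(B)| between two otherwise-identical sessions.

    Renders and analyses both truths end to end; used to demonstrate that
    per-jaw calibration offsets (within the +-2 mm jaw tolerance) do not
    move the result when pairing is done across the 180 deg collimator
    rotation.
    """
    from .pipeline import analyze_images  # local import: pipeline sits above solver
    from .synthetic import render_session

    plan = plan_acquisition(vendor, mode)
    results = []
    for truth in (truth_a, truth_b):
        images = render_session(truth, plan, **render_kwargs)
        results.append(analyze_images(images))
    a, b = results
    return max(abs(a.S_bar_mm[d] - b.S_bar_mm[d]) for d in ROOM_AXES)
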