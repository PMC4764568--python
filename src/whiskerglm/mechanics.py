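"""Whisker kinematics and quasi-static contact mechanics.

A whisker imaged in the horizontal plane is well described, away from the
contact zone, by a quadratic Bezier curve.  From that curve we extract the
two quantities that matter for mechanotransduction at the follicle:

* the *angle* of the whisker at its base relative to the anterior-posterior
  axis (protraction = increasing angle), and
* the *curvature* at the base, whose change relative to the intrinsic
  (unforced) curvature is proportional to the bending moment exerted by an
  object pressing on the whisker shaft.

Given the bending moment and the whisker-object contact geometry, the
quasi-static cantilever framework yields the magnitude of the contact force
and its axial/lateral components at the base.  During free whisking the
relevant moment is instead the inertial one, proportional to angular
acceleration, which we estimate with a Savitzky-Golay smoother.

All angles are degrees at the public interfaces and radians internally;
lengths are mm, curvature mm^-1, time is sampled at 1 kHz unless stated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "BezierCurve",
    "ContactGeometry",
    "NoContactError",
    "DegenerateCurveError",
    "curvature_at_base",
    "curvature_change",
    "angle_at_base",
    "contact_forces",
    "contact_point",
    "angular_acceleration",
    "push_angle",
    "touch_episodes",
]


class DegenerateCurveError(ValueError):
    """Raised when a Bezier curve has a vanishing tangent or coincident points."""


class NoContactError(ValueError):
    """Raised when the whisker curve never approaches the pole."""


@dataclass(frozen=True)
class BezierCurve:
    """Quadratic Bezier curve ``B(s) = (1-s)^2 P0 + 2 s (1-s) P1 + s^2 P2``.

    ``P0`` is the whisker base (follicle end); ``s`` runs from 0 (base) to 1
    (distal end of the tracked segment).  Control points are (x, y) in mm.
    """

    control_points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points, dtype=float)
        if pts.shape != (3, 2):
            raise ValueError(f"expected 3 planar control points, got shape {pts.shape}")
        object.__setattr__(self, "control_points", pts)

    @property
    def base(self) -> np.ndarray:
        return self.control_points[0]

    def point(self, s):
        s = np.asarray(s, dtype=float)[..., None]
        p0, p1, p2 = self.control_points
        return (1 - s) ** 2 * p0 + 2 * s * (1 - s) * p1 + s**2 * p2

    def deriv1(self, s):
        s = np.asarray(s, dtype=float)[..., None]
        p0, p1, p2 = self.control_points
        return 2 * ((1 - s) * (p1 - p0) + s * (p2 - p1))

    def deriv2(self) -> np.ndarray:
        p0, p1, p2 = self.control_points
        return 2 * (p0 - 2 * p1 + p2)

    def curvature(self, s):
        """Signed curvature kappa(s) = (x'y'' - x''y') / (x'^2 + y'^2)^(3/2)."""
        d1 = self.deriv1(s)
        d2 = self.deriv2()
        speed2 = np.sum(d1**2, axis=-1)
        if np.any(speed2 < 1e-24):
            raise DegenerateCurveError("vanishing tangent: curvature undefined")
        cross = d1[..., 0] * d2[1] - d2[0] * d1[..., 1]
        return cross / speed2**1.5


@dataclass
class ContactGeometry:
    """Forces at the whisker base implied by a bending moment and contact geometry.

    ``M`` is the bending moment (proxy units: bending stiffness x mm^-1),
    ``r`` the lever-arm length from base to contact (mm), ``phi`` the angle
    between the lever arm and the contact force (radians), and
    ``theta_base`` / ``theta_contact`` the tangent angle at the base and the
    direction of the force, both relative to the horizontal (radians).
    ``F`` is the force magnitude; ``F_ax`` and ``F_lat`` its projections onto
    the tangent and normal to the whisker at its base.
    """

    M: np.ndarray
    r: np.ndarray
    phi: np.ndarray
    theta_base: np.ndarray
    theta_contact: np.ndarray
    F: np.ndarray
    F_ax: np.ndarray
    F_lat: np.ndarray


def curvature_at_base(curve: BezierCurve) -> float:
    """Signed curvature of the whisker at its base (s = 0), in mm^-1."""
    return float(curve.curvature(0.0))


def angle_at_base(curve: BezierCurve, ap_axis=(1.0, 0.0)) -> float:
    """Angle (degrees) between the base tangent and the anterior-posterior axis.

    The angle is signed, in (-180, 180], measured counter-clockwise from
    ``ap_axis`` to the tangent; under the protraction-positive convention a
    protracting whisker has increasing angle.
    """
    tangent = curve.deriv1(0.0)
    ap = np.asarray(ap_axis, dtype=float)
    if np.hypot(*tangent) < 1e-12:
        raise DegenerateCurveError("vanishing tangent at base: angle undefined")
    if np.hypot(*ap) < 1e-12:
        raise ValueError("ap_axis must be a nonzero vector")
    ang = np.arctan2(ap[0] * tangent[1] - ap[1] * tangent[0], ap @ tangent)
    return float(np.degrees(ang))


def curvature_change(
    kappa_series, trial_bounds, intrinsic_window_ms: int = 100, fs_hz: float = 1000.0
) -> np.ndarray:
    """Per-trial curvature change Delta-kappa = kappa - intrinsic curvature.

    The intrinsic (unforced) curvature of each trial is estimated as the mean
    of ``kappa`` over the first ``intrinsic_window_ms`` of that trial, before
    any object contact occurs.
    """
    kappa = np.asarray(kappa_series, dtype=float)
    window = int(round(intrinsic_window_ms * fs_hz / 1000.0))
    out = np.empty_like(kappa)
    for start, stop in trial_bounds:
        if stop - start < window:
            raise ValueError(
                f"trial [{start}, {stop}) shorter than intrinsic window ({window} bins)"
            )
        out[start:stop] = kappa[start:stop] - kappa[start : start + window].mean()
    return out


def contact_forces(M, r, phi, theta_base, theta_contact) -> ContactGeometry:
    """Contact force at the base from moment and contact geometry.

    F = M / (r sin(phi));  F_ax = F sin(theta_base - theta_contact);
    F_lat = F cos(theta_base - theta_contact).  Angles in radians.  Inputs
    may be scalars or broadcastable arrays.
    """
    M, r, phi, theta_base, theta_contact = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (M, r, phi, theta_base, theta_contact))
    )
    if np.any(r <= 0):
        raise ValueError("lever arm r must be positive")
    s = np.sin(phi)
    if np.any(np.abs(s) < 1e-12):
        raise ValueError("sin(phi) = 0: force undefined (lever arm parallel to force)")
    F = M / (r * s)
    dtheta = theta_base - theta_contact
    geom = ContactGeometry(
        M=M, r=r, phi=phi, theta_base=theta_base, theta_contact=theta_contact,
        F=F, F_ax=F * np.sin(dtheta), F_lat=F * np.cos(dtheta),
    )
    return geom


def contact_point(curve: BezierCurve, pole_center, pole_radius: float, tol: float = 0.2):
    """Whisker-pole contact location and lever-arm geometry.

    Finds the parameter ``s*`` minimising the distance from the curve to the
    pole centre (exactly, via the cubic stationarity condition of the squared
    distance).  Returns a dict with the contact point, ``s``, the lever arm
    length ``r`` (base to contact, mm), ``phi`` (angle between the lever arm
    and the force direction, taken as the normal to the whisker tangent at
    contact; only ``sin(phi)`` is mechanically meaningful so the sign of the
    normal is immaterial), the minimal distance, and an ``at_endpoint`` flag
    raised when the minimiser sits at the distal end of the tracked segment
    (tip slip-off: geometry unreliable there).

    Raises :class:`NoContactError` if the curve never comes within
    ``pole_radius + tol`` of the pole centre.
    """
    c = np.asarray(pole_center, dtype=float)
    p0, p1, p2 = curve.control_points
    a = p0 - 2 * p1 + p2            # B(s) = a s^2 + b1 s + (p0 - c) relative to centre
    b1 = 2 * (p1 - p0)
    c0 = p0 - c
    # d/ds |B(s)-c|^2 is a cubic: 4(a.a)s^3 + 6(a.b1)s^2 + 2(b1.b1 + 2 a.c0)s + 2 b1.c0
    coeffs = [4 * a @ a, 6 * a @ b1, 2 * (b1 @ b1 + 2 * (a @ c0)), 2 * (b1 @ c0)]
    candidates = [0.0, 1.0]
    lead = next((i for i, cf in enumerate(coeffs) if abs(cf) > 1e-14), None)
    if lead is not None and lead < 3:
        roots = np.roots(coeffs[lead:])
        candidates += [float(np.real(z)) for z in roots if abs(np.imag(z)) < 1e-10 and 0 < np.real(z) < 1]
    pts = curve.point(np.array(candidates))
    dists = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
    i = int(np.argmin(dists))
    s_star, dist = candidates[i], float(dists[i])
    if dist > pole_radius + tol:
        raise NoContactError(
            f"closest approach {dist:.3f} mm exceeds pole radius + tolerance "
            f"({pole_radius + tol:.3f} mm)"
        )
    contact = curve.point(s_star)
    lever = contact - curve.base
    r = float(np.hypot(*lever))
    tangent = curve.deriv1(s_star)
    normal = np.array([-tangent[1], tangent[0]])
    nn = np.hypot(*normal)
    if nn < 1e-12 or r < 1e-12:
        raise DegenerateCurveError("degenerate contact geometry")
    cosang = np.clip((lever @ normal) / (r * nn), -1.0, 1.0)
    phi = float(np.arccos(cosang))
    at_endpoint = s_star > 1 - 1e-9
    if at_endpoint:
        warnings.warn(
            "contact point at distal end of tracked segment (possible tip "
            "slip-off); lever-arm geometry unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    return {
        "point": contact,
        "s": s_star,
        "r": r,
        "phi": phi,
        "distance": dist,
        "at_endpoint": at_endpoint,
    }


def angular_acceleration(
    angle_series,
    poly_order: int = 5,
    frame_ms: int = 31,
    fs_hz: float = 1000.0,
    strategy: str = "smooth_diff",
) -> np.ndarray:
    """Angular acceleration (deg/s^2) from an angle trace sampled at ``fs_hz``.

    The trace is smoothed with a Savitzky-Golay filter (polynomial order 5,
    window 31 samples by default).  With ``strategy="smooth_diff"`` the
    second derivative is then taken by repeated central differences; with
    ``strategy="sg_derivative"`` the filter's own second-derivative
    coefficients are used.  Both reproduce polynomials up to ``poly_order``
    exactly.  Values within half a window of either end are edge-affected
    and should be excluded from analyses.
    """
    x = np.asarray(angle_series, dtype=float)
    frame = int(frame_ms)
    if frame % 2 == 0 or frame <= poly_order:
        raise ValueError("frame must be odd and greater than the polynomial order")
    if x.size <= frame:
        raise ValueError("series must be longer than the filter frame")
    dt = 1.0 / fs_hz
    if strategy == "smooth_diff":
        smooth = savgol_filter(x, frame, poly_order)
        return np.gradient(np.gradient(smooth, dt), dt)
    if strategy == "sg_derivative":
        return savgol_filter(x, frame, poly_order, deriv=2, delta=dt)
    raise ValueError(f"unknown strategy {strategy!r}")


def touch_episodes(touch_mask) -> list[tuple[int, int]]:
    """Half-open [start, stop) intervals of contiguous 1s in a binary mask."""
    t = np.asarray(touch_mask).astype(bool).astype(np.int8)
    edges = np.diff(np.concatenate(([0], t, [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def push_angle(angle_series, touch) -> np.ndarray:
    """Push angle: whisker angle minus its value in the frame before touch onset.

    ``touch`` may be a binary mask or a list of [start, stop) episodes.  The
    result is NaN outside touch.  An episode starting at bin 0 has no
    reference frame; it is left NaN and a warning is issued.
    """
    angle = np.asarray(angle_series, dtype=float)
    episodes = touch if isinstance(touch, (list, tuple)) else touch_episodes(touch)
    out = np.full(angle.shape, np.nan)
    for start, stop in episodes:
        if start == 0:
            warnings.warn(
                "touch episode at bin 0 has no pre-onset reference frame; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        out[start:stop] = angle[start:stop] - angle[start - 1]
    return out
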