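"""From a tracked whisker curve to contact forces at the base.

A whisker imaged at 1 kHz is described per frame by a quadratic Bezier
curve.  This script takes one bent-whisker frame, measures curvature and
angle at the base, locates the contact point on a pole, and resolves the
bending moment into the force magnitude and its axial/lateral components.
"""

import numpy as np

from whiskerglm import (
    BezierCurve,
    angle_at_base,
    contact_forces,
    contact_point,
    curvature_at_base,
)

# a protracted, bent whisker (control points in mm; base at the origin)
whisker = BezierCurve([(0.0, 0.0), (6.0, 2.5), (10.0, 7.0)])
pole_center, pole_radius = (8.6, 4.5), 0.795

kappa = curvature_at_base(whisker)
theta = angle_at_base(whisker)
print(f"curvature at base : {kappa:8.4f} mm^-1")
print(f"angle at base     : {theta:8.2f} deg")

contact = contact_point(whisker, pole_center, pole_radius)
print(f"contact at s = {contact['s']:.3f}, lever arm r = {contact['r']:.2f} mm, "
      f"phi = {np.degrees(contact['phi']):.1f} deg")

# moment proxy: bending stiffness x curvature change (intrinsic curvature 0 here)
M = 1.0 * kappa
theta_contact = np.arctan2(*whisker.deriv1(contact["s"])[::-1]) + np.pi / 2
geom = contact_forces(M, contact["r"], contact["phi"],
                      np.radians(theta), theta_contact)
print(f"force magnitude F : {geom.F:8.4f} (stiffness-normalised units)")
print(f"axial component   : {geom.F_ax:8.4f}   lateral component: {geom.F_lat:8.4f}")
print(f"identity check    : F_ax^2 + F_lat^2 - F^2 = "
      f"{geom.F_ax**2 + geom.F_lat**2 - geom.F**2:.2e}")

print("\nF = M / (r sin phi); the axial/lateral split projects the contact force")
print("onto the tangent and normal to the whisker at its base.")
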