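"""Shared 2D frame conventions.

Arrays are indexed ``[row, col]``.  A point ``(x, y)`` has *x* along columns
and *y* along rows, i.e. *y* increases downwards in storage order.  All
azimuths exposed by the package are reported in the mathematical frame
(*y* up, counter-clockwise positive, degrees in ``[0, 360)``), so the storage
row axis enters every angle computation with a sign flip.  Keeping the flip
inside this module is what makes detector azimuths, scan-frame line
directions and crystallographic projections commensurable.
"""

from __future__ import annotations

import numpy as np


def wrap_360(phi):
    """Wrap an angle in degrees into ``[0, 360)``."""
    return np.mod(phi, 360.0)


def wrap_180(phi):
    """Wrap an axial angle (direction without sense) into ``[0, 180)``."""
    return np.mod(phi, 180.0)


def azimuth_deg(vx, vy_down):
    """Azimuth of a storage-frame vector ``(vx, vy_down)``, y-up convention."""
    return wrap_360(np.degrees(np.arctan2(-np.asarray(vy_down), np.asarray(vx))))


def azimuth_math(vx, vy_up):
    """Azimuth of a vector already expressed with y up."""
    return wrap_360(np.degrees(np.arctan2(np.asarray(vy_up), np.asarray(vx))))


def unit_from_azimuth(phi_deg):
    """Unit vector in storage coordinates ``(x, y_down)`` for a y-up azimuth."""
    r = np.radians(phi_deg)
    return np.array([np.cos(r), -np.sin(r)])


def ang_sep_mod180(a, b):
    """Acute separation between two axial angles, in ``[0, 90]`` degrees."""
    d = np.abs(np.mod(np.asarray(a) - np.asarray(b), 180.0))
    return np.minimum(d, 180.0 - d)


def signed_axial_delta(a, b):
    """Signed rotation from axial angle *a* to *b*, wrapped to ``(-90, 90]``."""
    d = np.mod(np.asarray(b) - np.asarray(a), 180.0)
    return np.where(d > 90.0, d - 180.0, d)


def rotation_matrix_storage(theta_deg):
    """Matrix rotating storage-frame ``(x, y_down)`` vectors by *theta* (y-up CCW)."""
    c, s = np.cos(np.radians(theta_deg)), np.sin(np.radians(theta_deg))
    return np.array([[c, s], [-s, c]])


def cross_z_math(u, v):
    """z-component of ``u x v`` evaluated in the y-up frame (storage inputs)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    # (ux, -uy) x (vx, -vy) -> ux*(-vy) - (-uy)*vx
    return -u[..., 0] * v[..., 1] + u[..., 1] * v[..., 0]
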