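"""Vector-geometry kernel for skeleton joint-angle computation.

All scoring formulas reduce to four constructions: the angle between two
vectors, the angle between the two segment vectors of a three-point joint
chain, the normal vector of the plane through three points, and the angle
between two plane normals.  Angles are reported in degrees throughout,
because every posture-scoring threshold in the RULA worksheet is printed in
degrees.

The three-point angle follows the chain convention: it is the angle between
the segment vectors ``b - a`` and ``c - b``, i.e. 0 deg for a straight
(collinear continuation) chain and the *supplement* of the interior angle at
the middle point ``b``.  This is the convention the posture formulas assume
(a fully extended elbow reads 0 deg of flexion, not 180).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "vector_angle",
    "three_point_angle",
    "normal_vector",
    "plane_angle",
    "rotation_matrix",
    "rotate_about",
    "tilt_towards",
]

#: Relative tolerance below which a cross product is considered collinear.
COLLINEAR_RTOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when an angle construction is undefined (zero vector,
    coincident points, or a collinear triple where a plane is required)."""


def _as_vec(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise DegenerateGeometryError("non-finite coordinates in vector")
    return a


def vector_angle(a, b) -> float:
    """Angle in degrees, in [0, 180], between two non-zero 3-vectors.

    Computed as ``atan2(|a x b|, a . b)``, which is equivalent to the
    clamped-arccos cosine formula but numerically accurate near 0 and 180
    degrees (where the cosine saturates); no domain error is possible for
    any finite inputs.
    """
    a = _as_vec(a)
    b = _as_vec(b)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateGeometryError("zero-norm vector in angle computation")
    return float(
        np.degrees(np.arctan2(np.linalg.norm(np.cross(a, b)), np.dot(a, b)))
    )


def three_point_angle(a, b, c) -> float:
    """Chain angle at ``b`` in degrees: between segments ``b-a`` and ``c-b``.

    0 deg means the chain a->b->c continues in a straight line; 180 deg means
    it doubles back.  Raises :class:`DegenerateGeometryError` when ``a == b``
    or ``b == c``.
    """
    a = _as_vec(a)
    b = _as_vec(b)
    c = _as_vec(c)
    return vector_angle(b - a, c - b)


def normal_vector(a, b, c) -> np.ndarray:
    """Plane normal ``(b - a) x (c - a)`` of the plane through three points.

    Orientation follows the operand order (right-hand rule).  Raises
    :class:`DegenerateGeometryError` when the points are collinear, judged
    against ``COLLINEAR_RTOL`` relative to the operand scale.
    """
    a = _as_vec(a)
    b = _as_vec(b)
    c = _as_vec(c)
    u = b - a
    v = c - a
    n = np.cross(u, v)
    scale = np.linalg.norm(u) * np.linalg.norm(v)
    if scale == 0.0 or np.linalg.norm(n) < COLLINEAR_RTOL * scale:
        raise DegenerateGeometryError("collinear points do not define a plane")
    return n


def plane_angle(n1, n2) -> float:
    """Angle in degrees between two planes given by their normals."""
    return vector_angle(n1, n2)


# ---------------------------------------------------------------------------
# rotation helpers (used by the fixture generator and by tests)

def rotation_matrix(axis, degrees: float) -> np.ndarray:
    """Rotation matrix for a rotation of ``degrees`` about ``axis``
    (Rodrigues formula; axis need not be normalised)."""
    axis = _as_vec(axis)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise DegenerateGeometryError("zero rotation axis")
    x, y, z = axis / n
    t = np.radians(degrees)
    c, s = np.cos(t), np.sin(t)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def rotate_about(points: np.ndarray, axis, degrees: float,
                 origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Rotate an (..., 3) array of points about an axis through ``origin``."""
    origin = np.asarray(origin, dtype=float)
    R = rotation_matrix(axis, degrees)
    pts = np.asarray(points, dtype=float)
    return (pts - origin) @ R.T + origin


def tilt_towards(v, towards, degrees: float) -> np.ndarray:
    """Rotate unit-direction ``v`` by exactly ``degrees`` towards ``towards``.

    ``towards`` is first orthogonalised against ``v``; the result is the unit
    vector at the requested angle from ``v`` in the plane spanned by both.
    """
    v = _as_vec(v)
    v = v / np.linalg.norm(v)
    t = _as_vec(towards)
    w = t - v * np.dot(v, t)
    nw = np.linalg.norm(w)
    if nw < COLLINEAR_RTOL:
        raise DegenerateGeometryError("tilt target parallel to source vector")
    w = w / nw
    r = np.radians(degrees)
    return v * np.cos(r) + w * np.sin(r)
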