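"""Parametric leaf-end curves, leaf profiles and planar geometry utilities.

Coordinate conventions
----------------------
All geometry lives in a leaf-local frame: the origin sits at the leaf
mid-height, ``x`` runs along the beam-depth direction *pointing back toward
the source*, and ``y`` runs along the leaf-motion (lateral) direction.  The
leaf end curve spans ``x in [-lh/2, +lh/2]`` for parameter ``t in [0, 1]``;
for ``t`` outside the unit interval the point lies on the straight distal
(``t < 0``, ``x = -lh/2``) or proximal (``t > 1``, ``x = +lh/2``) leaf edge,
both of which descend in ``-y`` (into the leaf body).  Leaf material lies on
the ``-y`` side of the end curve, so the open field is at ``+y``.

In the machine frame the leaf-local origin sits at depth SCD on the beam
axis and depth increases away from the source, so a local point maps to
machine depth ``X = SCD - x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "LeafEndCurve",
    "CircularArc",
    "EllipticalArc",
    "BezierEnd",
    "BSplineEnd",
    "PiecewiseArcEnd",
    "LeafProfile",
    "FeasibilityReport",
    "MachineScene",
    "leaf_end",
    "eval_leaf_curve",
    "build_outline",
    "path_length",
    "check_feasibility",
    "varian_piecewise_end",
    "max_lateral_deviation",
    "beam_half_angle",
]

_TOL = 1e-12


class LeafEndCurve:
    """Base class for parametric leaf-end curves.

    Subclasses implement :meth:`end_point` and :meth:`end_derivative` for
    ``t in [0, 1]``; the straight leaf edges outside the unit interval are
    handled here.
    """

    family = "abstract"

    def __init__(self, lh: float):
        if lh <= 0:
            raise ValueError("leaf height must be positive")
        self.lh = float(lh)

    # -- interface ---------------------------------------------------------
    def end_point(self, t):
        raise NotImplementedError

    def end_derivative(self, t):
        raise NotImplementedError

    def design_vector(self) -> np.ndarray:
        raise NotImplementedError

    def constraint_violations(self) -> list[str]:
        """Table-style bound/linear/concavity constraints that are violated."""
        raise NotImplementedError

    # -- shared ------------------------------------------------------------
    def point(self, t):
        """Curve point, extended onto the straight leaf edges for t outside [0,1]."""
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite curve parameter t")
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        x = np.empty_like(t)
        y = np.empty_like(t)
        inside = (t >= 0.0) & (t <= 1.0)
        if np.any(inside):
            xi, yi = self.end_point(t[inside])
            x[inside], y[inside] = xi, yi
        lo = t < 0.0
        if np.any(lo):
            _, y0 = self.end_point(np.array([0.0]))
            x[lo] = -self.lh / 2
            y[lo] = t[lo] + y0[0]
        hi = t > 1.0
        if np.any(hi):
            _, y1 = self.end_point(np.array([1.0]))
            x[hi] = self.lh / 2
            y[hi] = (1.0 - t[hi]) + y1[0]
        if scalar:
            return float(x[0]), float(y[0])
        return x, y

    def tangent(self, t):
        """Unit tangent; one-sided at the edge joins."""
        t = float(t)
        if not np.isfinite(t):
            raise ValueError("non-finite curve parameter t")
        if t < 0.0:
            return np.array([0.0, 1.0])
        if t > 1.0:
            return np.array([0.0, -1.0])
        dx, dy = self.end_derivative(np.array([t]))
        v = np.array([float(dx[0]), float(dy[0])])
        n = np.hypot(*v)
        if n == 0.0:
            raise ValueError("degenerate tangent")
        return v / n

    def height_samples(self, n: int = 1025):
        """(x, y) samples of the end curve with x sorted ascending.

        All feasible families are single-valued y(x); used for height-field
        queries and outline construction.
        """
        t = np.linspace(0.0, 1.0, n)
        x, y = self.end_point(t)
        order = np.argsort(x)
        return x[order], y[order]

    def y_of_x(self, x):
        xs, ys = self.height_samples(4097)
        if np.any(np.diff(xs) < -1e-12):
            raise ValueError("curve is not single-valued in x")
        return np.interp(x, xs, ys)

    @property
    def x_domain(self) -> tuple[float, float]:
        return (-self.lh / 2, self.lh / 2)

    def __repr__(self):  # pragma: no cover - cosmetic
        p = ", ".join(f"{v:.4g}" for v in self.design_vector())
        return f"{type(self).__name__}(lh={self.lh:g}, p=[{p}])"


class CircularArc(LeafEndCurve):
    """Circular-arc leaf end of radius ``R`` with arc-centre depth offset ``d``.

    The arc centre sits at local ``(d, 0)``; the curve is
    ``x = -R cos(pi/2 - phi + t (varphi + phi)) + d``,
    ``y =  R sin(pi/2 - phi + t (varphi + phi))`` with
    ``varphi = arcsin((lh/2 - d)/R)`` and ``phi = arcsin((lh/2 + d)/R)``,
    so the endpoints land exactly on ``x = -lh/2`` (t=0) and ``x = +lh/2``
    (t=1).
    """

    family = "circular"

    def __init__(self, lh: float, R: float, d: float = 0.0):
        super().__init__(lh)
        self.R = float(R)
        self.d = float(d)
        self._varphi = np.arcsin(np.clip((lh / 2 - self.d) / self.R, -1, 1))
        self._phi = np.arcsin(np.clip((lh / 2 + self.d) / self.R, -1, 1))

    def _angle(self, t):
        return np.pi / 2 - self._phi + t * (self._varphi + self._phi)

    def end_point(self, t):
        a = self._angle(np.asarray(t, dtype=float))
        return -self.R * np.cos(a) + self.d, self.R * np.sin(a)

    def end_derivative(self, t):
        a = self._angle(np.asarray(t, dtype=float))
        k = self._varphi + self._phi
        return self.R * np.sin(a) * k, self.R * np.cos(a) * k

    def design_vector(self):
        return np.array([self.R, self.d])

    def constraint_violations(self):
        lh = self.lh
        out = []
        if self.R < lh / 2 - _TOL:
            out.append(f"R >= lh/2 violated (R={self.R:g})")
        if abs(self.d) > lh / 2 + _TOL:
            out.append(f"|d| <= lh/2 violated (d={self.d:g})")
        if -self.R + self.d + lh / 2 > _TOL:
            out.append("-R + d + lh/2 <= 0 violated")
        if -self.R - self.d + lh / 2 > _TOL:
            out.append("-R - d + lh/2 <= 0 violated")
        return out


class EllipticalArc(LeafEndCurve):
    """Half-elliptical leaf end: semimajor axis fixed at ``a = lh/2`` along
    the depth axis, semiminor axis ``b`` along leaf motion.

    ``x = a cos((1-t) pi)``, ``y = b sin((1-t) pi)``.  The special case
    ``b = lh/2`` is the circular arc ``R = lh/2, d = 0``.
    """

    family = "elliptical"

    def __init__(self, lh: float, b: float):
        super().__init__(lh)
        self.a = lh / 2
        self.b = float(b)

    def end_point(self, t):
        t = np.asarray(t, dtype=float)
        return self.a * np.cos((1 - t) * np.pi), self.b * np.sin((1 - t) * np.pi)

    def end_derivative(self, t):
        t = np.asarray(t, dtype=float)
        return (self.a * np.pi * np.sin((1 - t) * np.pi),
                -self.b * np.pi * np.cos((1 - t) * np.pi))

    def design_vector(self):
        return np.array([self.b])

    def constraint_violations(self):
        out = []
        if not (0.0 <= self.b <= self.lh / 2 + _TOL):
            out.append(f"0 <= b <= lh/2 violated (b={self.b:g})")
        if self.b < self.a:  # eccentricity must satisfy 0 < sqrt(1-b^2/a^2) < 1
            if self.b <= _TOL:
                out.append("eccentricity bound 0 < (1-b^2/a^2)^(1/2) < 1 violated (b=0)")
        return out


class BezierEnd(LeafEndCurve):
    """Cubic (by default) Bezier leaf end with fixed endpoints
    ``P0 = (-lh/2, 0)`` and ``Pn = (+lh/2, 0)``.

    ``control`` holds the interior control points ``P1..P_{n-1}``.
    """

    family = "bezier"

    def __init__(self, lh: float, control: Sequence[tuple[float, float]]):
        super().__init__(lh)
        interior = np.asarray(control, dtype=float).reshape(-1, 2)
        self.P = np.vstack([[-lh / 2, 0.0], interior, [lh / 2, 0.0]])
        self.n = len(self.P) - 1

    def end_point(self, t):
        t = np.asarray(t, dtype=float)[..., None]
        n = self.n
        from math import comb

        B = sum(comb(n, i) * t**i * (1 - t) ** (n - i) * self.P[i]
                for i in range(n + 1))
        return B[..., 0], B[..., 1]

    def end_derivative(self, t):
        t = np.asarray(t, dtype=float)[..., None]
        n = self.n
        from math import comb

        D = sum(comb(n - 1, i) * t**i * (1 - t) ** (n - 1 - i)
                * n * (self.P[i + 1] - self.P[i]) for i in range(n))
        return D[..., 0], D[..., 1]

    def design_vector(self):
        return self.P[1:-1].ravel()

    def constraint_violations(self):
        lh, n, P = self.lh, self.n, self.P
        out = []
        for i in range(1, n):
            xlo = (-0.5 + (i - 1) / (n - 1)) * lh
            xhi = (-0.5 + i / (n - 1)) * lh
            if not (xlo - _TOL <= P[i, 0] <= xhi + _TOL):
                out.append(f"x ordering bound violated at control point {i}")
            if not (-_TOL <= P[i, 1] <= lh / 2 + _TOL):
                out.append(f"0 <= y_{i} <= lh/2 violated")
        for i in range(n - 1):
            if P[i, 1] + P[i + 2, 1] - 2 * P[i + 1, 1] > _TOL:
                out.append(f"concavity y_{i} + y_{i+2} - 2 y_{i+1} <= 0 violated")
        return out


class BSplineEnd(LeafEndCurve):
    """Clamped cubic B-spline leaf end with ``n + 1`` control points.

    Control-point abscissae are fixed at ``x_i = (-1/2 + i/n) lh``; the last
    ordinate is pinned to ``y_n = 0``.  ``y`` holds the free ordinates
    ``y_0..y_{n-1}``.  The knot vector is open-uniform on [0, 1].
    """

    family = "bspline"
    degree = 3

    def __init__(self, lh: float, y: Sequence[float], n: int = 8):
        super().__init__(lh)
        y = np.asarray(y, dtype=float)
        if len(y) != n:
            raise ValueError(f"expected {n} free control ordinates, got {len(y)}")
        self.n = n
        k = self.degree
        self.P = np.column_stack([(-0.5 + np.arange(n + 1) / n) * lh,
                                  np.append(y, 0.0)])
        n_interior = (n + k + 2) - 2 * (k + 1)
        interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        self.knots = np.concatenate([np.zeros(k + 1), interior, np.ones(k + 1)])
        self._spl = BSpline(self.knots, self.P, k, extrapolate=False)
        self._dspl = self._spl.derivative()

    def end_point(self, t):
        t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
        v = self._spl(t)
        return v[..., 0], v[..., 1]

    def end_derivative(self, t):
        t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0 - 1e-12)
        v = self._dspl(t)
        return v[..., 0], v[..., 1]

    def design_vector(self):
        return self.P[:-1, 1].copy()

    def constraint_violations(self):
        lh, n, y = self.lh, self.n, self.P[:, 1]
        out = []
        for j in range(n):
            if not (-_TOL <= y[j] <= lh / 2 + _TOL):
                out.append(f"0 <= y_{j} <= lh/2 violated")
        for i in range(n - 1):
            if y[i] + y[i + 2] - 2 * y[i + 1] > _TOL:
                out.append(f"concavity y_{i} + y_{i+2} - 2 y_{i+1} <= 0 violated")
        return out


class PiecewiseArcEnd(LeafEndCurve):
    """Central circular arc blended C1 into two straight segments.

    The segments make angle ``alpha_l`` (degrees) with the collimator
    rotation axis (the depth axis), i.e. their slope is ``-/+ tan(alpha_l)``
    on the right/left of the apex.  The arc has radius ``R`` and apex at
    local ``(0, 0)`` (this family carries its own lateral datum; comparisons
    against other curves should align datums first).
    """

    family = "piecewise"

    def __init__(self, lh: float, R: float, alpha_deg: float):
        super().__init__(lh)
        if R < 0 or not (0 < alpha_deg <= 90):
            raise ValueError("require R >= 0 and 0 < alpha_l <= 90 degrees")
        self.R = float(R)
        self.alpha = np.radians(alpha_deg)
        self.xb = self.R * np.sin(self.alpha)
        if self.xb >= lh / 2 - 1e-12 and alpha_deg < 90:
            raise ValueError(
                "no tangent blend inside the leaf height: R*sin(alpha_l) "
                f"= {self.xb:.4g} >= lh/2 = {lh / 2:.4g}")
        if alpha_deg == 90 and abs(self.R - lh / 2) > 1e-12:
            raise ValueError("alpha_l = 90 deg requires R = lh/2 (vertical edges)")

    def _y_of_x(self, x):
        x = np.asarray(x, dtype=float)
        R, xb, al = self.R, self.xb, self.alpha
        yb = np.sqrt(R * R - xb * xb) - R
        arc = np.sqrt(np.maximum(R * R - x * x, 0.0)) - R
        seg = yb - np.tan(al) * (np.abs(x) - xb)
        return np.where(np.abs(x) <= xb, arc, seg)

    def end_point(self, t):
        t = np.asarray(t, dtype=float)
        x = -self.lh / 2 + t * self.lh
        return x, self._y_of_x(x)

    def end_derivative(self, t):
        t = np.asarray(t, dtype=float)
        x = -self.lh / 2 + t * self.lh
        slope = np.where(np.abs(x) <= self.xb,
                         -x / np.sqrt(np.maximum(self.R**2 - x * x, 1e-300)),
                         -np.sign(x) * np.tan(self.alpha))
        return np.full_like(x, self.lh), slope * self.lh

    def design_vector(self):
        return np.array([self.R, np.degrees(self.alpha)])

    def constraint_violations(self):
        return []


_FAMILIES = {
    "circular": CircularArc,
    "elliptical": EllipticalArc,
    "bezier": BezierEnd,
    "bspline": BSplineEnd,
    "piecewise": PiecewiseArcEnd,
}


def leaf_end(family: str, lh: float, **params) -> LeafEndCurve:
    """Factory: build a leaf-end curve of the given family."""
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown leaf-end family {family!r}") from None
    return cls(lh, **params)


def eval_leaf_curve(spec: LeafEndCurve, t: float):
    """Evaluate a leaf curve at parameter ``t`` (edges included).

    Returns ``((x, y), unit_tangent)``.
    """
    return spec.point(float(t)), spec.tangent(float(t))


@dataclass
class FeasibilityReport:
    feasible: bool
    violated: list[str] = field(default_factory=list)


def check_feasibility(spec: LeafEndCurve) -> FeasibilityReport:
    """Evaluate every bound, linear and concavity constraint for the family."""
    violated = spec.constraint_violations()
    return FeasibilityReport(feasible=not violated, violated=violated)


@dataclass
class LeafProfile:
    """Closed leaf outline: end curve plus straight edges and a back closure."""

    curve: LeafEndCurve
    back_depth: float
    polygon: Polygon

    @property
    def floor(self) -> float:
        return float(self.polygon.bounds[1])


def build_outline(spec: LeafEndCurve, back_depth: float | None = None,
                  n: int = 2048) -> LeafProfile:
    """Close the leaf end curve into a simple polygon.

    The two straight leaf edges are extended down to
    ``min(end ordinates) - back_depth`` and joined by a straight back
    segment.  ``back_depth`` defaults to ``3 * lh``, deep enough that no
    modelled ray exits through the closure.
    """
    if back_depth is None:
        back_depth = 3.0 * spec.lh
    # traverse the end curve in parameter order so that a self-intersecting
    # curve yields an invalid ring instead of being silently reordered
    t = np.linspace(0.0, 1.0, n)
    xs, ys = spec.end_point(t)
    floor = min(ys[0], ys[-1]) - back_depth
    ring = ([(xs[0], floor)] + list(zip(xs, ys)) + [(xs[-1], floor)])
    poly = Polygon(ring)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("leaf outline is self-intersecting; "
                         "control polygon is infeasible")
    return LeafProfile(curve=spec, back_depth=float(back_depth), polygon=poly)


def path_length(segment: tuple[tuple[float, float], tuple[float, float]],
                profile: LeafProfile) -> float:
    """Total in-material length of a straight segment through the leaf.

    Both endpoints must lie outside the material (rays start at the source
    and end on the scoring plane).  Disjoint sub-chords are summed; a
    non-intersecting or grazing segment yields 0.
    """
    (x0, y0), (x1, y1) = segment
    for p in ((x0, y0), (x1, y1)):
        if profile.polygon.contains(Point(p)):
            raise ValueError(f"segment endpoint {p} lies inside leaf material")
    inter = LineString([(x0, y0), (x1, y1)]).intersection(profile.polygon)
    return float(inter.length)


def varian_piecewise_end(R: float, alpha_l: float, lh: float) -> PiecewiseArcEnd:
    """Piecewise leaf end: central arc of radius ``R`` tangentially blended
    to straight segments at ``alpha_l`` degrees to the rotation axis."""
    return PiecewiseArcEnd(lh, R=R, alpha_deg=alpha_l)


def max_lateral_deviation(curve_a: LeafEndCurve, curve_b: LeafEndCurve,
                          align: str | None = None) -> float:
    """Maximum |y_A(x) - y_B(x)| over the common depth domain.

    Both curves must be single-valued in x.  ``align="minimax"`` first
    removes the arbitrary relative lateral datum by the shift that minimises
    the maximum deviation (each leaf's absolute lateral zero is a machine
    calibration, not a shape property).
    """
    lo = max(curve_a.x_domain[0], curve_b.x_domain[0])
    hi = min(curve_a.x_domain[1], curve_b.x_domain[1])
    lh = max(curve_a.lh, curve_b.lh)
    n = int(np.ceil((hi - lo) / (1e-3 * lh))) + 1
    x = np.linspace(lo, hi, max(n, 11))
    delta = curve_a.y_of_x(x) - curve_b.y_of_x(x)
    if align == "minimax":
        delta = delta - (delta.max() + delta.min()) / 2
    elif align is not None:
        raise ValueError(f"unknown alignment {align!r}")
    return float(np.max(np.abs(delta)))


def beam_half_angle(FS: float, SAD: float) -> float:
    """Beam half-angle (degrees) to the corner of the maximum square field:
    ``arctan(sqrt(2) (FS/2) / SAD)``."""
    if FS <= 0 or SAD <= 0:
        raise ValueError("FS and SAD must be positive")
    return float(np.degrees(np.arctan(np.sqrt(2.0) * FS / 2.0 / SAD)))


@dataclass(frozen=True)
class MachineScene:
    """Machine geometry and leaf material.

    Distances in cm, density in g/cm^3, mass attenuation in cm^2/g.  ``sdd``
    and ``dh`` are stored for completeness but enter no computation.  The
    scoring plane sits at depth SAD; the leaf occupies depths
    ``[SCD - lh/2, SCD + lh/2]``.
    """

    sad: float
    scd: float
    fs: float
    lh: float
    rho: float
    mu_rho: float
    sdd: float | None = None
    dh: float | None = None

    def __post_init__(self):
        if not (0 < self.scd < self.sad):
            raise ValueError("require 0 < SCD < SAD")
        if self.lh <= 0 or self.rho <= 0 or self.mu_rho <= 0:
            raise ValueError("lh, rho and mu_a/rho must be positive")

    @property
    def mu_a(self) -> float:
        """Linear attenuation coefficient (1/cm)."""
        return self.rho * self.mu_rho

    @property
    def alpha_b(self) -> float:
        """Beam half-angle (degrees) for the maximum square field."""
        return beam_half_angle(self.fs, self.sad)

    def depth_of(self, x_local) -> np.ndarray:
        """Machine depth of a leaf-local x (local x points toward the source)."""
        return self.scd - np.asarray(x_local, dtype=float)
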