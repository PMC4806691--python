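"""Tangent Secant Theory (TST) penumbra evaluator.

The lateral fluence penumbra of a leaf end at a given position is obtained
from two geometric constructions instead of a full profile calculation:

* the 80% intensity point ``P80`` is the scoring-plane intercept of the
  grazing (tangent) line drawn from the source point ``E`` that leaves 80%
  of the source intensity visible;
* the 20% intensity point ``P20`` is the intercept of the secant line drawn
  from the source point ``C`` (one equivalent source size ``e`` above ``E``,
  toward the open field) whose in-material chord through the leaf tip equals
  the effective path length ``l``.

``W = y(P80) - y(P20)``.  The pair ``(e, l)`` condenses the focal-spot blur
and the transmission tail into two calibrated scalars.

Machine frame: depth ``X`` from the source plane (``X = 0``) to the scoring
plane (``X = SAD``); lateral ``y`` along leaf motion with the open field at
``+y``.  A leaf-local point ``(x, y)`` maps to ``(SCD - x, tau + y)`` where
``tau`` is the lateral leaf shift for the requested position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import MultiPoint, Point

from .leafgeom import LeafEndCurve, MachineScene
from .source_model import SourceDistribution, source_quantile

__all__ = ["TSTParams", "PenumbraBreakdown", "PlacedLeaf", "place_leaf",
           "tangent_point", "secant_chord", "tst_penumbra", "position_sweep"]

#: source-quantile level whose tangent ray leaves 80% of the source visible
#: (the leaf covers the -y side, so the visible mass is the upper tail)
P80_SOURCE_QUANTILE = 0.2

_NT = 257  # bracketing grid on the curve parameter


@dataclass(frozen=True)
class TSTParams:
    """The model's two calibrated scalars (cm)."""

    e: float  # equivalent source size
    l: float  # effective path length

    def __post_init__(self):
        if self.e <= 0 or self.l <= 0:
            raise ValueError("e and l must be positive")


@dataclass
class PenumbraBreakdown:
    """Full geometric decomposition of one TST penumbra evaluation."""

    W: float
    p80: float
    p20: float
    D: tuple[float, float]          # tangency point (machine X, y)
    A: tuple[float, float]          # secant chord entry point
    B: tuple[float, float]          # secant chord exit point
    E: tuple[float, float]          # 80%-visibility source point
    C_src: tuple[float, float]      # secant source point
    T: float                        # leaf position on the scoring plane
    tau: float                      # physical lateral leaf shift
    tangent_at_endpoint: bool = False


class PlacedLeaf:
    """A leaf-end curve placed in the machine at lateral shift ``tau``.

    Precomputes a parameter-grid sample of the curve in machine depth for
    bracketing; exact evaluations refine every root.
    """

    def __init__(self, spec: LeafEndCurve, scene: MachineScene, tau: float,
                 _cache=None):
        self.spec = spec
        self.scene = scene
        self.tau = float(tau)
        if _cache is None:
            _cache = _curve_cache(spec, scene)
        self.tg, self.X, self.yloc, self.tip = _cache
        self._cache = _cache

    # -- exact machine-frame evaluations ------------------------------------
    def pt(self, t):
        x, y = self.spec.end_point(t)
        return self.scene.scd - x, self.tau + y

    def _slope(self, t, yq: float, Xq: float = 0.0) -> float:
        X, y = self.pt(t)
        return (y - yq) / (X - Xq)

    def _cross(self, t, yq: float, Xq: float = 0.0):
        """cross(P - Q, P') for an upstream point Q = (Xq, yq)."""
        x, y = self.spec.end_point(t)
        dx, dy = self.spec.end_derivative(t)
        return (self.scene.scd - x - Xq) * dy + dx * (self.tau + y - yq)

    def support_slope(self, yq: float, Xq: float = 0.0):
        """Grazing-line slope from an upstream point (Xq, yq); Xq defaults to
        the source plane.

        Returns ``(slope, t, at_endpoint)``; the whole curve lies on or
        below the returned line.
        """
        vals = self._cross(self.tg, yq, Xq)
        sgn = np.sign(vals)
        idx = np.flatnonzero(sgn[:-1] * sgn[1:] < 0)
        cands = [0.0, 1.0]
        for j in idx:
            cands.append(brentq(self._cross, self.tg[j], self.tg[j + 1],
                                args=(yq, Xq), xtol=1e-14))
        slopes = [self._slope(t, yq, Xq) for t in cands]
        k = int(np.argmax(slopes))
        return slopes[k], cands[k], k < 2

    # -- secant chord --------------------------------------------------------
    def _ray_gap(self, t, yq: float, m: float):
        """Signed lateral gap ray-minus-curve along the curve parameter."""
        x, y = self.spec.end_point(t)
        return yq + m * (self.scene.scd - x) - (self.tau + y)

    def chord(self, yq: float, m: float):
        """In-material chord of the ray ``y = yq + m X`` through the closed
        leaf profile (end curve plus straight edges).

        Returns ``(length, entry, exit)`` with entry/exit in machine
        coordinates; ``(0.0, None, None)`` if the ray misses the leaf.
        """
        gaps = self._ray_gap(self.tg, yq, m)
        sgn = np.sign(gaps)
        idx = np.flatnonzero(sgn[:-1] * sgn[1:] < 0)
        Xcr = []
        for j in idx:
            t = brentq(self._ray_gap, self.tg[j], self.tg[j + 1],
                       args=(yq, m), xtol=3e-15)
            x, _ = self.spec.end_point(t)
            Xcr.append(self.scene.scd - x)
        # a ray below a curve endpoint enters/exits through the vertical edge
        for te, g in ((0.0, gaps[0]), (1.0, gaps[-1])):
            if g < 0.0:
                x, _ = self.spec.end_point(te)
                Xcr.append(self.scene.scd - x)
        if len(Xcr) < 2:
            return 0.0, None, None
        Xcr.sort()
        if len(Xcr) % 2:
            Xcr = Xcr[:-1]
        total = sum(b - a for a, b in zip(Xcr[::2], Xcr[1::2]))
        scale = float(np.sqrt(1.0 + m * m))
        entry = (Xcr[0], yq + m * Xcr[0])
        exit_ = (Xcr[-1], yq + m * Xcr[-1])
        return total * scale, entry, exit_


def _curve_cache(spec: LeafEndCurve, scene: MachineScene):
    tg = np.linspace(0.0, 1.0, _NT)
    x, y = spec.end_point(tg)
    X = scene.scd - x
    i = int(np.argmax(y))
    # refine the tip (max-y point) with a local parabolic pass
    if 0 < i < _NT - 1:
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda t: -spec.end_point(np.array([t]))[1][0],
                              bounds=(tg[i - 1], tg[i + 1]), method="bounded",
                              options={"xatol": 1e-12})
        xt, yt = spec.end_point(np.array([res.x]))
        tip = (scene.scd - float(xt[0]), float(yt[0]))
    else:
        tip = (float(X[i]), float(y[i]))
    return tg, X, y, tip


def place_leaf(spec: LeafEndCurve, scene: MachineScene, T: float,
               _cache=None) -> PlacedLeaf:
    """Place a leaf so that its tip, projected through the source centroid,
    lands at scoring-plane position ``T``."""
    if _cache is None:
        _cache = _curve_cache(spec, scene)
    Xtip, ytip = _cache[3]
    tau = T * Xtip / scene.sad - ytip
    return PlacedLeaf(spec, scene, tau, _cache=_cache)


def tangent_point(E: tuple[float, float], leaf: PlacedLeaf):
    """Tangency point ``D`` of the grazing line from ``E`` bounding the open
    field.

    ``E`` is a machine-frame point upstream of the leaf (typically on the
    source plane).  Returns ``(D, t, at_endpoint)``.  Raises if ``E`` lies
    inside the convex hull of the curve.
    """
    XE, yE = E
    hull = MultiPoint(list(zip(leaf.X, leaf.tau + leaf.yloc))).convex_hull
    if hull.intersects(Point(XE, yE)):
        raise ValueError("source point lies on or inside the leaf-end hull")
    if XE >= float(np.min(leaf.X)):
        raise ValueError("tangent source point must lie upstream of the leaf")
    slope, t, at_end = leaf.support_slope(yE, XE)
    D = leaf.pt(t)
    return (float(D[0]), float(D[1])), float(t), bool(at_end)


def secant_chord(C_src: tuple[float, float], leaf: PlacedLeaf, l: float):
    """Secant ray from ``C_src`` with in-material chord of length ``l``.

    Returns ``(A, B, slope)`` where ``A``/``B`` are the chord entry/exit
    points (machine frame).  ``l = 0`` returns the grazing tangency point
    twice.  Raises if no chord of the requested length exists.
    """
    XC, yC = C_src
    if XC != 0.0:
        raise ValueError("secant source point must lie on the source plane")
    if l < 0:
        raise ValueError("path length must be nonnegative")
    m_gr, t_gr, _ = leaf.support_slope(yC)
    if l == 0.0:
        D = leaf.pt(t_gr)
        return (float(D[0]), float(D[1])), (float(D[0]), float(D[1])), m_gr
    dm = 1e-5
    while leaf.chord(yC, m_gr - dm)[0] < l:
        dm *= 2.0
        if dm > 4.0:
            cmax = leaf.chord(yC, m_gr - 4.0)[0]
            raise ValueError(
                f"no secant chord of length {l:g} cm (max found {cmax:g} cm)")
    m = brentq(lambda mm: leaf.chord(yC, mm)[0] - l, m_gr - dm, m_gr,
               xtol=1e-15)
    length, A, B = leaf.chord(yC, m)
    return A, B, float(m)


def tst_penumbra(spec: LeafEndCurve, T: float, params: TSTParams,
                 scene: MachineScene, src: SourceDistribution,
                 _cache=None) -> PenumbraBreakdown:
    """TST penumbra width at leaf position ``T`` (scoring-plane cm)."""
    leaf = place_leaf(spec, scene, T, _cache=_cache)
    yE = source_quantile(src, P80_SOURCE_QUANTILE)
    s80, tD, at_end = leaf.support_slope(yE)
    D = leaf.pt(tD)
    p80 = yE + scene.sad * s80
    # the secant source point sits one equivalent source size above the
    # 80%-visibility point, on the open-field side
    yC = yE + params.e
    A, B, m = secant_chord((0.0, yC), leaf, params.l)
    p20 = yC + scene.sad * m
    return PenumbraBreakdown(
        W=float(p80 - p20), p80=float(p80), p20=float(p20),
        D=(float(D[0]), float(D[1])), A=A, B=B,
        E=(0.0, float(yE)), C_src=(0.0, float(yC)),
        T=float(T), tau=leaf.tau, tangent_at_endpoint=bool(at_end))


def position_sweep(spec: LeafEndCurve, positions, params: TSTParams,
                   scene: MachineScene, src: SourceDistribution) -> np.ndarray:
    """Penumbra widths over a list of leaf positions (one shared curve cache)."""
    cache = _curve_cache(spec, scene)
    return np.array([tst_penumbra(spec, T, params, scene, src, _cache=cache).W
                     for T in positions])
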