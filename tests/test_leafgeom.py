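import numpy as np
import pytest
from shapely.geometry import LineString

from mlcpen import (CircularArc, EllipticalArc, MachineScene, beam_half_angle,
                    build_outline, check_feasibility, eval_leaf_curve,
                    leaf_end, max_lateral_deviation, path_length,
                    varian_piecewise_end)

LH = 8.0


def _families():
    return [
        leaf_end("circular", LH, R=16.213, d=-0.732),
        leaf_end("circular", LH, R=4.0, d=0.0),
        leaf_end("elliptical", LH, b=0.728),
        leaf_end("bezier", LH, control=[(-1.594, 1.077), (0.814, 0.748)]),
        leaf_end("bspline", LH, y=[0.4, 0.6, 0.7, 0.72, 0.7, 0.57, 0.42, 0.24]),
    ]


@pytest.mark.parametrize("spec", _families(), ids=lambda s: s.family)
def test_endpoint_closure(spec):
    """Every family lands exactly on x = -lh/2 at t=0 and x = +lh/2 at t=1."""
    (x0, _), _ = eval_leaf_curve(spec, 0.0)
    (x1, _), _ = eval_leaf_curve(spec, 1.0)
    assert abs(x0 + LH / 2) < 1e-10
    assert abs(x1 - LH / 2) < 1e-10


def test_circular_minimal_radius_endpoints():
    """The semicircular arc R = lh/2, d = 0 starts at (-lh/2, 0)."""
    spec = CircularArc(LH, R=4.0, d=0.0)
    (x, y), _ = eval_leaf_curve(spec, 0.0)
    assert abs(x + 4.0) < 1e-12 and abs(y) < 1e-12
    # apex at t = 0.5
    _, ya = spec.end_point(np.array([0.5]))
    assert abs(ya[0] - 4.0) < 1e-12


def test_edges_outside_unit_interval():
    spec = CircularArc(LH, R=10.0, d=0.5)
    (x, y), tan = eval_leaf_curve(spec, -0.7)
    _, y0 = spec.end_point(np.array([0.0]))
    assert x == -LH / 2
    assert np.isclose(y, -0.7 + y0[0])
    assert np.allclose(tan, [0.0, 1.0])
    (x, y), tan = eval_leaf_curve(spec, 1.3)
    _, y1 = spec.end_point(np.array([1.0]))
    assert x == LH / 2
    assert np.isclose(y, (1 - 1.3) + y1[0])
    assert np.allclose(tan, [0.0, -1.0])


def test_nonfinite_t_rejected():
    spec = CircularArc(LH, R=10.0, d=0.0)
    with pytest.raises(ValueError):
        spec.point(np.nan)


def test_elliptical_b_half_lh_is_circular():
    """b = lh/2 reproduces the circular arc R = lh/2, d = 0 pointwise."""
    ell = EllipticalArc(LH, b=LH / 2)
    circ = CircularArc(LH, R=LH / 2, d=0.0)
    t = np.linspace(0, 1, 501)
    xe, ye = ell.end_point(t)
    xc, yc = circ.end_point(t)
    assert np.max(np.hypot(xe - xc, ye - yc)) < 1e-9


def _de_casteljau(P, t):
    P = [np.asarray(p, dtype=float) for p in P]
    while len(P) > 1:
        P = [(1 - t) * a + t * b for a, b in zip(P[:-1], P[1:])]
    return P[0]


def test_bezier_matches_de_casteljau():
    """Bernstein-basis evaluation agrees with de Casteljau subdivision."""
    spec = leaf_end("bezier", LH, control=[(-1.594, 1.077), (0.814, 0.748)])
    ctrl = [(-4, 0), (-1.594, 1.077), (0.814, 0.748), (4, 0)]
    for t in (0.25, 0.5, 0.9):
        x, y = spec.end_point(np.array([t]))
        ref = _de_casteljau(ctrl, t)
        assert np.hypot(x[0] - ref[0], y[0] - ref[1]) < 1e-12


def test_bspline_clamped_endpoints():
    y = [0.4, 0.6, 0.7, 0.72, 0.7, 0.57, 0.42, 0.24]
    spec = leaf_end("bspline", LH, y=y)
    x0, y0 = spec.end_point(np.array([0.0]))
    assert abs(x0[0] + LH / 2) < 1e-12 and abs(y0[0] - 0.4) < 1e-12
    x1, y1 = spec.end_point(np.array([1.0]))
    assert abs(x1[0] - LH / 2) < 1e-12 and abs(y1[0]) < 1e-12


@pytest.mark.parametrize("spec", [
    leaf_end("bezier", LH, control=[(-1.594, 1.077), (0.814, 0.748)]),
    leaf_end("bspline", LH, y=[0.4, 0.6, 0.7, 0.72, 0.7, 0.57, 0.42, 0.24]),
], ids=["bezier", "bspline"])
def test_concave_control_polygon_gives_concave_curve(spec):
    """Concavity constraints on control ordinates imply y''(x) <= 0."""
    assert check_feasibility(spec).feasible
    xs, ys = spec.height_samples(2001)
    d2 = np.diff(ys, 2) / np.diff(xs)[:-1] ** 2
    assert np.all(d2 <= 1e-9)


def test_feasibility_circular_boundary():
    rep = check_feasibility(CircularArc(LH, R=4.0, d=0.0))
    assert rep.feasible
    rep = check_feasibility(CircularArc(LH, R=3.9, d=0.0))
    assert not rep.feasible
    assert any("lh/2" in v for v in rep.violated)


def test_feasibility_bezier_concavity_violation():
    spec = leaf_end("bezier", LH, control=[(-2.0, 0.5), (2.0, 0.0)])
    rep = check_feasibility(spec)
    assert not rep.feasible
    assert any("concavity" in v for v in rep.violated)


def test_outline_area_circular():
    """Half-disc plus rectangle, against the shoelace area of the outline."""
    spec = CircularArc(LH, R=4.0, d=0.0)
    prof = build_outline(spec, back_depth=10.0)
    expected = np.pi * 4.0**2 / 2 + LH * 10.0
    assert abs(prof.polygon.area - expected) / expected < 1e-3


def test_outline_rejects_self_intersection():
    # crossed control polygon strong enough to fold the cubic into a loop
    spec = leaf_end("bezier", LH, control=[(8.0, 4.0), (-8.0, 4.0)])
    with pytest.raises(ValueError):
        build_outline(spec)


def test_outline_feasible_bezier_is_simple(bez_opt):
    prof = build_outline(bez_opt)
    assert prof.polygon.is_valid and prof.polygon.is_simple


def test_path_length_horizontal_chords():
    """Horizontal line through the semicircular cap: chord = 2 sqrt(R^2-h^2)."""
    spec = CircularArc(LH, R=4.0, d=0.0)
    prof = build_outline(spec)
    for h in (0.5, 2.0, 3.5):
        got = path_length(((-6.0, h), (6.0, h)), prof)
        assert abs(got - 2 * np.sqrt(16.0 - h * h)) < 1e-4


def test_path_length_miss_graze_and_reversal():
    spec = CircularArc(LH, R=4.0, d=0.0)
    prof = build_outline(spec)
    assert path_length(((-6.0, 5.0), (6.0, 5.0)), prof) == 0.0
    assert path_length(((-6.0, 4.0), (6.0, 4.0)), prof) < 1e-6  # tangent at apex
    a = path_length(((-6.0, 1.0), (6.0, -1.0)), prof)
    b = path_length(((6.0, -1.0), (-6.0, 1.0)), prof)
    assert abs(a - b) < 1e-12


def test_path_length_additive_under_split():
    spec = CircularArc(LH, R=4.0, d=0.0)
    prof = build_outline(spec)
    # split point beyond the leaf in x, outside material
    whole = path_length(((-10.0, 1.0), (10.0, 1.0)), prof)
    left = path_length(((-10.0, 1.0), (5.0, 1.0)), prof)
    right = path_length(((5.0, 1.0), (10.0, 1.0)), prof)
    assert abs(whole - (left + right)) < 1e-9


def test_path_length_endpoint_inside_rejected():
    spec = CircularArc(LH, R=4.0, d=0.0)
    prof = build_outline(spec)
    with pytest.raises(ValueError):
        path_length(((0.0, 0.0), (6.0, 1.0)), prof)


def test_varian_blend_points_and_c1():
    """Blend points at x = +-R sin(alpha); slope continuous across them."""
    R, al, lh = 8.0, 11.3, 5.65
    spec = varian_piecewise_end(R, al, lh)
    xb = R * np.sin(np.radians(al))
    assert abs(spec.xb - xb) < 1e-12
    eps = 1e-7
    for xs in (-xb, xb):
        t0 = (xs - eps + lh / 2) / lh
        t1 = (xs + eps + lh / 2) / lh
        _, s0 = spec.end_derivative(np.array([t0]))
        _, s1 = spec.end_derivative(np.array([t1]))
        assert abs(s0[0] - s1[0]) / lh < 1e-4


def test_varian_blend_beyond_leaf_rejected():
    # R >= lh / (2 sin(alpha)) puts the blend point outside the leaf height
    with pytest.raises(ValueError):
        varian_piecewise_end(16.0, 11.3, 5.65)


def test_varian_vertical_edge_limit():
    """alpha = 90 degrees degenerates to the semicircle with vertical ends."""
    spec = varian_piecewise_end(4.0, 90.0, LH)
    _, y = spec.end_point(np.array([0.0, 0.5, 1.0]))
    assert abs(y[1] - 0.0) < 1e-12  # apex datum
    assert abs(y[0] + 4.0) < 1e-9 and abs(y[2] + 4.0) < 1e-9


def test_max_lateral_deviation_identity_and_shift():
    a = CircularArc(LH, R=10.0, d=0.0)
    assert max_lateral_deviation(a, a) == 0.0

    class Shifted(CircularArc):
        def end_point(self, t):
            x, y = super().end_point(t)
            return x, y + 0.25

    b = Shifted(LH, R=10.0, d=0.0)
    assert abs(max_lateral_deviation(a, b) - 0.25) < 1e-9
    # the shift is removed under minimax alignment
    assert max_lateral_deviation(a, b, align="minimax") < 1e-9


def test_beam_half_angle():
    assert abs(beam_half_angle(40.0, 100.0) - 15.8) < 0.05
    assert beam_half_angle(1e-9, 100.0) < 1e-6
    assert np.isclose(beam_half_angle(20.0, 100.0),
                      np.degrees(np.arctan(np.sqrt(2) * 10 / 100)))
    with pytest.raises(ValueError):
        beam_half_angle(0.0, 100.0)


def test_machine_scene_validation():
    with pytest.raises(ValueError):
        MachineScene(sad=100, scd=120, fs=40, lh=8, rho=19.3, mu_rho=0.05)
    s = MachineScene(sad=100, scd=46, fs=40, lh=8, rho=19.3, mu_rho=0.05)
    assert np.isclose(s.mu_a, 0.965)
    assert np.isclose(s.depth_of(2.0), 44.0)
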