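"""Closed-curve spanning, crossing counts and the lasso taxonomy.

The independent oracle here is a deliberately simple scalar
Moller-Trumbore implementation (no vectorization, no dedup shortcuts)
that counts signed segment-triangle intersections by exhaustive
enumeration.
"""

import numpy as np
import pytest

from plasso.structure import DisulphideBridge, Structure
from plasso.synth import default_spec, make_bundle
from plasso.topology import (
    ClosedCurve,
    TopologyError,
    chaikin_closed,
    classify_lasso,
    close_loop,
    count_crossings,
    net_crossing,
    scan_candidates,
    span_surface,
)


# ---------------------------------------------------------------------------
# brute-force oracle


def _oracle_hits(p0, p1, tri):
    """Scalar segment-triangle test; returns (hit, t, sign, point)."""
    a, b, c = (np.asarray(v, float) for v in tri)
    d = np.asarray(p1, float) - p0
    e1, e2 = b - a, c - a
    n = np.cross(e1, e2)
    denom = d @ n
    if abs(denom) < 1e-12:
        return None
    t = -((p0 - a) @ n) / denom
    if not (0.0 <= t <= 1.0):
        return None
    pt = p0 + t * d
    # barycentric
    w = pt - a
    d00, d01, d11 = e1 @ e1, e1 @ e2, e2 @ e2
    d20, d21 = w @ e1, w @ e2
    det = d00 * d11 - d01 * d01
    u = (d11 * d20 - d01 * d21) / det
    v = (d00 * d21 - d01 * d20) / det
    if u < -1e-9 or v < -1e-9 or u + v > 1 + 1e-9:
        return None
    return t, int(np.sign(denom)), pt


def oracle_net(tris, chain):
    """Exhaustive all-pairs net crossing with same-point de-duplication."""
    total = 0
    for k in range(len(chain) - 1):
        seen = []
        for tri in tris:
            hit = _oracle_hits(chain[k], chain[k + 1], tri)
            if hit is None:
                continue
            _, sg, pt = hit
            if any(np.linalg.norm(pt - q) < 1e-6 for q in seen):
                continue
            seen.append(pt)
            total += sg
    return total


# ---------------------------------------------------------------------------
# surface construction


def test_planar_square_fan_has_square_area():
    sq = ClosedCurve(np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float))
    surf = span_surface(sq)
    assert len(surf.triangles) == 4
    assert surf.area() == pytest.approx(1.0)


def test_triangle_spans_itself():
    tri = ClosedCurve(np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0]], float))
    surf = span_surface(tri)
    assert surf.area() == pytest.approx(2.0)


def test_collinear_curve_is_degenerate():
    line = ClosedCurve(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float))
    with pytest.raises(TopologyError):
        span_surface(line)


def test_fan_area_bounds_projection(rng=np.random.default_rng(4)):
    """The fan area is at least the area enclosed by the curve projected
    on its best-fit plane (the fan can only add relief)."""
    for _ in range(25):
        m = rng.integers(5, 12)
        th = np.sort(rng.uniform(0, 2 * np.pi, m))
        r = rng.uniform(1, 3, m)
        pts = np.column_stack(
            [r * np.cos(th), r * np.sin(th), 0.3 * rng.standard_normal(m)]
        )
        surf = span_surface(ClosedCurve(pts))
        flat = pts.copy()
        flat[:, 2] = 0
        proj = 0.5 * abs(
            np.sum(flat[:, 0] * np.roll(flat[:, 1], -1)
                   - np.roll(flat[:, 0], -1) * flat[:, 1])
        )
        assert surf.area() >= proj - 1e-9


# ---------------------------------------------------------------------------
# crossings


def test_unit_square_vertical_segment_crosses_once_positively():
    sq = ClosedCurve(np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float))
    surf = span_surface(sq)
    chain = np.array([[0.5, 0.5, -1.0], [0.5, 0.5, 1.0]])
    cr = count_crossings(surf, chain)
    assert len(cr) == 1
    assert cr[0].sign == 1


def test_far_away_segment_does_not_cross():
    sq = ClosedCurve(np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float))
    surf = span_surface(sq)
    chain = np.array([[5.0, 5.0, -1.0], [5.0, 5.0, 1.0]])
    assert count_crossings(surf, chain) == []


def test_net_crossings_match_bruteforce_on_random_instances():
    """200 random curve/chain instances: vectorized counting equals the
    scalar all-pairs oracle."""
    rng = np.random.default_rng(20)
    for trial in range(200):
        m = rng.integers(4, 10)
        th = np.sort(rng.uniform(0, 2 * np.pi, m))
        r = rng.uniform(1.5, 3.0, m)
        pts = np.column_stack(
            [r * np.cos(th), r * np.sin(th), 0.5 * rng.standard_normal(m)]
        )
        surf = span_surface(ClosedCurve(pts))
        chain = rng.uniform(-4, 4, (rng.integers(2, 8), 3))
        got = net_crossing(count_crossings(surf, chain))
        want = oracle_net(surf.triangles, chain)
        assert got == want, f"instance {trial}"


def test_smoothing_preserves_closure_and_shrinks_length():
    rng = np.random.default_rng(8)
    for _ in range(50):
        m = rng.integers(5, 20)
        pts = rng.uniform(-5, 5, (m, 3))
        c0 = ClosedCurve(pts)
        c1 = ClosedCurve(chaikin_closed(pts, 1))
        c2 = ClosedCurve(chaikin_closed(pts, 3))
        assert c1.length() <= c0.length() + 1e-9
        assert c2.length() <= c1.length() + 1e-9


# ---------------------------------------------------------------------------
# classification


def test_classification_invariant_under_rigid_motion(pierced_C):
    rng = np.random.default_rng(12)
    i, j = pierced_C.meta["cys_pair"]
    b = DisulphideBridge(i, j)
    ref = classify_lasso(pierced_C, b)
    for _ in range(3):
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        s2 = pierced_C.transformed(q, rng.uniform(-40, 40, 3))
        cls = classify_lasso(s2, b)
        assert cls.label == ref.label
        assert (cls.net_N, cls.net_C) == (ref.net_N, ref.net_C)


def test_net_crossing_stable_across_smoothing_levels(pierced_C, pierced_N):
    for s in (pierced_C, pierced_N):
        i, j = s.meta["cys_pair"]
        b = DisulphideBridge(i, j)
        nets = {
            r: (lambda c: (c.net_N, c.net_C))(
                classify_lasso(s, b, smooth_rounds=r, check_rounds=())
            )
            for r in (0, 1, 2, 3)
        }
        assert len(set(nets.values())) == 1


def test_tiny_loop_closes_to_triangle():
    coords = np.array(
        [[0, 0, 0], [3.8, 0, 0], [5.0, 3.4, 0.2], [3.0, 6.3, 0.1],
         [6.5, 7.0, 1.0]], float)
    s = Structure(np.arange(1, 6), "ACACA", coords)
    curve = close_loop(s, DisulphideBridge(1, 3))
    assert curve.n_vertices == 3


def test_chain_break_inside_loop_is_fatal():
    coords = np.array(
        [[0, 0, 0], [3.8, 0, 0], [30.0, 0, 0], [33.8, 0, 0], [37.6, 0, 0]],
        float)
    s = Structure(np.arange(1, 6), "ACACA", coords)
    with pytest.raises(TopologyError, match="chain break"):
        close_loop(s, DisulphideBridge(1, 3))


def test_scan_filter_keeps_midsize_pierced_loops_only():
    """Pierced candidates with loop sizes {30, 50, 95, 210}: the 40-200
    window retains exactly {50, 95}. Built from stand-in classifications
    by driving scan through structures is costly, so the filter logic is
    exercised through real bundles plus bound checks."""
    sizes = [30, 50, 95, 210]
    kept = [x for x in sizes if 40 < x < 200]
    assert kept == [50, 95]

    # end-to-end: default pierced fixtures (loops ~30 and ~39) are both
    # rejected by the 40-200 discovery window but kept by a scaled one
    s1 = make_bundle(default_spec("pierced_C"))
    s2 = make_bundle(default_spec("pierced_N"))
    acc, report = scan_candidates([s1, s2], loop_min=40, loop_max=200)
    assert acc == []
    assert all(e["status"] == "rejected" for e in report)
    acc2, report2 = scan_candidates([s1, s2], loop_min=20, loop_max=100)
    assert len(acc2) == 2
    assert {e["status"] for e in report2} == {"accepted"}


def test_scan_of_empty_set_is_empty():
    acc, report = scan_candidates([])
    assert acc == [] and report == []


def test_nonpierced_kinds_are_rejected_with_reason():
    s = make_bundle(default_spec("cinch"))
    acc, report = scan_candidates([s], loop_min=2, loop_max=200)
    assert acc == []
    assert "not pierced" in report[0]["reason"]
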