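"""Synthetic four-helix bundles with configurable lasso topology.

The generator builds idealized C-alpha bundles (helix rise 1.5 A/residue,
radius 2.3 A, 100 deg/residue, antiparallel axes ~10 A apart) whose
disulphide-closed covalent loop realizes one of eight topologies::

    none        no cysteines
    zero_knot   bridge between the two terminal residues
    cinch       internal bridge, small empty loop
    empty_loop  internal bridge, large empty loop (hGH-style control)
    lasso_N     N-terminal bridge, empty loop
    lasso_C     C-terminal bridge, empty loop
    pierced_N   N-terminal loop threaded by the C-terminal tail (plug-like)
    pierced_C   C-terminal loop threaded by a mid-chain element
                (leptin-like, slipknot-friendly)

Pierced variants deform the ideal square arrangement just enough to route
the covalent loop as an open ring and to pass the designated thread through
it exactly once (net crossing +-1, verified at generation time). Every
bundle is self-validated: virtual-bond lengths in [2.8, 4.5] A, no two
nonconsecutive residues closer than 3.8 A, and the lasso classification
must reproduce the requested kind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .structure import DisulphideBridge, Structure
from .topology import classify_lasso

HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TURN = math.radians(100.0)
CA_SPACING = 3.3           # loop resample spacing before the coil wiggle
                           # (the wiggle arc brings bonds back to ~3.7 A)
MIN_NONADJ = 3.8           # hard-sphere floor for nonconsecutive residues
SS_CA_TARGET = 6.3         # preferred C-alpha separation of the cys pair
SG_BOND = 2.05

KINDS = (
    "none", "zero_knot", "cinch", "empty_loop",
    "lasso_N", "lasso_C", "pierced_N", "pierced_C",
)


class InfeasibleBundleError(ValueError):
    """Requested bundle geometry cannot satisfy the generator invariants."""


@dataclass
class BundleSpec:
    helix_length: int = 12
    loop_length: int = 6
    lasso_kind: str = "none"
    cys_pair: tuple | None = None   # explicit internal indices, optional
    seed: int = 0

    def __post_init__(self):
        if self.lasso_kind not in KINDS:
            raise InfeasibleBundleError(f"unknown lasso_kind {self.lasso_kind!r}")
        if self.helix_length < 6:
            raise InfeasibleBundleError("helix_length must be >= 6")
        if self.loop_length < 2:
            raise InfeasibleBundleError("loop_length must be >= 2")


# ---------------------------------------------------------------------------
# geometric primitives


def _helix(cx, cy, z0, n, direction=1, phase=0.0):
    k = np.arange(n)
    ang = phase + k * HELIX_TURN
    return np.column_stack(
        [
            cx + HELIX_RADIUS * np.cos(ang),
            cy + HELIX_RADIUS * np.sin(ang),
            z0 + direction * HELIX_RISE * k,
        ]
    )


def _spline_length(pts, dense=600):
    t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    if t[-1] < 1e-9:
        raise InfeasibleBundleError("degenerate loop control path")
    cs = CubicSpline(t / t[-1], pts, axis=0)
    u = np.linspace(0, 1, dense)
    xyz = cs(u)
    seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    return cs, np.concatenate([[0.0], np.cumsum(seg)]), xyz


def _coil_wiggle(pts, p_prev, p_next, amplitude=1.1, period=3.4, phase0=0.0):
    """Superimpose a small helical perturbation on a resampled path.

    Straight C-alpha stretches put virtual bond angles near 180 deg, where
    the dihedral geometry degenerates; real backbone traces always carry
    local curvature. The wiggle displaces interior points perpendicular to
    the local tangent on a ~3-residue period, using parallel-transported
    normal frames so the perturbation never cancels along curved paths.
    """
    if len(pts) < 2:
        return pts
    ext = np.vstack([p_prev, pts, p_next])
    tang = ext[2:] - ext[:-2]
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    m = len(pts)
    n1 = np.empty((m, 3))
    seedv = np.array([0.477, -0.638, 0.604])  # generic direction
    v = seedv - (seedv @ tang[0]) * tang[0]
    n1[0] = v / np.linalg.norm(v)
    for k in range(1, m):
        v = n1[k - 1] - (n1[k - 1] @ tang[k]) * tang[k]
        nv = np.linalg.norm(v)
        if nv < 1e-6:
            v = seedv - (seedv @ tang[k]) * tang[k]
            nv = np.linalg.norm(v)
        n1[k] = v / nv
    n2 = np.cross(tang, n1)
    k = np.arange(m)
    ph = phase0 + 2.0 * np.pi * k / period
    # taper at the junctions so the anchor bonds stay within tolerance
    taper = np.minimum(1.0, np.minimum((k + 1) / 2.0, (m - k) / 2.0))
    amp = (amplitude * taper)[:, None]
    return pts + amp * (np.cos(ph)[:, None] * n1 + np.sin(ph)[:, None] * n2)


def _loop(p_from, p_to, waypoints, n_min, wiggle=1.1):
    """Interior residues of a connecting loop.

    A Catmull-Rom-style cubic through the waypoints is resampled at uniform
    arclength and overlaid with a helical wiggle (see ``_coil_wiggle``).
    The residue count is ``max(n_min, fit)`` so the spacing stays near
    ``CA_SPACING``; when more residues are requested than the path can
    hold, the waypoints are inflated away from the straight chord until the
    path is long enough.
    """
    p_from = np.asarray(p_from, float)
    p_to = np.asarray(p_to, float)
    wps = [np.asarray(w, float) for w in waypoints]
    chord_dir = p_to - p_from
    chord_len = np.linalg.norm(chord_dir)
    chord_dir = chord_dir / max(chord_len, 1e-9)

    def build(scale):
        ctrl = [p_from]
        for w in wps:
            rel = w - p_from
            along = rel @ chord_dir
            perp = rel - along * chord_dir
            ctrl.append(p_from + along * chord_dir + scale * perp)
        ctrl.append(p_to)
        return np.array(ctrl)

    cs, s, _ = _spline_length(build(1.0))
    L = s[-1]
    n = max(n_min, int(math.ceil(L / CA_SPACING)) - 1)
    target = CA_SPACING * (n + 1)
    scale = 1.0
    if L < target * 0.97:
        f = lambda sc: _spline_length(build(sc))[1][-1] - target
        try:
            scale = brentq(f, 1.0, 12.0, xtol=1e-3)
        except ValueError as exc:
            raise InfeasibleBundleError(
                f"cannot stretch loop to hold {n} residues"
            ) from exc
    cs, s, xyz = _spline_length(build(scale), dense=1200)
    L = s[-1]
    want = L * np.arange(1, n + 1) / (n + 1)
    u = np.interp(want, s, np.linspace(0, 1, len(s)))
    return _best_wiggle(cs(u), p_from, p_to, wiggle)


def _facing_pair(coords, window_a, window_b):
    """Closest residue pair between two index windows."""
    ia = np.array(window_a)
    ib = np.array(window_b)
    d = np.linalg.norm(coords[ia][:, None] - coords[ib][None], axis=2)
    k = np.unravel_index(np.argmin(d), d.shape)
    return int(ia[k[0]]), int(ib[k[1]]), float(d[k])


def _pinch(coords, i, j, target=SS_CA_TARGET, max_move=1.5):
    """Nudge residues i and j toward each other to a bondable separation.

    The displacement is distributed over a 5-residue window around each
    cysteine so virtual-bond lengths stay within tolerance.
    """
    v = coords[j] - coords[i]
    d = np.linalg.norm(v)
    if d <= target:
        return
    move = min((d - target) / 2.0, max_move)
    u = v / d
    w = {-2: 0.25, -1: 0.6, 0: 1.0, 1: 0.6, 2: 0.25}
    n = len(coords)
    for off, frac in w.items():
        if 0 <= i + off < n and abs((i + off) - j) > 2:
            coords[i + off] += frac * move * u
        if 0 <= j + off < n and abs((j + off) - i) > 2:
            coords[j + off] -= frac * move * u


# ---------------------------------------------------------------------------
# layouts

# Canonical frame constants for the square up-up-down-down bundle. z values
# expressed as fractions of the helix height scale with helix_length.
_D = 10.2


def _square_layout(h, loop_n, kind):
    """Segment plan for the unpierced kinds (and pierced_C's backbone)."""
    ztop = HELIX_RISE * (h - 1)
    d = _D
    segs = []  # (name, kind, points) resolved sequentially

    plan = {
        "A": dict(axis=(0.0, 0.0), dir=+1, z0=0.0, phase=math.radians(225)),
        "B": dict(axis=(d, 0.0), dir=+1, z0=0.0, phase=math.radians(-45)),
        "C": dict(axis=(d, d), dir=-1, z0=ztop, phase=math.radians(45)),
        "D": dict(axis=(0.0, d), dir=-1, z0=ztop, phase=math.radians(135)),
    }
    loops = {
        "AB": [(-2.2, -5.8, 0.92 * ztop), (d / 2 - 3, -7.6, 0.58 * ztop),
               (d / 2 + 3, -7.6, 0.20 * ztop)],
        "BC": [(d + 5.2, d / 2, ztop + 3.2)],
        "CD": [(d / 2 + 3, d + 7.5, 0.22 * ztop), (d / 2 - 3.5, d + 7.5, 0.70 * ztop)],
    }
    return plan, loops, ztop, d


def _build_square(h, loop_n, kind):
    plan, loops, ztop, d = _square_layout(h, loop_n, kind)
    helices = {}
    for name, p in plan.items():
        helices[name] = _helix(*p["axis"], p["z0"], h, p["dir"], p["phase"])

    base_n = 4  # connecting loops auto-size

    def loop_between(a, b, wps, n_min):
        return _loop(helices[a][-1], helices[b][0], wps, n_min)

    ab = loop_between("A", "B", loops["AB"], base_n)
    bc = loop_between("B", "C", loops["BC"], base_n)
    cd = loop_between("C", "D", loops["CD"], base_n)

    parts = [
        ("A", "helix", helices["A"]),
        ("AB", "loop", ab),
        ("B", "helix", helices["B"]),
        ("BC", "loop", bc),
        ("C", "helix", helices["C"]),
        ("CD", "loop", cd),
        ("D", "helix", helices["D"]),
    ]
    return parts, ztop, d


def _assemble(parts):
    coords = np.vstack([p[2] for p in parts])
    segments = {}
    k = 0
    for name, skind, pts in parts:
        segments[name] = (k, k + len(pts) - 1)
        k += len(pts)
    return coords, segments


def _tail(p_anchor, waypoints, n, wiggle=1.1):
    """Open tail continuing from an anchor point through waypoints."""
    ctrl = np.array([p_anchor] + [np.asarray(w, float) for w in waypoints])
    cs, s, _ = _spline_length(ctrl, dense=800)
    L = s[-1]
    m = max(n, int(math.ceil(L / CA_SPACING)))
    want = L * np.arange(1, m + 1) / m
    u = np.interp(want, s, np.linspace(0, 1, len(s)))
    pts = cs(u)
    end_dir = pts[-1] - (pts[-2] if len(pts) > 1 else p_anchor)
    return _best_wiggle(pts, p_anchor, pts[-1] + end_dir, wiggle)


# ---------------------------------------------------------------------------
# bundle construction per kind


def _kind_geometry(spec: BundleSpec):
    h, ln, kind = spec.helix_length, spec.loop_length, spec.lasso_kind
    ztop = HELIX_RISE * (h - 1)
    zs = ztop / 16.5       # z scale relative to the reference 12-residue helix
    d = _D

    if kind in ("none", "zero_knot", "cinch", "empty_loop", "lasso_N", "lasso_C"):
        parts, ztop, d = _build_square(h, ln, kind)
        coords, segments = _assemble(parts)
        if kind == "zero_knot":
            # extend the C-terminus around the outside of helix A so the two
            # terminal residues can bridge
            start = coords[0]
            away = np.array([-0.707, -0.707, 0.0])
            target = start + 6.0 * away
            tail = _tail(
                coords[-1],
                [(-6.5, 6.0, 1.0 * zs), (-6.8, 0.5, 0.5 * zs), target],
                4,
            )
            coords = np.vstack([coords, tail])
        return coords, segments, d, ztop

    if kind == "pierced_C":
        # C-terminal lasso: ring = helix C + foot arc + helix D (up-up-down-
        # up variant) closed by adjacent cysteines at the C/D tops. Both
        # helix pairs are spread to 13.2 A, leaving an open core with a wide
        # top entrance between A and B; the AB crossover climbs over the A/B
        # gap, dives down the core, crosses the ring mid-face packed against
        # the C and D columns, returns over the top chord and descends the
        # outside of B. Unthreading must break the core/lane contacts.
        dw = 1.5   # half-widening of both helix pairs
        hel = {
            "A": _helix(-dw, 0.0, 0.0, h, +1, math.radians(20 - 100.0 * (h - 1))),
            "B": _helix(d + dw, 0.0, 0.0, h, +1, math.radians(-20)),
            "C": _helix(d + dw, d, ztop, h, -1, math.radians(180)),
            "D": _helix(-dw, d, 0.0, h, +1, math.radians(-100.0 * (h - 1))),
        }
        thread = _loop(
            hel["A"][-1], hel["B"][0],
            [
                (2.8, 0.2, ztop + 5.6),       # over the wide A/B gap
                (5.0, 2.4, ztop + 3.0),
                (5.1, 4.5, 0.74 * ztop),      # down the open core
                (5.4, 7.0, 0.54 * ztop),
                (5.4, 10.2, 0.49 * ztop),     # cross the C-D mid-face
                (5.4, 13.4, 0.45 * ztop),
                (5.1, 13.8, ztop + 4.5),      # up outside the face
                (6.6, 9.5, ztop + 6.6),       # back over the top chord
                (9.8, 0.5, ztop + 6.0),
                (9.4, -7.4, 0.62 * ztop),
                (14.5, -5.5, 4.0),            # down the outside of B
                (15.2, -3.0, 0.8),
            ],
            4,
            wiggle=0.8,
        )
        bc = _loop(
            hel["B"][-1], hel["C"][0],
            [(d + 8.2, 5.0, ztop + 4.2), (d + 2.2, 13.6, ztop + 3.4)],
            4,
        )
        arc = _loop(
            hel["C"][-1], hel["D"][0],
            [
                (d / 2 + 4.6, d + 1.2, -5.6),
                (d / 2 + 2.4, d + 1.6, -9.0),
                (d / 2 - 2.4, d + 1.6, -9.0),
                (d / 2 - 4.6, d + 1.2, -5.6),
            ],
            ln,
            wiggle=0.6,
        )
        parts = [
            ("A", "helix", hel["A"]),
            ("AB", "loop", thread),
            ("B", "helix", hel["B"]),
            ("BC", "loop", bc),
            ("C", "helix", hel["C"]),
            ("CD", "loop", arc),
            ("D", "helix", hel["D"]),
        ]
        coords, segments = _assemble(parts)
        return coords, segments, d, ztop

    if kind == "pierced_N":
        # N-terminal lasso: ring = helix A + over-the-top arc + helix B
        # (up-down-up-down variant) closed at the A/B feet. The A/B pair is
        # spread to 13.2 A; the C-terminal tail climbs from helix D into the
        # bundle core and plugs outward through the ring mid-face, ending
        # packed against both ring helices.
        dN = 10.4
        dab = 1.5
        hel = {
            "A": _helix(-dab, 0.0, 2.0, h, +1, math.radians(-10)),
            "B": _helix(dN + dab, 0.0, ztop, h, -1, math.radians(180 - 100.0 * (h - 1))),
            "C": _helix(dN, dN, 0.0, h, +1, math.radians(45)),
            "D": _helix(0.0, dN, ztop, h, -1, math.radians(135)),
        }
        arc = _loop(
            hel["A"][-1], hel["B"][0],
            [(dN / 2 - 2.6, -1.5, ztop + 10.5), (dN / 2 + 2.6, -1.5, ztop + 10.5)],
            ln,
            wiggle=0.8,
        )
        bc = _loop(
            hel["B"][-1], hel["C"][0],
            [(18.0, 2.8, -3.4), (dN + 6.8, dN / 2 + 1.0, -3.0)],
            4,
        )
        cdl = _loop(hel["C"][-1], hel["D"][0], [(dN / 2, dN + 5.5, ztop + 2.6)], 4)
        tail = _tail(
            hel["D"][-1],
            [
                (-3.6, 8.6, -4.6),
                (5.1, 5.1, -4.2),             # under the bundle
                (5.1, 5.1, 4.0),              # up the open core
                (5.2, 2.6, 9.0),
                (5.2, -4.6, 9.4),             # plugged out through the face
            ],
            8,
            wiggle=0.8,
        )
        parts = [
            ("A", "helix", hel["A"]),
            ("AB", "loop", arc),
            ("B", "helix", hel["B"]),
            ("BC", "loop", bc),
            ("C", "helix", hel["C"]),
            ("CD", "loop", cdl),
            ("D", "helix", hel["D"]),
            ("tail", "loop", tail),
        ]
        coords, segments = _assemble(parts)
        return coords, segments, dN, ztop

    raise InfeasibleBundleError(kind)


def _choose_cys(coords, segments, kind, n, explicit=None):
    """Return (i, j, thread_tail, expected_label, expected_terminus)."""
    if explicit is not None:
        i, j = sorted(explicit)
        return i, j, None
    a0, a1 = segments["A"]
    b0, b1 = segments["B"]
    c0, c1 = segments["C"]
    d0, d1 = segments["D"]
    if kind == "none":
        return None
    if kind == "zero_knot":
        return 0, n - 1, None
    if kind == "cinch":
        # top of B to top of C: short internal empty loop across the BC turn
        i, j, _ = _facing_pair(coords, range(b1 - 5, b1 + 1), range(c0, c0 + 6))
        return i, j, None
    if kind == "empty_loop":
        # feet of B and C: large empty loop (helix B + BC loop + helix C)
        i, j, _ = _facing_pair(coords, range(b0, b0 + 6), range(c1 - 5, c1 + 1))
        return i, j, None
    if kind == "lasso_N":
        i, j, _ = _facing_pair(coords, range(a0, a0 + 5), range(b0, b0 + 6))
        return i, j, None
    if kind == "lasso_C":
        i, j, _ = _facing_pair(coords, range(c1 - 5, c1 + 1), range(d1 - 4, d1 + 1))
        return i, j, None
    if kind == "pierced_C":
        # ring closes across the C/D helix tops: first residues of C,
        # last residues of D
        i, j, _ = _facing_pair(coords, range(c0, c0 + 5), range(d1 - 4, d1 + 1))
        return i, j, "N"
    if kind == "pierced_N":
        i, j, _ = _facing_pair(coords, range(a0, a0 + 4), range(b1 - 4, b1 + 1))
        return i, j, "C"
    raise InfeasibleBundleError(kind)


_EXPECTED = {
    "zero_knot": ("zero_knot", "both-termini"),
    "cinch": ("cinch", "internal"),
    "empty_loop": ("cinch", "internal"),
    "lasso_N": ("empty_lasso", "N"),
    "lasso_C": ("empty_lasso", "C"),
    "pierced_N": ("pierced_lasso", "N"),
    "pierced_C": ("pierced_lasso", "C"),
}


def _validate_geometry(coords):
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if d.min() < 2.8 or d.max() > 4.5:
        k = int(np.argmin(d)) if d.min() < 2.8 else int(np.argmax(d))
        raise InfeasibleBundleError(
            f"virtual bond {k}-{k+1} length {d[k]:.2f} A outside [2.8, 4.5]"
        )
    n = len(coords)
    dm = np.linalg.norm(coords[:, None] - coords[None], axis=2)
    dm[np.arange(n), np.arange(n)] = np.inf
    dm[np.arange(n - 1), np.arange(1, n)] = np.inf
    dm[np.arange(1, n), np.arange(n - 1)] = np.inf
    mn = dm.min()
    if mn < MIN_NONADJ:
        i, j = np.unravel_index(np.argmin(dm), dm.shape)
        raise InfeasibleBundleError(
            f"nonconsecutive residues {i},{j} only {mn:.2f} A apart (< {MIN_NONADJ})"
        )


def _random_rigid(seed):
    rng = np.random.default_rng(seed)
    # uniform random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-20, 20, 3)
    return q, t


def make_bundle(spec: BundleSpec, author_offset: int = 1,
                validate: bool = True) -> Structure:
    """Build one synthetic bundle according to ``spec``.

    The structure is returned in a seeded, generic rigid-body frame (so no
    coordinate plane is axis-aligned by accident). ``meta`` carries the
    segment map, the expected classification and the designated cys pair.

    Raises
    ------
    InfeasibleBundleError
        If the requested geometry violates the generator invariants or the
        built structure does not classify as the requested kind.
    """
    coords, segments, d, ztop = _kind_geometry(spec)
    n = len(coords)
    if not (60 <= n <= 250):
        raise InfeasibleBundleError(f"total length {n} outside [60, 250]")

    choice = _choose_cys(coords, segments, spec.lasso_kind, n, spec.cys_pair)
    sg = {}
    bridge = None
    if choice is not None:
        i, j, _tail_side = choice
        _pinch(coords, i, j)
        mid = 0.5 * (coords[i] + coords[j])
        u = coords[j] - coords[i]
        u = u / np.linalg.norm(u)
        sg[i] = mid - (SG_BOND / 2) * u
        sg[j] = mid + (SG_BOND / 2) * u
        bridge = DisulphideBridge(i, j)

    R, t = _random_rigid(spec.seed)
    coords = coords @ R.T + t
    sg = {k: R @ v + t for k, v in sg.items()}

    seq = np.array(["G"] * n)
    for name in ("A", "B", "C", "D"):
        s0, s1 = segments[name]
        seq[s0 : s1 + 1] = "A"
    if bridge is not None:
        seq[bridge.i] = "C"
        seq[bridge.j] = "C"

    s = Structure(
        residue_ids=np.arange(author_offset, author_offset + n),
        sequence="".join(seq),
        ca_coords=coords,
        sg_coords=sg,
        chain_id="A",
    )
    s.meta = {
        "kind": spec.lasso_kind,
        "segments": segments,
        "cys_pair": (bridge.i, bridge.j) if bridge else None,
        "spec": spec,
    }
    if spec.lasso_kind in _EXPECTED:
        s.meta["expected_label"], s.meta["expected_terminus"] = _EXPECTED[
            spec.lasso_kind
        ]

    if validate:
        _validate_geometry(s.ca_coords)
        if bridge is not None:
            cls = classify_lasso(s, bridge)
            exp_label, exp_term = _EXPECTED[spec.lasso_kind]
            if cls.label != exp_label or cls.terminus != exp_term:
                raise InfeasibleBundleError(
                    f"{spec.lasso_kind}: built bundle classifies as "
                    f"{cls.label}/{cls.terminus}, expected {exp_label}/{exp_term} "
                    f"(net N={cls.net_N}, C={cls.net_C})"
                )
            if spec.lasso_kind.startswith("pierced"):
                tail_net = cls.net_N if spec.lasso_kind == "pierced_C" else cls.net_C
                other = cls.net_C if spec.lasso_kind == "pierced_C" else cls.net_N
                if abs(tail_net) != 1 or other != 0:
                    raise InfeasibleBundleError(
                        f"{spec.lasso_kind}: net crossings N={cls.net_N} "
                        f"C={cls.net_C}, expected |thread|=1, other=0"
                    )
            s.meta["classification"] = cls
    return s


def default_spec(kind: str, seed: int = 0) -> BundleSpec:
    """Study-condition sizes for each lasso kind.

    The two pierced fixtures realize the small-loop C-lasso versus
    large-loop N-lasso contrast at reduced scale (loop sizes ~26 vs ~36
    residues standing in for the 50 versus >= 68 of the natural proteins).
    """
    if kind == "pierced_C":
        return BundleSpec(helix_length=12, loop_length=3, lasso_kind=kind, seed=seed)
    if kind == "pierced_N":
        return BundleSpec(helix_length=12, loop_length=16, lasso_kind=kind, seed=seed)
    if kind == "empty_loop":
        return BundleSpec(helix_length=12, loop_length=6, lasso_kind=kind, seed=seed)
    return BundleSpec(helix_length=12, loop_length=6, lasso_kind=kind, seed=seed)


def make_test_set(n: int, seed: int = 0):
    """``n`` bundles cycling through all lasso kinds, with the expected
    classification recorded at generation time."""
    out = []
    for k in range(n):
        kind = KINDS[k % len(KINDS)]
        spec = default_spec(kind, seed=seed + 1000 * k)
        s = make_bundle(spec)
        out.append((s, s.meta.get("classification")))
    return out


def leptin_analog(seed: int = 0) -> Structure:
    """A pierced_C bundle sized so the covalent loop spans 50 residues and
    the bridging cysteines carry author numbers 96 and 146."""
    base = make_bundle(
        BundleSpec(helix_length=23, loop_length=5, lasso_kind="pierced_C",
                   seed=seed)
    )
    i, j = base.meta["cys_pair"]
    if j - i != 50:
        # slide the loop-opening cysteine along helix C to span exactly 50
        # residues (leptin's C96 sits in a loop region, not a helix cap)
        s = make_bundle(
            BundleSpec(helix_length=23, loop_length=5, lasso_kind="pierced_C",
                       cys_pair=(i + (j - i - 50), j), seed=seed)
        )
    else:
        s = base
    i, j = s.meta["cys_pair"]
    s2 = Structure(
        residue_ids=np.arange(96 - i, 96 - i + s.n_residues),
        sequence=s.sequence,
        ca_coords=s.ca_coords,
        sg_coords=s.sg_coords,
        chain_id="A",
    )
    s2.meta = s.meta
    return s2


def _interior_angles(full):
    u = full[:-2] - full[1:-1]
    v = full[2:] - full[1:-1]
    c = (u * v).sum(1) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.degrees(np.arccos(np.clip(c, -1, 1)))


def _best_wiggle(pts, p_prev, p_next, amplitude):
    """Pick the wiggle phase whose straightest angle is most bent.

    Loop curvature can locally cancel the helical perturbation; trying four
    phase offsets and keeping the best is deterministic and cheap.
    """
    best = None
    best_max = np.inf
    for ph in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
        w = _coil_wiggle(pts, p_prev, p_next, amplitude=amplitude, phase0=ph)
        full = np.vstack([p_prev, w, p_next])
        mx = _interior_angles(full).max()
        if mx < best_max:
            best_max = mx
            best = w
    return best
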