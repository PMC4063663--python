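"""Covalent-loop (lasso) topology classification.

A disulphide bridge between residues ``i < j`` closes the backbone stretch
``i..j`` into a covalently closed loop. Spanning that loop with a triangle
fan and counting signed crossings of the two chain tails through the fan
distinguishes the taxonomy used throughout the package:

* ``zero_knot``   — both bridging cysteines sit at the chain termini,
* ``cinch``       — both cysteines internal, nothing threaded,
* ``empty_lasso`` — one terminal cysteine, nothing threaded,
* ``pierced_lasso`` — a tail passes through the loop (net crossing != 0).

The net crossing number of a tail is a topological quantity: it is
invariant under deformations of the spanning surface as long as neither the
loop nor the tail is crossed, which is why a cheap centroid fan is an
adequate stand-in for a minimal surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import DisulphideBridge, Structure, StructureError


class TopologyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# closed curve and spanning surface


@dataclass
class ClosedCurve:
    """Closed polygon in 3-space (closure between last and first vertex)."""

    vertices: np.ndarray  # (m, 3)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if len(self.vertices) < 3:
            raise TopologyError("closed curve needs >= 3 vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def length(self) -> float:
        v = self.vertices
        d = np.diff(np.vstack([v, v[:1]]), axis=0)
        return float(np.linalg.norm(d, axis=1).sum())


@dataclass
class SpannedSurface:
    """Centroid triangle fan over a closed curve."""

    triangles: np.ndarray  # (m, 3, 3)
    curve: ClosedCurve

    @property
    def centroid(self) -> np.ndarray:
        return self.triangles[0, 0]

    def normals(self) -> np.ndarray:
        t = self.triangles
        return np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])

    def mean_normal(self) -> np.ndarray:
        n = self.normals().sum(axis=0)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise TopologyError("surface has vanishing mean normal")
        return n / norm

    def area(self) -> float:
        return float(0.5 * np.linalg.norm(self.normals(), axis=1).sum())


def chaikin_closed(vertices: np.ndarray, rounds: int) -> np.ndarray:
    """Corner-cutting smoothing of a closed polygon (closure preserved).

    Each round replaces every edge (a, b) with the two points
    0.75 a + 0.25 b and 0.25 a + 0.75 b; total curve length never increases.
    """
    v = np.asarray(vertices, dtype=float)
    for _ in range(rounds):
        nxt = np.roll(v, -1, axis=0)
        out = np.empty((2 * len(v), 3))
        out[0::2] = 0.75 * v + 0.25 * nxt
        out[1::2] = 0.25 * v + 0.75 * nxt
        v = out
    return v


def close_loop(
    s: Structure, b: DisulphideBridge, smooth_rounds: int = 0
) -> ClosedCurve:
    """Close the backbone stretch ``i..j`` into a polygon via the bridge chord.

    Raises if a chain break falls inside the loop: a covalent loop spanning
    unresolved residues has no well-defined topology, so the analysis fails
    loudly instead of bridging the gap.
    """
    inside = [k for k in s.chain_breaks() if b.i <= k < b.j]
    if inside:
        raise TopologyError(
            f"chain break(s) inside covalent loop {b.i}-{b.j} "
            f"at segment(s) {inside}"
        )
    verts = s.ca_coords[b.i : b.j + 1]
    if smooth_rounds:
        verts = chaikin_closed(verts, smooth_rounds)
    return ClosedCurve(verts)


def span_surface(c: ClosedCurve) -> SpannedSurface:
    """Triangle fan from the curve centroid; boundary equals the curve."""
    v = c.vertices
    centroid = v.mean(axis=0)
    rel = v - centroid
    # degenerate when all vertices are collinear (no 2-D extent)
    sv = np.linalg.svd(rel, compute_uv=False)
    if len(sv) < 2 or sv[1] < 1e-9 * max(sv[0], 1.0):
        raise TopologyError("degenerate (collinear) closed curve")
    nxt = np.roll(v, -1, axis=0)
    tris = np.stack(
        [np.broadcast_to(centroid, v.shape), v, nxt], axis=1
    ).copy()
    return SpannedSurface(triangles=tris, curve=c)


# ---------------------------------------------------------------------------
# segment-triangle crossings


@dataclass
class Crossing:
    segment: int      # chain segment index (between points k and k+1)
    t: float          # position along the segment in [0, 1]
    sign: int         # +1 along, -1 against the surface orientation
    point: np.ndarray


def _segment_triangle_hits(p0, p1, tris, tol=1e-9):
    """Vectorized Moller-Trumbore: segments (S,3)->(S,3) vs triangles (T,3,3).

    Returns arrays (seg_idx, tri_idx, t, sign, point) for parametric hits
    with 0 <= t <= 1 inside the closed triangle, plus a boolean flag marking
    near-parallel (in-plane) incidences that require a jitter retry.
    """
    d = (p1 - p0)[:, None, :]                      # (S,1,3)
    a = tris[None, :, 0, :]                        # (1,T,3)
    e1 = (tris[:, 1] - tris[:, 0])[None, :, :]
    e2 = (tris[:, 2] - tris[:, 0])[None, :, :]
    n = np.cross(e1, e2)                           # (1,T,3)
    denom = (d * n).sum(-1)                        # (S,T)
    s_vec = p0[:, None, :] - a
    num = -(s_vec * n).sum(-1)
    scale = np.linalg.norm(n, axis=2) * (np.linalg.norm(d, axis=2) + 1e-30)
    parallel = np.abs(denom) < tol * np.maximum(scale, 1e-30)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    t = np.where(parallel, np.nan, t)
    in_t = (t >= -tol) & (t <= 1 + tol)
    # barycentric test at the intersection point
    pt = p0[:, None, :] + t[..., None] * d
    w = pt - a
    d00 = (e1 * e1).sum(-1)
    d01 = (e1 * e2).sum(-1)
    d11 = (e2 * e2).sum(-1)
    d20 = (w * e1).sum(-1)
    d21 = (w * e2).sum(-1)
    det = d00 * d11 - d01 * d01
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (d11 * d20 - d01 * d21) / det
        v = (d00 * d21 - d01 * d20) / det
    bary = (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
    hit = in_t & bary & ~parallel
    # a segment lying (numerically) in a triangle plane with an endpoint close
    # to the triangle needs the jitter retry
    grazing = parallel & (np.abs(num) < 1e-6 * np.maximum(scale, 1e-30))
    si, ti = np.nonzero(hit)
    signs = np.sign(denom[si, ti]).astype(int)
    return si, ti, t[si, ti], signs, pt[si, ti], bool(grazing.any())


def count_crossings(
    surf: SpannedSurface,
    chain: np.ndarray,
    eps_geo: float = 1e-3,
    _jitter_seed: int = 20140523,
) -> list[Crossing]:
    """Signed crossings of a polyline through the spanned surface.

    Crossings are ordered along the chain. Hits landing on internal fan
    edges (shared by two triangles) are de-duplicated; opposite-sign hits of
    the same segment closer than ``eps_geo`` pair-cancel. Segments lying
    exactly in a triangle plane trigger a deterministic jitter retry.
    """
    chain = np.asarray(chain, dtype=float)
    if chain.ndim != 2 or len(chain) < 2:
        return []
    p0, p1 = chain[:-1], chain[1:]
    tris = surf.triangles
    for attempt in range(4):
        si, ti, tt, sg, pts, grazing = _segment_triangle_hits(p0, p1, tris)
        if not grazing:
            break
        rng = np.random.default_rng(_jitter_seed + attempt)
        jit = 1e-4 * rng.standard_normal(chain.shape)
        p0, p1 = chain[:-1] + jit[:-1], chain[1:] + jit[1:]
    crossings: list[Crossing] = []
    order = np.lexsort((tt, si))
    for idx in order:
        c = Crossing(int(si[idx]), float(tt[idx]), int(sg[idx]), pts[idx])
        dup = False
        for prev in crossings:
            if prev.segment == c.segment and np.linalg.norm(prev.point - c.point) < 1e-6:
                dup = True
                break
        if not dup:
            crossings.append(c)
    # pair-cancellation of grazing touches within one segment
    cleaned: list[Crossing] = []
    for c in crossings:
        if (
            cleaned
            and cleaned[-1].segment == c.segment
            and cleaned[-1].sign == -c.sign
            and np.linalg.norm(cleaned[-1].point - c.point) < eps_geo
        ):
            cleaned.pop()
        else:
            cleaned.append(c)
    return cleaned


def net_crossing(crossings: list[Crossing]) -> int:
    return int(sum(c.sign for c in crossings))


def side_parity(
    crossings: list[Crossing], n_points: int
) -> np.ndarray:
    """Per-point parity along a polyline, walking from point 0 (parity 0).

    Point ``k`` accumulates the crossings of segments ``0..k-1``; odd parity
    means the point lies on the opposite side of the surface from point 0.
    """
    par = np.zeros(n_points, dtype=int)
    for c in crossings:
        par[c.segment + 1 :] += 1
    return par % 2


# ---------------------------------------------------------------------------
# classification


@dataclass
class LassoClassification:
    label: str                      # zero_knot | cinch | empty_lasso | pierced_lasso
    terminus: str                   # N | C | internal | both-termini
    bridge: DisulphideBridge
    loop_size: int
    crossings_N_tail: list = field(default_factory=list)
    crossings_C_tail: list = field(default_factory=list)
    threaded_segment: tuple | None = None
    ambiguous: bool = False

    @property
    def net_N(self) -> int:
        return net_crossing(self.crossings_N_tail)

    @property
    def net_C(self) -> int:
        return net_crossing(self.crossings_C_tail)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "terminus": self.terminus,
            "bridge_i": self.bridge.i,
            "bridge_j": self.bridge.j,
            "loop_size": self.loop_size,
            "net_N": self.net_N,
            "net_C": self.net_C,
            "threaded_segment": list(self.threaded_segment)
            if self.threaded_segment
            else None,
            "ambiguous": self.ambiguous,
        }


def _tail_crossings(surf, ca, b, tail):
    """Crossings of one tail, ordered walking from the free terminus.

    The bridging cysteines belong to the loop itself and are excluded from
    the tail polylines.
    """
    if tail == "N":
        pts = ca[: b.i]              # terminus ... residue i-1
    else:
        pts = ca[b.j + 1 :][::-1]    # terminus ... residue j+1
    if len(pts) < 2:
        return [], pts
    return count_crossings(surf, pts), pts


def classify_lasso(
    s: Structure,
    b: DisulphideBridge,
    terminal_margin: int = 10,
    smooth_rounds: int = 2,
    check_rounds: tuple = (0, 3),
) -> LassoClassification:
    """Classify the covalent-loop topology closed by bridge ``b``.

    ``loop_size`` follows the sequence-separation convention ``j - i``
    (e.g. a 96-146 bridge closes a 50-residue loop). The classification is
    recomputed at the smoothing levels in ``check_rounds``; disagreement of
    any net crossing number sets ``ambiguous`` instead of silently picking
    one answer.
    """
    ca = s.ca_coords
    n = s.n_residues

    def _nets(rounds):
        curve = close_loop(s, b, smooth_rounds=rounds)
        surf = span_surface(curve)
        cn, _ = _tail_crossings(surf, ca, b, "N")
        cc, _ = _tail_crossings(surf, ca, b, "C")
        return surf, cn, cc

    surf, cross_n, cross_c = _nets(smooth_rounds)
    nets = (net_crossing(cross_n), net_crossing(cross_c))
    ambiguous = False
    for r in check_rounds:
        if r == smooth_rounds:
            continue
        try:
            _, cn, cc = _nets(r)
        except TopologyError:
            ambiguous = True
            continue
        if (net_crossing(cn), net_crossing(cc)) != nets:
            ambiguous = True

    n_terminal = b.i <= terminal_margin - 1
    c_terminal = (n - 1 - b.j) <= terminal_margin - 1
    if n_terminal and c_terminal:
        terminus = "both-termini"
    elif n_terminal:
        terminus = "N"
    elif c_terminal:
        terminus = "C"
    else:
        terminus = "internal"

    pierced = nets[0] != 0 or nets[1] != 0
    if pierced:
        label = "pierced_lasso"
    elif terminus == "both-termini":
        label = "zero_knot"
    elif terminus == "internal":
        label = "cinch"
    else:
        label = "empty_lasso"

    threaded = None
    if pierced:
        if nets[0] != 0:
            par = side_parity(cross_n, b.i)
            far = np.nonzero(par == 1)[0]          # indices into 0..i-1
        else:
            par = side_parity(cross_c, n - 1 - b.j)
            far = n - 1 - np.nonzero(par == 1)[0]  # map reversed walk back
            far = np.sort(far)
        if len(far):
            runs = np.split(far, np.nonzero(np.diff(far) > 1)[0] + 1)
            longest = max(runs, key=len)
            threaded = (int(longest[0]), int(longest[-1]))

    return LassoClassification(
        label=label,
        terminus=terminus,
        bridge=b,
        loop_size=b.j - b.i,
        crossings_N_tail=cross_n,
        crossings_C_tail=cross_c,
        threaded_segment=threaded,
        ambiguous=ambiguous,
    )


def scan_candidates(
    structures: list[Structure],
    loop_min: int = 40,
    loop_max: int = 200,
    **classify_kwargs,
):
    """Classify every detected bridge and keep pierced lassos with
    ``loop_min < loop_size < loop_max`` (both bounds exclusive, matching the
    40/200 sequence-separation filter for candidate discovery).

    Returns ``(accepted, report)`` where ``report`` lists every candidate
    with its outcome and, for rejects, the reason.
    """
    from .structure import detect_disulphides

    accepted: list[LassoClassification] = []
    report: list[dict] = []
    for idx, s in enumerate(structures):
        bridges = detect_disulphides(s)
        for b in bridges:
            entry = {"structure": idx, "bridge": (b.i, b.j)}
            try:
                cls = classify_lasso(s, b, **classify_kwargs)
            except TopologyError as exc:
                entry.update(status="rejected", reason=f"topology error: {exc}")
                report.append(entry)
                continue
            entry.update(classification=cls.to_dict())
            if cls.label != "pierced_lasso":
                entry.update(status="rejected", reason=f"not pierced ({cls.label})")
            elif not (loop_min < cls.loop_size < loop_max):
                entry.update(
                    status="rejected",
                    reason=f"loop_size {cls.loop_size} outside ({loop_min}, {loop_max})",
                )
            else:
                entry.update(status="accepted")
                accepted.append(cls)
            report.append(entry)
    return accepted, report
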