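"""Threading-mechanism analysis along trajectories.

For each analyzed frame the covalent loop is rebuilt from the
instantaneous coordinates, spanned with a triangle fan and intersected
with the thread tail. The resulting per-frame crossing states distinguish
the two threading routes of pierced lassos:

* slipknotting — a doubled chain (hairpin or loop) passes through the
  closed loop first, the free terminus following only at the end;
* plugging — the free terminus leads through the loop in a single pass.

The operational rule (the source taxonomy names the routes but not a
frame-level criterion, so this is the package's documented
reconstruction): find the first analyzed frame from which the tail's net
crossing number equals the native value for at least ``min_dwell``
consecutive frames ("establishment"), walk back over the contiguous
crossing episode that produced it, and inspect the episode's first frame —
a single crossing within ``terminal_window`` residues of the free terminus
means the terminus led (plug); anything else (an opposite-sign crossing
pair, or a first crossing far from the terminus) means doubled chain
(slipknot). Transitions that never establish the native parity are labeled
``none`` — with a dynamic or reduced bridge the chain can reach the native
basin while the loop is open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .structure import DisulphideBridge, Structure
from .topology import (
    ClosedCurve,
    TopologyError,
    chaikin_closed,
    count_crossings,
    net_crossing,
    span_surface,
)


class MechanismError(ValueError):
    pass


@dataclass
class CrossingState:
    """Crossing summary of one analyzed frame."""

    frame: int
    crossings: list                 # Crossing objects, terminus -> cys order
    net: int
    undefined: bool = False         # degenerate (collapsed) loop geometry

    @property
    def count(self) -> int:
        return len(self.crossings)


@dataclass
class MechanismRecord:
    transition: tuple               # (start, end) in analyzed-frame units
    label: str                      # slipknot | plug | none
    first_crossing_residue: int | None = None
    established_at: int | None = None
    evidence: dict = field(default_factory=dict)


def _tail_points(x, b: DisulphideBridge, tail: str):
    if tail == "N":
        return x[: b.i]
    return x[b.j + 1 :][::-1]


def crossing_trace(traj, s: Structure, b: DisulphideBridge, tail: str,
                   stride: int = 1, smooth_rounds: int = 2):
    """Per-frame crossing states of one tail through the covalent loop.

    ``traj`` may be a Trajectory or a plain (m, n, 3) array; the loop
    surface is rebuilt from the instantaneous loop coordinates each frame.
    Frames with degenerate (collinear/collapsed) loops are marked
    undefined and excluded from classification windows.
    """
    frames = traj.frames if hasattr(traj, "frames") else np.asarray(traj)
    states = []
    for k in range(0, len(frames), stride):
        x = frames[k]
        verts = chaikin_closed(x[b.i : b.j + 1], smooth_rounds)
        try:
            surf = span_surface(ClosedCurve(verts))
            cr = count_crossings(surf, _tail_points(x, b, tail))
            states.append(CrossingState(k, cr, net_crossing(cr)))
        except TopologyError:
            states.append(CrossingState(k, [], 0, undefined=True))
    return states


def _episode_start(states, est_idx, max_gap: int = 2):
    """Walk back from establishment over the contiguous crossing episode."""
    k = est_idx
    gap = 0
    start = est_idx
    while k >= 0:
        st = states[k]
        if st.undefined:
            k -= 1
            continue
        if st.count > 0:
            start = k
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                break
        k -= 1
    return start


def classify_transition(
    states,
    transition: tuple,
    native_net: int,
    n_tail: int,
    min_dwell: int = 3,
    terminal_window: int = 3,
) -> MechanismRecord:
    """Label one folding transition as slipknot, plug, or none.

    ``states`` is the crossing trace (analyzed-frame units), ``transition``
    the (start, end) window, ``native_net`` the native net crossing of the
    tail (+-1) and ``n_tail`` the number of tail residues (the free
    terminus is tail residue 0 in walk order).
    """
    a, bnd = transition
    window = [st for st in states if a <= st.frame <= bnd]
    if not window:
        raise MechanismError("empty transition window")
    n_undef = sum(st.undefined for st in window)
    if n_undef > len(window) / 2:
        return MechanismRecord(transition, "none",
                               evidence={"degenerate_loop": True})

    # establishment: native parity held for >= min_dwell analyzed frames
    est = None
    run = 0
    for idx, st in enumerate(window):
        if st.undefined:
            continue
        if st.net == native_net:
            run += 1
            if run >= min_dwell:
                est = idx - min_dwell + 1
                break
        else:
            run = 0
    if est is None:
        return MechanismRecord(transition, "none")

    start = _episode_start(window, est)
    first = window[start]
    # crossing position in residues from the free terminus
    seg = min(c.segment for c in first.crossings) if first.crossings else None
    if (
        first.count == 1
        and seg is not None
        and seg <= terminal_window
    ):
        label = "plug"
    else:
        label = "slipknot"
    return MechanismRecord(
        transition,
        label,
        first_crossing_residue=seg,
        established_at=window[est].frame,
        evidence={
            "episode_start_frame": first.frame,
            "episode_start_count": first.count,
            "episode_signs": [c.sign for c in first.crossings],
        },
    )


def mechanism_stats(records) -> dict:
    """Fractions per label with Wilson 95% confidence intervals."""
    records = list(records)
    if not records:
        raise MechanismError("no records")
    labels = ("slipknot", "plug", "none")
    n = len(records)
    out = {"n": n}
    z = norm.ppf(0.975)
    for lab in labels:
        k = sum(r.label == lab for r in records)
        p = k / n
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        out[lab] = {
            "count": k,
            "fraction": p,
            "ci95": (max(0.0, center - half), min(1.0, center + half)),
        }
    return out


def modal_label(records) -> str:
    stats = mechanism_stats(records)
    return max(("slipknot", "plug", "none"), key=lambda l: stats[l]["count"])


def records_to_json(records) -> list:
    return [
        {
            "transition": list(r.transition),
            "label": r.label,
            "first_crossing_residue": r.first_crossing_residue,
            "established_at": r.established_at,
            "evidence": {k: v for k, v in r.evidence.items()},
        }
        for r in records
    ]
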