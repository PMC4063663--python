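"""Study protocols combining the simulation and analysis layers.

These are the reference workflows the package uses to characterize a
pierced-lasso bundle:

* ``harvest_unthreaded`` — draw unfolded, geometrically unthreaded
  conformations from a high-temperature run of the reduced-bridge model
  (the in-silico analog of a reduced denatured ensemble);
* ``threading_transitions`` — oxidative refolding: close the bridge on a
  harvested conformation and drive folding with a staircase of umbrella
  windows along Q until the native thread parity establishes, then label
  the threading route (slipknotting versus plugging);
* ``thermo_scan`` — constant-temperature runs bracketing the folding
  temperature plus multi-histogram reweighting for Cv(T) and Tf.

All protocol entry points take a seed and are deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import ThermoResult, compute_Q, detect_transitions, wham
from .md import RunConfig, Trajectory, minimize, run_langevin, run_umbrella
from .mechanism import (
    MechanismRecord,
    classify_transition,
    crossing_trace,
)
from .sbm import ContactMap, build_topology
from .structure import DisulphideBridge, Structure
from .topology import (
    ClosedCurve,
    TopologyError,
    chaikin_closed,
    count_crossings,
    net_crossing,
    span_surface,
)


def frame_net_crossing(x, b: DisulphideBridge, tail: str,
                       smooth_rounds: int = 2) -> int | None:
    """Net crossing of one tail for a single conformation (None when the
    instantaneous loop is degenerate)."""
    verts = chaikin_closed(x[b.i : b.j + 1], smooth_rounds)
    try:
        surf = span_surface(ClosedCurve(verts))
    except TopologyError:
        return None
    pts = x[: b.i] if tail == "N" else x[b.j + 1 :][::-1]
    return net_crossing(count_crossings(surf, pts))


def harvest_unthreaded(
    s: Structure,
    cm: ContactMap,
    bridge: tuple,
    tail: str,
    n_starts: int,
    seed: int = 0,
    T_harvest: float = 1.5,
    q_max: float = 0.55,
    d_ss_max: float = 1.6,
    min_separation: int = 15,
    steps_per_run: int = 600_000,
    max_runs: int = 24,
):
    """Unfolded, unthreaded starting conformations (nm) from reduced runs.

    Frames qualify when the chain is unfolded (Q < ``q_max``), the thread
    tail shows zero net crossing through the virtual loop, and the
    cysteines are within ``d_ss_max`` nm of each other so the bridge can
    be closed by a short relaxation.
    """
    i, j = bridge
    t_red = build_topology(s, cm, DisulphideBridge(i, j, "reduced"))
    starts = []
    for r in range(max_runs):
        tr = run_langevin(
            t_red, t_red.x_native,
            RunConfig(T=T_harvest, n_steps=steps_per_run, stride=2000,
                      seed=seed + 7919 * r),
        )
        q = compute_Q(tr, cm).q
        dss = np.linalg.norm(tr.frames[:, j] - tr.frames[:, i], axis=1)
        last = -min_separation
        for k in range(len(q)):
            if (
                q[k] < q_max
                and dss[k] < d_ss_max
                and k - last >= min_separation
                and frame_net_crossing(tr.frames[k], t_red.ss_bridge, tail) == 0
            ):
                starts.append(tr.frames[k].copy())
                last = k
                if len(starts) >= n_starts:
                    return starts
    return starts


@dataclass
class ThreadingAttempt:
    success: bool
    record: MechanismRecord | None
    trajectory_frames: np.ndarray | None
    q: np.ndarray | None


def _steered_fold(
    t_ox, x0, seed,
    T: float = 1.12,
    T_melt: float = 1.45,
    ladder=(0.65, 0.9),
    ladder_steps: int = 20_000,
    k_ladder: float = 1000.0,
    melt_steps: int = 30_000,
    k_melt: float = 1200.0,
    push_steps: int = 40_000,
    k_push: float = 3000.0,
    confirm_steps: int = 20_000,
    blocks_per_cycle: int = 2,
    max_cycles: int = 6,
    stride: int = 4000,
    bridge=None,
    tail: str = "N",
    native_net: int = 1,
):
    """One oxidative-refolding attempt driven along Q.

    The fold is pushed with umbrella blocks at Q_center = 1; whenever the
    chain stalls in the unthreaded near-native trap, a short hot window at
    Q_center = 0.7 re-melts it and the push restarts (annealing cycles).
    Returns ``(frames, threaded, last_cycle_start)`` where the last index
    marks the first frame of the final melt-and-fold cycle — the folding
    transition to classify.
    """
    x = x0
    v = None
    frames = []
    nframes = 0
    last_cycle_start = 0
    for w, qc in enumerate(ladder):
        tr = run_umbrella(
            t_ox, x, RunConfig(T=T, n_steps=ladder_steps, stride=stride,
                               seed=seed + w),
            Q_center=qc, k_umb=k_ladder, v0=v,
        )
        x, v = tr.x_final, tr.v_final
        frames.append(tr.frames)
        nframes += len(tr.frames)
    threaded = False
    for cyc in range(max_cycles):
        if cyc > 0:
            tr = run_umbrella(
                t_ox, x, RunConfig(T=T_melt, n_steps=melt_steps,
                                   stride=stride, seed=seed + 50 + 20 * cyc),
                Q_center=0.55, k_umb=k_melt, v0=v,
            )
            x, v = tr.x_final, tr.v_final
            last_cycle_start = nframes
            frames.append(tr.frames)
            nframes += len(tr.frames)
        for blk in range(blocks_per_cycle):
            tr = run_umbrella(
                t_ox, x, RunConfig(T=T, n_steps=push_steps, stride=stride,
                                   seed=seed + 100 + 20 * cyc + blk),
                Q_center=1.0, k_umb=k_push, v0=v,
            )
            x, v = tr.x_final, tr.v_final
            frames.append(tr.frames)
            nframes += len(tr.frames)
            tail_nets = [
                frame_net_crossing(fr, bridge, tail) for fr in tr.frames[-2:]
            ]
            if all(nn == native_net for nn in tail_nets):
                threaded = True
                break
        if threaded:
            break
    if threaded and confirm_steps > 0:
        # extend past establishment so the classifier sees a full dwell
        tr = run_umbrella(
            t_ox, x, RunConfig(T=T, n_steps=confirm_steps, stride=stride,
                               seed=seed + 999),
            Q_center=1.0, k_umb=k_push, v0=v,
        )
        frames.append(tr.frames)
    return np.concatenate(frames, axis=0), threaded, last_cycle_start


def threading_transitions(
    s: Structure,
    cm: ContactMap,
    n_transitions: int,
    seed: int = 0,
    tail: str | None = None,
    T_fold: float = 1.12,
    max_attempts: int | None = None,
    q_lo: float = 0.62,
    q_hi: float = 0.93,
    min_dwell: int = 3,
    trace_stride: int = 2,
    **harvest_kwargs,
):
    """Collect classified threading transitions by oxidative refolding.

    Returns ``(records, n_attempts)``. Each record labels one completed
    folding transition of the oxidized-bridge model as slipknot or plug;
    attempts that do not thread within the push budget are discarded (they
    are stalled, not folded — the native basin requires the thread).
    """
    i, j = s.meta["cys_pair"]
    if tail is None:
        tail = "N" if s.meta["kind"] == "pierced_C" else "C"
    cls = s.meta.get("classification")
    native_net = None
    if cls is not None:
        native_net = cls.net_N if tail == "N" else cls.net_C
    if not native_net:
        native_net = 1
    bridge = DisulphideBridge(i, j, "oxidized")
    t_ox = build_topology(s, cm, bridge)
    if max_attempts is None:
        max_attempts = 3 * n_transitions

    records = []
    attempts = 0
    chunk = 0
    queue: list = []
    while len(records) < n_transitions and attempts < max_attempts:
        if not queue:
            queue = harvest_unthreaded(
                s, cm, (i, j), tail, n_starts=24,
                seed=seed + 104729 * chunk, **harvest_kwargs,
            )
            chunk += 1
            if not queue:
                break
        x0 = queue.pop(0)
        attempts += 1
        x0r = minimize(t_ox, x0, n_steps=800)
        if frame_net_crossing(x0r, bridge, tail) != 0:
            continue    # bridge closure accidentally threaded the loop
        frames, threaded, cyc0 = _steered_fold(
            t_ox, x0r, seed=seed + 997 * attempts, T=T_fold,
            bridge=bridge, tail=tail, native_net=native_net,
        )
        if not threaded:
            continue
        # classify the final melt-and-fold cycle only
        frames = frames[cyc0:]
        q = compute_Q(frames, cm).q
        trans = detect_transitions(q, q_lo=q_lo, q_hi=q_hi,
                                   min_dwell=min_dwell)
        if not trans:
            # threading completed without Q dwelling below q_lo in the
            # final cycle; the whole cycle is the transition window
            trans = [(0, len(q) - 1)]
        states = crossing_trace(frames, s, bridge, tail,
                                stride=trace_stride)
        rec = classify_transition(
            states,
            (trans[-1][0], len(q) - 1),
            native_net=native_net,
            n_tail=i if tail == "N" else s.n_residues - 1 - j,
            min_dwell=min_dwell,
        )
        if rec.label != "none":
            records.append(rec)
    return records, attempts


def thermo_scan(
    s: Structure,
    cm: ContactMap,
    state: str,
    temps,
    seed: int = 0,
    n_steps: int = 1_200_000,
    n_equil: int = 150_000,
    stride: int = 500,
    eps_ss: float = 1.0,
):
    """Constant-T runs from the native state plus WHAM.

    Returns ``(ThermoResult, trajectories)``; the trajectories are reused
    for mechanism-curve analysis.
    """
    i, j = s.meta["cys_pair"]
    ss = DisulphideBridge(i, j, state)
    t = build_topology(s, cm, ss, eps_ss=eps_ss)
    trajs = []
    energies = []
    for k, T in enumerate(temps):
        eq = run_langevin(
            t, t.x_native,
            RunConfig(T=T, n_steps=n_equil, stride=n_equil, seed=seed + 31 * k),
        )
        tr = run_langevin(
            t, eq.x_final,
            RunConfig(T=T, n_steps=n_steps, stride=stride,
                      seed=seed + 31 * k + 1),
            v0=eq.v_final,
        )
        trajs.append(tr)
        energies.append(tr.epot)
    thermo = wham(energies, list(temps))
    return thermo, trajs


def tf_quick(s: Structure, cm: ContactMap, state: str, seed: int = 0,
             temps=(0.9, 1.05, 1.2, 1.35), n_steps: int = 250_000,
             eps_ss: float = 1.0) -> float:
    """Cheap Tf estimate: temperature where the mean Q crosses 0.5
    (linear interpolation over a coarse scan); used to center ladders."""
    i, j = s.meta["cys_pair"]
    t = build_topology(s, cm, DisulphideBridge(i, j, state), eps_ss=eps_ss)
    means = []
    for k, T in enumerate(temps):
        tr = run_langevin(
            t, t.x_native,
            RunConfig(T=T, n_steps=n_steps, stride=1000, seed=seed + k),
        )
        q = compute_Q(tr, cm).q
        means.append(q[len(q) // 3 :].mean())
    means = np.array(means)
    temps = np.array(temps)
    if means[0] < 0.5:
        return float(temps[0])
    if means[-1] > 0.5:
        return float(temps[-1])
    k = int(np.argmax(means < 0.5))
    t0, t1 = temps[k - 1], temps[k]
    m0, m1 = means[k - 1], means[k]
    return float(t0 + (m0 - 0.5) / (m0 - m1) * (t1 - t0))
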