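"""Folding analysis: native-contact fractions, transitions, WHAM.

Q is the sharp native-contact fraction (a contact is formed when the pair
distance is below ``lam`` times its native distance, lam = 1.2 by
default); q_segment restricts the count to contacts owning at least one
endpoint inside a residue interval. WHAM (Ferrenberg-Swendsen multiple
histogram reweighting) turns energy histograms from several temperatures
into a relative density of states, specific-heat curves Cv(T), and the
folding temperature Tf at the Cv maximum; the umbrella variant recovers an
unbiased free-energy profile F(Q) from biased windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .md import Trajectory
from .sbm import ContactMap


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# native contact fractions


@dataclass
class QSeries:
    q: np.ndarray                      # (m,) in [0, 1]
    formed: np.ndarray | None = None   # (m, n_contacts) booleans, optional

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if np.any((self.q < 0) | (self.q > 1)):
            raise AnalysisError("Q out of [0, 1]")

    def __len__(self):
        return len(self.q)


def _frames_of(traj) -> np.ndarray:
    if isinstance(traj, Trajectory):
        return traj.frames
    return np.asarray(traj, dtype=float)


def contact_distances(frames, cm: ContactMap) -> np.ndarray:
    return np.linalg.norm(
        frames[:, cm.pairs[:, 0]] - frames[:, cm.pairs[:, 1]], axis=2
    )


def compute_Q(traj, cm: ContactMap, lam: float = 1.2,
              keep_formed: bool = False) -> QSeries:
    """Per-frame fraction of native contacts formed (r < lam * r0)."""
    if lam <= 1:
        raise AnalysisError("lam must exceed 1")
    if cm.n_contacts == 0:
        raise AnalysisError("empty contact map")
    frames = _frames_of(traj)
    formed = contact_distances(frames, cm) < lam * cm.r0
    return QSeries(formed.mean(axis=1), formed if keep_formed else None)


def segment_contacts(cm: ContactMap, segment: tuple) -> np.ndarray:
    """Indices of contacts with at least one endpoint inside ``segment``
    (closed interval of internal residue indices)."""
    a, b = segment
    inside = ((cm.pairs >= a) & (cm.pairs <= b)).any(axis=1)
    return np.nonzero(inside)[0]


def compute_q_segment(traj, cm: ContactMap, segment: tuple,
                      lam: float = 1.2) -> QSeries:
    """Q restricted to the contacts owned by one secondary-structure
    element (ownership = either endpoint inside the interval)."""
    idx = segment_contacts(cm, segment)
    if len(idx) == 0:
        raise AnalysisError(f"segment {segment} owns no native contacts")
    sub = ContactMap(cm.pairs[idx], cm.r0[idx])
    return compute_Q(traj, sub, lam=lam)


# ---------------------------------------------------------------------------
# transition detection


def detect_transitions(q, q_lo: float = 0.2, q_hi: float = 0.8,
                       min_dwell: int = 100, direction: str = "folding"):
    """Dwell-to-dwell passages of a Q time series.

    A folding event is a passage from a dwell of at least ``min_dwell``
    frames below ``q_lo`` to a dwell of the same length above ``q_hi``
    (symmetric for unfolding). Returns a list of (start, end) frame
    indices: the last frame of the departing dwell and the first frame of
    the arriving dwell.
    """
    if direction not in ("folding", "unfolding", "both"):
        raise AnalysisError(f"unknown direction {direction!r}")
    q = np.asarray(q.q if isinstance(q, QSeries) else q, dtype=float)
    lo = q < q_lo
    hi = q > q_hi

    def dwell_ends(mask):
        """Frames where a run of >= min_dwell True values ends."""
        run = 0
        ends = np.zeros(len(mask), dtype=bool)
        for k, m in enumerate(mask):
            run = run + 1 if m else 0
            ends[k] = run >= min_dwell
        return ends

    lo_ok = dwell_ends(lo)
    hi_ok = dwell_ends(hi)

    events = []

    def passages(src_ok, dst_ok, label):
        k = 0
        n = len(q)
        while k < n:
            if src_ok[k]:
                # leave the source dwell; look for the next completed
                # destination dwell before any new source dwell completes
                start = k
                m = k + 1
                while m < n and not src_ok[m] and not dst_ok[m]:
                    m += 1
                if m < n and dst_ok[m]:
                    events.append((start, m - min_dwell + 1, label))
                    k = m
                else:
                    k = m
            k += 1

    if direction in ("folding", "both"):
        passages(lo_ok, hi_ok, "folding")
    if direction in ("unfolding", "both"):
        passages(hi_ok, lo_ok, "unfolding")
    events.sort(key=lambda e: e[0])
    if direction == "both":
        return events
    return [(a, b) for a, b, _ in events]


# ---------------------------------------------------------------------------
# WHAM


@dataclass
class ThermoResult:
    e_centers: np.ndarray      # energy bin centers
    log_omega: np.ndarray      # relative log density of states
    T_grid: np.ndarray
    Cv: np.ndarray
    Tf: float


def wham(energies_list, temps, n_bins: int = 120, tol: float = 1e-8,
         max_iter: int = 10000, T_grid=None) -> ThermoResult:
    """Ferrenberg-Swendsen iteration over energy histograms.

    ``energies_list`` holds one array of potential-energy samples per run,
    ``temps`` the corresponding temperatures (k_B = 1). Returns the
    relative density of states and Cv(T) = (<E^2> - <E>^2) / T^2 with Tf
    at the Cv maximum.
    """
    temps = np.asarray(temps, dtype=float)
    if len(energies_list) != len(temps):
        raise AnalysisError("one temperature per energy series required")
    if len(temps) < 1:
        raise AnalysisError("need at least one run")
    allE = np.concatenate([np.asarray(e, float) for e in energies_list])
    lo, hi = allE.min(), allE.max()
    pad = 1e-9 + 1e-6 * (hi - lo)
    edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    H = np.zeros((len(temps), n_bins))
    N = np.zeros(len(temps))
    for k, e in enumerate(energies_list):
        H[k], _ = np.histogram(e, bins=edges)
        N[k] = len(e)

    # histogram-overlap sanity: consecutive (sorted by T) runs must share bins
    order = np.argsort(temps)
    occ = H > 0
    for a, b in zip(order[:-1], order[1:]):
        if not np.any(occ[a] & occ[b]):
            overlap = (occ @ occ.T).astype(int)
            raise AnalysisError(
                f"no histogram overlap between runs at T={temps[a]} and "
                f"T={temps[b]}; overlap matrix:\n{overlap}"
            )

    beta = 1.0 / temps
    Hsum = H.sum(axis=0)
    mask = Hsum > 0
    log_f = np.zeros(len(temps))          # -beta_k * F_k
    lbE = -np.outer(beta, centers)        # (K, B)

    for _ in range(max_iter):
        # log denominator per bin: log sum_k N_k exp(log_f_k - beta_k E)
        a = np.log(N)[:, None] + log_f[:, None] + lbE
        amax = a.max(axis=0)
        log_den = amax + np.log(np.exp(a - amax).sum(axis=0))
        with np.errstate(divide="ignore"):
            log_omega = np.where(mask, np.log(Hsum) - log_den, -np.inf)
        # update free energies
        b = log_omega[None, :] + lbE
        bmax = b.max(axis=1)
        new_log_f = -(bmax + np.log(np.exp(b - bmax[:, None]).sum(axis=1)))
        new_log_f -= new_log_f[0]
        if np.max(np.abs(new_log_f - log_f)) < tol:
            log_f = new_log_f
            break
        log_f = new_log_f

    a = np.log(N)[:, None] + log_f[:, None] + lbE
    amax = a.max(axis=0)
    log_den = amax + np.log(np.exp(a - amax).sum(axis=0))
    with np.errstate(divide="ignore"):
        log_omega = np.where(mask, np.log(Hsum) - log_den, -np.inf)

    if T_grid is None:
        T_grid = np.linspace(temps.min() * 0.8, temps.max() * 1.2, 220)
    T_grid = np.asarray(T_grid, dtype=float)
    Cv = np.empty_like(T_grid)
    for k, T in enumerate(T_grid):
        w = log_omega - centers / T
        w = w - w[mask].max()
        p = np.where(mask, np.exp(w), 0.0)
        p /= p.sum()
        e1 = (p * centers).sum()
        e2 = (p * centers**2).sum()
        Cv[k] = (e2 - e1 * e1) / T**2
    Tf = float(T_grid[np.argmax(Cv)])
    return ThermoResult(centers, log_omega, T_grid, Cv, Tf)


def wham_umbrella(q_list, centers_list, k_umb, T, n_bins: int = 60,
                  tol: float = 1e-8, max_iter: int = 20000):
    """Unbiased free energy F(Q) from harmonic umbrella windows.

    ``q_list`` holds the sampled reaction-coordinate values per window,
    ``centers_list`` the window centers; the bias is 0.5 k (q - qc)^2 with
    a common (or per-window) force constant ``k_umb``.

    Returns (q_centers, F) with F shifted to min 0.
    """
    K = len(q_list)
    if K != len(centers_list):
        raise AnalysisError("one center per window required")
    k_arr = np.broadcast_to(np.asarray(k_umb, float), (K,))
    allq = np.concatenate([np.asarray(q, float) for q in q_list])
    lo, hi = allq.min(), allq.max()
    pad = 1e-9 + 1e-6 * (hi - lo)
    edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    qc = 0.5 * (edges[:-1] + edges[1:])

    H = np.zeros((K, n_bins))
    N = np.zeros(K)
    for k, q in enumerate(q_list):
        H[k], _ = np.histogram(q, bins=edges)
        N[k] = len(q)
    Hsum = H.sum(axis=0)
    mask = Hsum > 0
    beta = 1.0 / T
    # bias energy of each window evaluated at each bin center
    U = 0.5 * k_arr[:, None] * (qc[None, :] - np.asarray(centers_list)[:, None]) ** 2
    lbU = -beta * U

    log_f = np.zeros(K)
    for _ in range(max_iter):
        a = np.log(N)[:, None] + log_f[:, None] + lbU
        amax = a.max(axis=0)
        log_den = amax + np.log(np.exp(a - amax).sum(axis=0))
        with np.errstate(divide="ignore"):
            log_p = np.where(mask, np.log(Hsum) - log_den, -np.inf)
        b = log_p[None, :] + lbU
        bmax = b.max(axis=1)
        new_log_f = -(bmax + np.log(np.exp(b - bmax[:, None]).sum(axis=1)))
        new_log_f -= new_log_f[0]
        if np.max(np.abs(new_log_f - log_f)) < tol:
            log_f = new_log_f
            break
        log_f = new_log_f

    a = np.log(N)[:, None] + log_f[:, None] + lbU
    amax = a.max(axis=0)
    log_den = amax + np.log(np.exp(a - amax).sum(axis=0))
    with np.errstate(divide="ignore"):
        log_p = np.where(mask, np.log(Hsum) - log_den, -np.inf)
    F = -T * log_p
    F -= F[mask].min()
    return qc[mask], F[mask]


# ---------------------------------------------------------------------------
# mechanism curves (q_segment vs Q)


@dataclass
class MechanismCurve:
    q_bins: np.ndarray          # bin centers of global Q
    mean_q_segment: np.ndarray  # mean q_segment per bin (NaN when empty)
    counts: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    segment: tuple = ()


def mechanism_curves(trajs, cm: ContactMap, segments: dict, n_bins: int = 10,
                     lam: float = 1.2, n_boot: int = 200, seed: int = 0):
    """Mean q_segment conditioned on global Q, with bootstrap CIs.

    ``segments`` maps names to residue intervals. Frames from all supplied
    trajectories are pooled.
    """
    if not isinstance(trajs, (list, tuple)):
        trajs = [trajs]
    qs = np.concatenate([compute_Q(t, cm, lam).q for t in trajs])
    edges = np.linspace(0, 1, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(qs, edges) - 1, 0, n_bins - 1)
    rng = np.random.default_rng(seed)

    out = {}
    for name, seg in segments.items():
        qseg = np.concatenate(
            [compute_q_segment(t, cm, seg, lam).q for t in trajs]
        )
        mean = np.full(n_bins, np.nan)
        lo = np.full(n_bins, np.nan)
        hi = np.full(n_bins, np.nan)
        counts = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            sel = qseg[which == b]
            counts[b] = len(sel)
            if counts[b] == 0:
                continue
            mean[b] = sel.mean()
            if counts[b] >= 4:
                boots = rng.choice(sel, size=(n_boot, counts[b])).mean(axis=1)
                lo[b], hi[b] = np.percentile(boots, [2.5, 97.5])
            else:
                lo[b] = hi[b] = mean[b]
        out[name] = MechanismCurve(centers, mean, counts, lo, hi, tuple(seg))
    return out


def curves_to_tsv(curves: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("segment\tq_bin\tmean_q_segment\tcount\tci_lo\tci_hi\n")
        for name, c in curves.items():
            for k in range(len(c.q_bins)):
                fh.write(
                    f"{name}\t{c.q_bins[k]:.3f}\t{c.mean_q_segment[k]:.4f}"
                    f"\t{c.counts[k]}\t{c.ci_lo[k]:.4f}\t{c.ci_hi[k]:.4f}\n"
                )
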