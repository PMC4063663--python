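"""C-alpha structure-based (Go-type) model.

The Hamiltonian contains harmonic bonds and angles anchored at their native
values, the standard two-term cosine dihedral, Gaussian-well native
contacts with a hard excluded-volume core, and pure (sigma/r)^12 repulsion
between all other pairs separated by at least ``min_seq_sep`` residues::

    V = sum k_b (r - r0)^2  +  sum k_a (th - th0)^2
      + sum k_d1 [1 - cos(phi - phi0)] + k_d2 [1 - cos 3(phi - phi0)]
      + sum_native eps [ (1 + (sigma/r)^12)(1 - e^{-(r-r0)^2 / 2w^2}) - 1 ]
      + sum_nonnative eps (sigma/r)^12      (truncated and shifted)

with k_b = 2e4 eps/nm^2, k_a = 40 eps/rad^2, k_d1 = eps, k_d2 = 0.5 eps and
sigma = 4 A. Every native contact contributes exactly -eps at its native
distance. Internal units: nm, epsilon, k_B = 1.

The disulphide bridge enters in one of three oxidation states:

* ``oxidized`` — an unbreakable harmonic bond at the native S-S distance;
* ``dynamic``  — a breakable Gaussian contact of depth ``eps_ss`` that can
  form and break during folding;
* ``reduced``  — excluded volume only (the pair is removed from the
  contact map entirely).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .structure import DisulphideBridge, Structure

# force-field constants (reduced units)
K_BOND = 2.0e4        # eps / nm^2
K_ANGLE = 40.0        # eps / rad^2
K_DIH_1 = 1.0         # eps
K_DIH_3 = 0.5         # eps
SIGMA_NM = 0.4        # excluded-volume diameter, 4 A
WIDTH_NM = 0.05       # Gaussian contact well width, 0.5 A
REP_CUTOFF_NM = 0.8   # repulsion truncation
NB_SKIN_NM = 0.3      # neighbor-list skin
A_TO_NM = 0.1


class SBMError(ValueError):
    pass


@dataclass
class ContactMap:
    pairs: np.ndarray   # (m, 2) int, i < j
    r0: np.ndarray      # (m,) native distances, nm

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.r0 = np.asarray(self.r0, dtype=float)
        if len(self.pairs) != len(self.r0):
            raise SBMError("pairs/r0 length mismatch")
        if np.any(self.r0 <= 0):
            raise SBMError("native distances must be positive")
        keys = set()
        for i, j in self.pairs:
            if i >= j:
                raise SBMError("contact pairs must have i < j")
            if (i, j) in keys:
                raise SBMError(f"duplicate contact {i},{j}")
            keys.add((i, j))

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)

    def without(self, i: int, j: int) -> "ContactMap":
        i, j = min(i, j), max(i, j)
        keep = ~((self.pairs[:, 0] == i) & (self.pairs[:, 1] == j))
        return ContactMap(self.pairs[keep], self.r0[keep])

    def has(self, i: int, j: int) -> bool:
        i, j = min(i, j), max(i, j)
        return bool(np.any((self.pairs[:, 0] == i) & (self.pairs[:, 1] == j)))


def build_contact_map(
    s: Structure,
    method: str = "ca_cutoff",
    cutoff: float = 8.0,
    min_seq_sep: int = 4,
    screen_radius: float = 1.0,
) -> ContactMap:
    """Native contacts from the C-alpha geometry.

    ``ca_cutoff``: all pairs with CA-CA distance below ``cutoff`` (A) and
    ``|i - j| >= min_seq_sep``. ``shadow_approx`` additionally discards a
    pair when the straight segment between the two residues passes within
    ``screen_radius`` (A) of any third residue, a light-weight stand-in for
    shadow-map screening of occluded interactions.
    """
    if cutoff <= 0:
        raise SBMError("cutoff must be positive")
    if method not in ("ca_cutoff", "shadow_approx"):
        raise SBMError(f"unknown contact method {method!r}")
    if s.chain_breaks():
        raise SBMError("structure has chain breaks; contact map undefined")
    ca = s.ca_coords
    n = len(ca)
    d = np.linalg.norm(ca[:, None] - ca[None], axis=2)
    ii, jj = np.nonzero((d < cutoff) & (np.triu(np.ones((n, n), bool), min_seq_sep)))
    pairs = np.column_stack([ii, jj])
    if method == "shadow_approx" and len(pairs):
        keep = np.ones(len(pairs), dtype=bool)
        for k, (i, j) in enumerate(pairs):
            a, b = ca[i], ca[j]
            ab = b - a
            L2 = ab @ ab
            for m in range(n):
                if m == i or m == j:
                    continue
                t = np.clip((ca[m] - a) @ ab / L2, 0.0, 1.0)
                if t <= 0.0 or t >= 1.0:
                    continue
                if np.linalg.norm(a + t * ab - ca[m]) < screen_radius:
                    keep[k] = False
                    break
        pairs = pairs[keep]
    r0 = np.linalg.norm(ca[pairs[:, 0]] - ca[pairs[:, 1]], axis=1) * A_TO_NM
    return ContactMap(pairs, r0)


@dataclass
class SBMTopology:
    """Complete parameterization of the Hamiltonian for one chain."""

    n: int
    x_native: np.ndarray            # (n, 3) nm
    bonds_idx: np.ndarray
    bonds_r0: np.ndarray
    angles_idx: np.ndarray
    angles_t0: np.ndarray
    dih_idx: np.ndarray
    dih_p0: np.ndarray
    contacts_idx: np.ndarray
    contacts_r0: np.ndarray
    contacts_eps: np.ndarray
    ss_bridge: DisulphideBridge | None = None
    k_bond: float = K_BOND
    k_angle: float = K_ANGLE
    k_dih1: float = K_DIH_1
    k_dih3: float = K_DIH_3
    sigma: float = SIGMA_NM
    width: float = WIDTH_NM
    rep_cutoff: float = REP_CUTOFF_NM
    min_seq_sep: int = 4

    @property
    def n_contacts(self) -> int:
        return len(self.contacts_idx)

    def exclusion_keys(self) -> np.ndarray:
        """Sorted i*n+j codes excluded from generic repulsion."""
        keys = [int(i) * self.n + int(j) for i, j in self.contacts_idx]
        # the disulphide bond (oxidized state) is a bonded term
        for i, j in self.bonds_idx:
            i, j = int(i), int(j)
            if j - i >= self.min_seq_sep:
                keys.append(i * self.n + j)
        return np.array(sorted(set(keys)), dtype=np.int64)

    def pack(self):
        """Arguments for the jitted kernels, in kernel order."""
        return (
            self.bonds_idx, self.bonds_r0, self.k_bond,
            self.angles_idx, self.angles_t0, self.k_angle,
            self.dih_idx, np.cos(self.dih_p0), np.sin(self.dih_p0),
            self.k_dih1, self.k_dih3,
            self.contacts_idx, self.contacts_r0, self.contacts_eps,
            self.sigma, self.width,
        )


def _native_angles(x):
    u = x[:-2] - x[1:-1]
    v = x[2:] - x[1:-1]
    c = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.arccos(np.clip(c, -1, 1))


def _native_dihedrals(x):
    b1 = x[1:-2] - x[:-3]
    b2 = x[2:-1] - x[1:-2]
    b3 = x[3:] - x[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, n2)
    s = np.einsum("ij,ij->i", m, b2 / np.linalg.norm(b2, axis=1)[:, None])
    c = np.einsum("ij,ij->i", n1, n2)
    return np.arctan2(s, c)


def build_topology(
    s: Structure,
    cm: ContactMap,
    ss: DisulphideBridge | None = None,
    eps_ss: float = 1.0,
) -> SBMTopology:
    """Assemble the Hamiltonian for one oxidation state of the bridge."""
    n = s.n_residues
    if n < 4:
        raise SBMError("need at least 4 residues")
    x = s.ca_coords * A_TO_NM
    bonds_idx = np.column_stack([np.arange(n - 1), np.arange(1, n)]).astype(np.int64)
    bonds_r0 = np.linalg.norm(np.diff(x, axis=0), axis=1)
    angles_idx = np.column_stack(
        [np.arange(n - 2), np.arange(1, n - 1), np.arange(2, n)]
    ).astype(np.int64)
    angles_t0 = _native_angles(x)
    dih_idx = np.column_stack(
        [np.arange(n - 3), np.arange(1, n - 2), np.arange(2, n - 1), np.arange(3, n)]
    ).astype(np.int64)
    dih_p0 = _native_dihedrals(x)

    cmap = cm
    if ss is not None:
        if ss.j - ss.i < 4:
            raise SBMError("disulphide pair too close in sequence for a contact")
        if s.sequence[ss.i] != "C" or s.sequence[ss.j] != "C":
            raise SBMError("disulphide residues must be cysteines")
        r_ss = float(np.linalg.norm(x[ss.j] - x[ss.i]))
        if ss.state == "oxidized":
            # unbreakable bond; the native SS contact (when present) stays
            # in the map so contact counts and Q are comparable across
            # states (reduced = oxidized - 1 when the pair is native)
            if not cm.has(ss.i, ss.j):
                cmap = ContactMap(
                    np.vstack([cm.pairs, [[ss.i, ss.j]]]),
                    np.append(cm.r0, r_ss),
                )
            bonds_idx = np.vstack([bonds_idx, [[ss.i, ss.j]]]).astype(np.int64)
            bonds_r0 = np.append(bonds_r0, r_ss)
        elif ss.state == "dynamic":
            cmap = cm.without(ss.i, ss.j)
            cmap = ContactMap(
                np.vstack([cmap.pairs, [[ss.i, ss.j]]]),
                np.append(cmap.r0, r_ss),
            )
        elif ss.state == "reduced":
            cmap = cm.without(ss.i, ss.j)

    eps = np.ones(cmap.n_contacts)
    if ss is not None and ss.state == "dynamic":
        # the appended SS contact is last
        eps[-1] = eps_ss

    return SBMTopology(
        n=n,
        x_native=x,
        bonds_idx=bonds_idx,
        bonds_r0=bonds_r0,
        angles_idx=angles_idx,
        angles_t0=angles_t0,
        dih_idx=dih_idx,
        dih_p0=dih_p0,
        contacts_idx=cmap.pairs.copy(),
        contacts_r0=cmap.r0.copy(),
        contacts_eps=eps,
        ss_bridge=ss,
    )


def _all_pairs(t: SBMTopology, x):
    """Repulsion pair list without a distance cutoff (exact evaluation)."""
    n = t.n
    excl = set(int(k) for k in t.exclusion_keys())
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + t.min_seq_sep, n)
        if i * n + j not in excl
    ]
    return np.array(pairs, dtype=np.int64).reshape(-1, 2)


def energy(t: SBMTopology, x: np.ndarray) -> dict:
    """Potential energy breakdown (eps) at coordinates ``x`` (nm)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (t.n, 3):
        raise SBMError(f"coordinates must be ({t.n}, 3)")
    d = np.linalg.norm(x[:, None] - x[None], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1e-6:
        raise SBMError("coincident particles (infinite core)")
    f = np.zeros_like(x)
    pairs = _all_pairs(t, x)
    eb, ea, ed, ec, er = _kernels.compute_forces(
        x, f, *t.pack(), pairs, len(pairs), 1.0, t.rep_cutoff
    )
    return {
        "bond": eb,
        "angle": ea,
        "dihedral": ed,
        "contact": ec,
        "repulsion": er,
        "total": eb + ea + ed + ec + er,
    }


def forces(t: SBMTopology, x: np.ndarray) -> np.ndarray:
    """Analytic forces -dV/dx (eps/nm)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (t.n, 3):
        raise SBMError(f"coordinates must be ({t.n}, 3)")
    f = np.zeros_like(x)
    pairs = _all_pairs(t, x)
    _kernels.compute_forces(x, f, *t.pack(), pairs, len(pairs), 1.0, t.rep_cutoff)
    return f


def save_topology(t: SBMTopology, path) -> None:
    """Serialize as a sectioned TSV text file."""
    with open(path, "w") as fh:
        fh.write(f"# plasso SBM topology\tn={t.n}\n")
        fh.write(
            f"# constants\tk_bond={t.k_bond}\tk_angle={t.k_angle}"
            f"\tk_dih1={t.k_dih1}\tk_dih3={t.k_dih3}"
            f"\tsigma={t.sigma}\twidth={t.width}\n"
        )
        if t.ss_bridge is not None:
            fh.write(
                f"# ss_bridge\t{t.ss_bridge.i}\t{t.ss_bridge.j}"
                f"\t{t.ss_bridge.state}\n"
            )
        fh.write("[native]\n")
        for p in t.x_native:
            fh.write(f"{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\n")
        fh.write("[bonds]\n")
        for (i, j), r0 in zip(t.bonds_idx, t.bonds_r0):
            fh.write(f"{i}\t{j}\t{r0:.6f}\n")
        fh.write("[angles]\n")
        for (i, j, k), t0 in zip(t.angles_idx, t.angles_t0):
            fh.write(f"{i}\t{j}\t{k}\t{t0:.6f}\n")
        fh.write("[dihedrals]\n")
        for (i, j, k, l), p0 in zip(t.dih_idx, t.dih_p0):
            fh.write(f"{i}\t{j}\t{k}\t{l}\t{p0:.6f}\n")
        fh.write("[contacts]\n")
        for (i, j), r0, e in zip(t.contacts_idx, t.contacts_r0, t.contacts_eps):
            fh.write(f"{i}\t{j}\t{r0:.6f}\t{e:.3f}\n")
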