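"""Langevin / NVE integration of the structure-based model.

Reduced units throughout: k_B = 1, time step ``dt`` in reduced time.
Beads carry a uniform mass of 100 — the GROMACS-style convention of
roughly one amino-acid mass in amu with energies in epsilon and lengths
in nm — which makes the conventional dt = 0.005 stable against the stiff
k_b = 2e4 eps/nm^2 bonds (bond frequency omega dt = 0.1). Temperature
control uses the BAOAB splitting of Langevin dynamics with friction
``gamma = 1 / coupling``; the coupling constant defaults to 2 reduced
time units, read as the thermostat time constant. ``gamma = 0`` (NVE)
reduces the scheme exactly to velocity Verlet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .sbm import NB_SKIN_NM, SBMTopology


class MDError(RuntimeError):
    pass


@dataclass
class RunConfig:
    T: float = 1.0              # temperature, eps
    n_steps: int = 100_000
    dt: float = 0.005           # reduced time
    coupling: float = 2.0       # Langevin time constant; gamma = 1/coupling
    stride: int = 200           # frame interval in steps
    seed: int = 0
    mass: float = 100.0         # uniform bead mass (see module docstring)

    def __post_init__(self):
        if self.dt <= 0:
            raise MDError("dt must be positive")
        if self.stride < 1:
            raise MDError("stride must be >= 1")
        if self.T < 0:
            raise MDError("temperature must be >= 0")


@dataclass
class Trajectory:
    frames: np.ndarray          # (m, n, 3) nm
    times: np.ndarray           # (m,) reduced time
    temperature: float
    epot: np.ndarray            # (m,) potential energy, bias excluded
    ekin: np.ndarray
    ebias: np.ndarray
    seed: int
    bias: tuple | None = None   # (Q_center, k_umb) when biased
    x_final: np.ndarray | None = None
    v_final: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_residues(self) -> int:
        return self.frames.shape[1]

    def etot(self) -> np.ndarray:
        return self.epot + self.ekin + self.ebias

    def save_dcd(self, path, top_structure=None) -> None:
        """Write frames as DCD (coordinates back-converted to Angstrom)."""
        import mdtraj

        n = self.n_residues
        topo = mdtraj.Topology()
        ch = topo.add_chain()
        prev = None
        for i in range(n):
            res = topo.add_residue("ALA", ch)
            at = topo.add_atom("CA", mdtraj.element.carbon, res)
            if prev is not None:
                topo.add_bond(prev, at)
            prev = at
        # mdtraj uses nm internally; our frames are already nm
        traj = mdtraj.Trajectory(self.frames.copy(), topo)
        traj.save_dcd(str(path))

    def save_log(self, path, extra: dict | None = None) -> None:
        """Per-frame TSV log (time, T, energies, optional extra columns)."""
        cols = {
            "time": self.times,
            "T_set": np.full(self.n_frames, self.temperature),
            "epot": self.epot,
            "ekin": self.ekin,
            "ebias": self.ebias,
        }
        if extra:
            cols.update(extra)
        names = list(cols)
        with open(path, "w") as fh:
            fh.write("\t".join(names) + "\n")
            for k in range(self.n_frames):
                fh.write("\t".join(f"{cols[c][k]:.6g}" for c in names) + "\n")


def _run(
    t: SBMTopology,
    x0: np.ndarray,
    cfg: RunConfig,
    gamma: float,
    v0: np.ndarray | None = None,
    k_umb: float = 0.0,
    q_center: float = 0.0,
    q_lam: float = 1.2,
    q_beta_w: float = 0.1,
) -> Trajectory:
    x = np.ascontiguousarray(x0, dtype=float).copy()
    if x.shape != (t.n, 3):
        raise MDError(f"x0 must be ({t.n}, 3)")
    if not np.all(np.isfinite(x)):
        raise MDError("x0 contains non-finite coordinates")
    rng = np.random.default_rng(cfg.seed)
    if v0 is None:
        v = rng.normal(0.0, np.sqrt(max(cfg.T, 1e-12) / cfg.mass), size=(t.n, 3))
    else:
        v = np.ascontiguousarray(v0, dtype=float).copy()

    m = cfg.n_steps // cfg.stride
    frames = np.empty((m, t.n, 3))
    epot = np.empty(m)
    ebias = np.empty(m)
    ekin = np.empty(m)
    bad = _kernels.integrate(
        x, v, cfg.n_steps, cfg.dt, gamma, cfg.T, cfg.mass,
        int(rng.integers(0, 2**31 - 1)), cfg.stride,
        *t.pack(),
        t.exclusion_keys(), 1.0, t.rep_cutoff, NB_SKIN_NM,
        k_umb, q_center, q_lam, q_beta_w,
        frames, epot, ebias, ekin,
    )
    if bad >= 0:
        raise MDError(f"integration diverged at step {bad} (non-finite energy)")
    finite = np.isfinite(epot)
    if not finite.all():
        first = int(np.argmin(finite))
        raise MDError(
            f"integration diverged at step {(first + 1) * cfg.stride} "
            f"(non-finite energy)"
        )
    times = cfg.dt * cfg.stride * np.arange(1, m + 1)
    return Trajectory(
        frames=frames,
        times=times,
        temperature=cfg.T,
        epot=epot,
        ekin=ekin,
        ebias=ebias,
        seed=cfg.seed,
        bias=(q_center, k_umb) if k_umb > 0 else None,
        x_final=x,
        v_final=v,
    )


def run_langevin(t: SBMTopology, x0, cfg: RunConfig, v0=None) -> Trajectory:
    """Production run at constant temperature ``cfg.T``."""
    return _run(t, x0, cfg, gamma=1.0 / cfg.coupling, v0=v0)


def run_nve(t: SBMTopology, x0, cfg: RunConfig, v0=None) -> Trajectory:
    """Microcanonical run (velocity Verlet); validates the integrator."""
    return _run(t, x0, cfg, gamma=0.0, v0=v0)


def run_umbrella(
    t: SBMTopology,
    x0,
    cfg: RunConfig,
    Q_center: float,
    k_umb: float,
    cm=None,
    q_lam: float = 1.2,
    v0=None,
) -> Trajectory:
    """Langevin run with a harmonic bias 0.5 k (Q_s - Q_center)^2.

    The biased coordinate is a differentiable native-contact fraction built
    from logistic switches of width 0.1 r0 at lambda r0 (the sharp-count Q
    used in analysis is unchanged). ``cm`` defaults to the topology's own
    contact list.
    """
    if not (0.0 <= Q_center <= 1.0):
        raise MDError("Q_center must lie in [0, 1]")
    if k_umb < 0:
        raise MDError("k_umb must be >= 0")
    if k_umb == 0:
        return run_langevin(t, x0, cfg, v0=v0)
    return _run(
        t, x0, cfg, gamma=1.0 / cfg.coupling, v0=v0,
        k_umb=k_umb, q_center=Q_center, q_lam=q_lam,
    )


def minimize(t: SBMTopology, x0, n_steps: int = 200, step: float = 1e-5):
    """Crude steepest-descent relaxation (clash removal before dynamics)."""
    from .sbm import forces as sbm_forces

    x = np.array(x0, dtype=float)
    for _ in range(n_steps):
        f = sbm_forces(t, x)
        mx = np.abs(f).max()
        if mx < 1e3:
            break
        x += np.clip(step * f, -0.01, 0.01)
    return x
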