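"""Integrator validation: thermostat, determinism, NVE properties."""

import dataclasses

import numpy as np
import pytest

from plasso.md import MDError, RunConfig, run_langevin, run_nve, run_umbrella
from plasso.sbm import SBMTopology, build_contact_map, build_topology
from plasso.structure import DisulphideBridge
from plasso.synth import default_spec, make_bundle
from plasso._kernels import smooth_q


def _single_bond_topology(k=200.0, r0=0.5):
    """Two beads joined by one harmonic bond (analytic reference system)."""
    x = np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]])
    e2 = np.empty((0, 2), dtype=np.int64)
    e0 = np.empty(0)
    return SBMTopology(
        n=2,
        x_native=x,
        bonds_idx=np.array([[0, 1]], dtype=np.int64),
        bonds_r0=np.array([r0]),
        angles_idx=np.empty((0, 3), dtype=np.int64),
        angles_t0=e0,
        dih_idx=np.empty((0, 4), dtype=np.int64),
        dih_p0=e0,
        contacts_idx=e2,
        contacts_r0=e0,
        contacts_eps=e0,
        k_bond=k,
    )


@pytest.fixture(scope="module")
def folded():
    s = make_bundle(default_spec("pierced_C", seed=9))
    i, j = s.meta["cys_pair"]
    cm = build_contact_map(s)
    t = build_topology(s, cm, DisulphideBridge(i, j, "oxidized"))
    return t, cm


def test_harmonic_bond_length_variance_is_boltzmann():
    """A single harmonic bond at temperature T: Var(r - r0) = T / (2 k)
    (one effective relative coordinate along the bond axis)."""
    t = _single_bond_topology(k=200.0, r0=0.5)
    T = 0.4
    tr = run_langevin(
        t, t.x_native,
        RunConfig(T=T, n_steps=400_000, dt=0.005, stride=40, seed=3),
    )
    r = np.linalg.norm(tr.frames[:, 1] - tr.frames[:, 0], axis=1)
    var = np.var(r - 0.5)
    expect = T / (2 * 200.0)
    # 3-sigma sampling envelope for the variance of ~1e4 correlated samples
    assert var == pytest.approx(expect, rel=0.25)


def test_same_seed_reproduces_bitwise(folded):
    t, _ = folded
    cfg = RunConfig(T=1.0, n_steps=20_000, stride=500, seed=77)
    tr1 = run_langevin(t, t.x_native, cfg)
    tr2 = run_langevin(t, t.x_native, cfg)
    np.testing.assert_array_equal(tr1.frames, tr2.frames)
    np.testing.assert_array_equal(tr1.epot, tr2.epot)


def test_zero_friction_limit_is_velocity_verlet(folded):
    """With gamma -> 0 (coupling -> inf) a Langevin step equals the NVE
    velocity-Verlet step exactly."""
    t, _ = folded
    v0 = np.zeros((t.n, 3))
    cfg_nve = RunConfig(T=0.5, n_steps=50, stride=1, seed=1)
    cfg_inf = RunConfig(T=0.5, n_steps=50, stride=1, seed=1, coupling=1e18)
    tr_nve = run_nve(t, t.x_native, cfg_nve, v0=v0)
    tr_inf = run_langevin(t, t.x_native, cfg_inf, v0=v0)
    np.testing.assert_allclose(tr_inf.frames, tr_nve.frames, atol=1e-12)


def test_nve_is_time_reversible(folded):
    t, _ = folded
    eq = run_langevin(t, t.x_native,
                      RunConfig(T=0.3, n_steps=5_000, stride=5_000, seed=5))
    x0, v0 = eq.x_final.copy(), eq.v_final.copy()
    fwd = run_nve(t, x0, RunConfig(T=0.3, n_steps=100, stride=100, seed=0),
                  v0=v0)
    back = run_nve(t, fwd.x_final, RunConfig(T=0.3, n_steps=100, stride=100,
                                             seed=0), v0=-fwd.v_final)
    np.testing.assert_allclose(back.x_final, x0, atol=1e-10)


def test_free_translation_conserves_energy_exactly():
    t = _single_bond_topology()
    x0 = t.x_native
    v0 = np.tile([0.01, 0.0, 0.0], (2, 1))  # rigid translation
    tr = run_nve(t, x0, RunConfig(T=0.1, n_steps=2_000, stride=100, seed=0),
                 v0=v0)
    et = tr.etot()
    np.testing.assert_allclose(et, et[0], atol=1e-12)


def test_nve_error_scales_as_dt_squared(folded):
    """Velocity Verlet is second order: the energy-fluctuation amplitude
    grows ~dt^2 (log-log slope 2 +- 0.3 over a factor-5 dt range)."""
    t, _ = folded
    eq = run_langevin(t, t.x_native,
                      RunConfig(T=0.3, n_steps=10_000, stride=10_000, seed=6))
    stds = []
    dts = (0.002, 0.005, 0.01)
    for dt in dts:
        tr = run_nve(
            t, eq.x_final,
            RunConfig(T=0.3, n_steps=int(100.0 / dt), dt=dt,
                      stride=max(1, int(0.5 / dt)), seed=0),
            v0=eq.v_final,
        )
        stds.append(tr.etot().std())
    slope = np.polyfit(np.log(dts), np.log(stds), 1)[0]
    assert slope == pytest.approx(2.0, abs=0.3)


def test_umbrella_bias_bookkeeping(folded):
    """The recorded bias energy equals 0.5 k (Q_s - Q_c)^2 recomputed from
    the stored frames."""
    t, cm = folded
    tr = run_umbrella(
        t, t.x_native, RunConfig(T=1.0, n_steps=20_000, stride=500, seed=9),
        Q_center=0.8, k_umb=500.0,
    )
    for k in range(tr.n_frames):
        qs = smooth_q(tr.frames[k], t.contacts_idx, t.contacts_r0, 1.2, 0.1)
        expect = 0.5 * 500.0 * (qs - 0.8) ** 2
        assert tr.ebias[k] == pytest.approx(expect, abs=1e-9)


def test_zero_bias_reduces_to_plain_langevin(folded):
    t, _ = folded
    cfg = RunConfig(T=1.0, n_steps=10_000, stride=500, seed=12)
    tr_plain = run_langevin(t, t.x_native, cfg)
    tr_zero = run_umbrella(t, t.x_native, cfg, Q_center=0.5, k_umb=0.0)
    np.testing.assert_array_equal(tr_plain.frames, tr_zero.frames)


def test_invalid_configs_rejected(folded):
    t, _ = folded
    with pytest.raises(MDError):
        RunConfig(dt=-0.1)
    with pytest.raises(MDError):
        RunConfig(stride=0)
    with pytest.raises(MDError):
        run_umbrella(t, t.x_native, RunConfig(), Q_center=1.5, k_umb=10.0)
    with pytest.raises(MDError):
        run_umbrella(t, t.x_native, RunConfig(), Q_center=0.5, k_umb=-1.0)


def test_divergence_is_reported_with_step(folded):
    t, _ = folded
    bad = dataclasses.replace(t, k_bond=1e12)  # hopelessly stiff
    with pytest.raises(MDError, match="step"):
        run_langevin(bad, t.x_native,
                     RunConfig(T=1.0, n_steps=5_000, stride=10, seed=1))


def test_trajectory_log_and_dcd_written(tmp_path, folded):
    t, cm = folded
    tr = run_langevin(t, t.x_native,
                      RunConfig(T=0.8, n_steps=5_000, stride=500, seed=2))
    tr.save_log(tmp_path / "run.tsv")
    header = (tmp_path / "run.tsv").read_text().splitlines()[0]
    assert header.split("\t") == ["time", "T_set", "epot", "ekin", "ebias"]
    tr.save_dcd(tmp_path / "run.dcd")
    import mdtraj

    assert (tmp_path / "run.dcd").exists()
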