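"""Hamiltonian construction and evaluation."""

import dataclasses

import numpy as np
import pytest

from plasso.sbm import (
    ContactMap,
    SBMError,
    build_contact_map,
    build_topology,
    energy,
    forces,
    save_topology,
)
from plasso.structure import DisulphideBridge, Structure
from plasso.synth import default_spec, make_bundle


@pytest.fixture(scope="module")
def fixture():
    s = make_bundle(default_spec("pierced_C", seed=9))
    i, j = s.meta["cys_pair"]
    cm = build_contact_map(s)
    return s, cm, (i, j)


# ---------------------------------------------------------------------------
# contact maps


def test_contact_map_matches_exhaustive_recount(fixture):
    s, cm, _ = fixture
    ca = s.ca_coords
    n = len(ca)
    expect = {
        (i, j)
        for i in range(n)
        for j in range(i + 4, n)
        if np.linalg.norm(ca[i] - ca[j]) < 8.0
    }
    got = {tuple(p) for p in cm.pairs}
    assert got == expect


def _serpentine():
    """Gap-free three-row serpentine: rows at y = 0, 3.5, 7."""
    pts = []
    for row, y in enumerate((0.0, 3.5, 7.0)):
        xs = [0.0, 3.8, 7.6]
        if row == 1:
            xs = xs[::-1]
        pts += [[x, y, 0.0] for x in xs]
    return Structure(np.arange(1, 10), "A" * 9, np.array(pts))


def test_pair_distance_and_separation_rules():
    s = _serpentine()
    cm = build_contact_map(s, cutoff=8.0)
    assert cm.has(1, 7)           # 7.0 A apart, separation 6
    assert not cm.has(3, 5)       # close in space but separation 2
    assert not cm.has(2, 3)       # bonded neighbors never contact


def test_shadow_screening_removes_occluded_pair():
    # serpentine: residue 4 sits exactly on the 1-7 connecting segment
    s = _serpentine()
    plain = build_contact_map(s, cutoff=8.0)
    shadow = build_contact_map(s, method="shadow_approx", cutoff=8.0)
    assert plain.has(1, 7)
    assert not shadow.has(1, 7)
    # a pair whose segment clears all third residues survives
    assert plain.has(1, 5) and shadow.has(1, 5)


def test_bad_cutoff_rejected(fixture):
    s, _, _ = fixture
    with pytest.raises(SBMError):
        build_contact_map(s, cutoff=-1.0)


# ---------------------------------------------------------------------------
# oxidation states


def test_oxidized_adds_one_bond_and_keeps_the_ss_contact(fixture):
    s, cm, (i, j) = fixture
    t = build_topology(s, cm, DisulphideBridge(i, j, "oxidized"))
    assert len(t.bonds_idx) == s.n_residues - 1 + 1
    assert tuple(t.bonds_idx[-1]) == (i, j)
    assert t.n_contacts == cm.n_contacts + (0 if cm.has(i, j) else 1)


def test_reduced_contact_count_is_oxidized_minus_ss(fixture):
    s, cm, (i, j) = fixture
    t_ox = build_topology(s, cm, DisulphideBridge(i, j, "oxidized"))
    t_red = build_topology(s, cm, DisulphideBridge(i, j, "reduced"))
    assert len(t_red.bonds_idx) == s.n_residues - 1
    assert t_red.n_contacts == t_ox.n_contacts - 1


def test_dynamic_state_matches_contact_energy_at_native(fixture):
    s, cm, (i, j) = fixture
    t_dyn = build_topology(s, cm, DisulphideBridge(i, j, "dynamic"))
    t_red = build_topology(s, cm, DisulphideBridge(i, j, "reduced"))
    e_dyn = energy(t_dyn, t_dyn.x_native)
    e_red = energy(t_red, t_red.x_native)
    # the dynamic SS contact contributes exactly -eps_ss at native
    assert e_dyn["contact"] == pytest.approx(e_red["contact"] - 1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# energies and forces


def test_native_state_energy_anchors(fixture):
    """At the native coordinates the bonded terms vanish identically and
    the contact term equals -eps per contact."""
    s, cm, (i, j) = fixture
    t = build_topology(s, cm, DisulphideBridge(i, j, "oxidized"))
    e = energy(t, t.x_native)
    assert e["bond"] == pytest.approx(0.0, abs=1e-18)
    assert e["angle"] == pytest.approx(0.0, abs=1e-18)
    assert e["dihedral"] == pytest.approx(0.0, abs=1e-12)
    assert e["contact"] == pytest.approx(-t.n_contacts, abs=1e-9)


def test_single_bond_stretch_is_harmonic(fixture):
    s, cm, (i, j) = fixture
    t = build_topology(s, cm, DisulphideBridge(i, j, "oxidized"))
    x = t.x_native.copy()
    delta = 0.013
    direction = x[1] - x[0]
    direction /= np.linalg.norm(direction)
    x[0] -= delta * direction
    e = energy(t, x)
    assert e["bond"] == pytest.approx(t.k_bond * delta**2, rel=1e-9)


def test_forces_match_finite_differences(fixture):
    s, cm, (i, j) = fixture
    t = build_topology(s, cm, DisulphideBridge(i, j, "oxidized"))
    rng = np.random.default_rng(1)
    x = t.x_native + 0.012 * rng.standard_normal((t.n, 3))
    f = forces(t, x)
    h = 1e-6
    for _ in range(30):
        a = rng.integers(0, t.n)
        d = rng.integers(0, 3)
        xp = x.copy()
        xp[a, d] += h
        xm = x.copy()
        xm[a, d] -= h
        fd = -(energy(t, xp)["total"] - energy(t, xm)["total"]) / (2 * h)
        assert f[a, d] == pytest.approx(fd, rel=1e-6, abs=1e-4)


def test_net_force_and_torque_vanish(fixture):
    s, cm, (i, j) = fixture
    t = build_topology(s, cm, DisulphideBridge(i, j, "dynamic"))
    rng = np.random.default_rng(2)
    x = t.x_native + 0.02 * rng.standard_normal((t.n, 3))
    f = forces(t, x)
    np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)
    torque = np.cross(x, f).sum(axis=0)
    np.testing.assert_allclose(torque, 0.0, atol=1e-8)


def test_energy_invariant_under_rigid_motion(fixture):
    s, cm, (i, j) = fixture
    t = build_topology(s, cm, DisulphideBridge(i, j, "oxidized"))
    rng = np.random.default_rng(3)
    x = t.x_native + 0.01 * rng.standard_normal((t.n, 3))
    e0 = energy(t, x)["total"]
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    e1 = energy(t, x @ q.T + rng.uniform(-5, 5, 3))["total"]
    assert e1 == pytest.approx(e0, abs=1e-9)


def test_contact_term_bounded_below(fixture):
    s, cm, (i, j) = fixture
    t = build_topology(s, cm, DisulphideBridge(i, j, "reduced"))
    rng = np.random.default_rng(4)
    for _ in range(10):
        x = t.x_native + 0.2 * rng.standard_normal((t.n, 3))
        assert energy(t, x)["contact"] >= -t.n_contacts - 1e-9


def test_oxidized_not_above_dynamic_at_native(fixture):
    s, cm, (i, j) = fixture
    t_ox = build_topology(s, cm, DisulphideBridge(i, j, "oxidized"))
    t_dyn = build_topology(s, cm, DisulphideBridge(i, j, "dynamic"))
    assert (energy(t_ox, t_ox.x_native)["total"]
            <= energy(t_dyn, t_dyn.x_native)["total"] + 1e-9)


def test_coincident_particles_rejected(fixture):
    s, cm, (i, j) = fixture
    t = build_topology(s, cm, DisulphideBridge(i, j, "oxidized"))
    x = t.x_native.copy()
    x[10] = x[40]
    with pytest.raises(SBMError, match="coincident"):
        energy(t, x)


def test_topology_serialization_round_trips_sections(tmp_path, fixture):
    s, cm, (i, j) = fixture
    t = build_topology(s, cm, DisulphideBridge(i, j, "oxidized"))
    path = tmp_path / "top.tsv"
    save_topology(t, path)
    text = path.read_text()
    for section in ("[native]", "[bonds]", "[angles]", "[dihedrals]",
                    "[contacts]"):
        assert section in text
    assert text.count("\n") > t.n * 3
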