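"""Q series, transition detection, WHAM and mechanism curves."""

import numpy as np
import pytest

from plasso.analysis import (
    AnalysisError,
    compute_Q,
    compute_q_segment,
    detect_transitions,
    mechanism_curves,
    segment_contacts,
    wham,
    wham_umbrella,
)
from plasso.sbm import ContactMap, build_contact_map
from plasso.synth import default_spec, make_bundle


@pytest.fixture(scope="module")
def fixture():
    s = make_bundle(default_spec("pierced_C", seed=9))
    cm = build_contact_map(s)
    return s, cm


# ---------------------------------------------------------------------------
# Q and q_segment


def test_native_frame_has_unit_Q(fixture):
    s, cm = fixture
    frames = (s.ca_coords * 0.1)[None]
    assert compute_Q(frames, cm).q[0] == 1.0


def test_extended_chain_has_negligible_Q(fixture):
    s, cm = fixture
    n = s.n_residues
    ext = np.zeros((1, n, 3))
    ext[0, :, 0] = np.arange(n) * 0.38
    assert compute_Q(ext, cm).q[0] < 0.05


def test_Q_matches_per_pair_recount(fixture):
    s, cm = fixture
    rng = np.random.default_rng(0)
    frames = (s.ca_coords * 0.1)[None] + 0.05 * rng.standard_normal((10, s.n_residues, 3))
    qs = compute_Q(frames, cm).q
    for k in range(10):
        formed = 0
        for (i, j), r0 in zip(cm.pairs, cm.r0):
            if np.linalg.norm(frames[k, i] - frames[k, j]) < 1.2 * r0:
                formed += 1
        assert qs[k] == pytest.approx(formed / cm.n_contacts)


def test_whole_chain_segment_equals_global_Q(fixture):
    s, cm = fixture
    rng = np.random.default_rng(1)
    frames = (s.ca_coords * 0.1)[None] + 0.03 * rng.standard_normal((5, s.n_residues, 3))
    qa = compute_Q(frames, cm).q
    qb = compute_q_segment(frames, cm, (0, s.n_residues - 1)).q
    np.testing.assert_allclose(qa, qb)


def test_contactless_segment_is_an_error():
    cm = ContactMap(np.array([[0, 5]]), np.array([0.8]))
    frames = np.zeros((1, 20, 3))
    frames[0, :, 0] = np.arange(20) * 0.38
    with pytest.raises(AnalysisError):
        compute_q_segment(frames, cm, (10, 14))


def test_helix_segment_matches_hand_count(fixture):
    s, cm = fixture
    a0, a1 = s.meta["segments"]["A"]
    idx = segment_contacts(cm, (a0, a1))
    hand = [
        k for k, (i, j) in enumerate(cm.pairs)
        if (a0 <= i <= a1) or (a0 <= j <= a1)
    ]
    assert list(idx) == hand
    frames = (s.ca_coords * 0.1)[None]
    assert compute_q_segment(frames, cm, (a0, a1)).q[0] == 1.0


def test_empty_contact_map_rejected():
    with pytest.raises(AnalysisError):
        compute_Q(np.zeros((1, 5, 3)),
                  ContactMap(np.empty((0, 2), int), np.empty(0)))


# ---------------------------------------------------------------------------
# transitions


def test_monotone_ramp_is_one_folding_event():
    q = np.concatenate([np.zeros(150), np.linspace(0, 1, 100), np.ones(150)])
    ev = detect_transitions(q, min_dwell=100)
    assert len(ev) == 1
    start, end = ev[0]
    assert start < end


def test_telegraph_signal_counts_all_cycles():
    cyc = np.concatenate([np.full(120, 0.05), np.full(120, 0.95)])
    q = np.tile(cyc, 5)
    fold = detect_transitions(q, min_dwell=100, direction="folding")
    unfold = detect_transitions(q, min_dwell=100, direction="unfolding")
    assert len(fold) == 5
    assert len(unfold) == 4   # the final high dwell is not left again


def test_brief_blips_are_not_events():
    q = np.full(600, 0.05)
    q[300:310] = 0.95         # shorter than min_dwell
    assert detect_transitions(q, min_dwell=100) == []


# ---------------------------------------------------------------------------
# WHAM


def test_wham_recovers_harmonic_oscillator_heat_capacity():
    """Energy samples of a 1-D harmonic oscillator at three temperatures:
    Cv = 1/2 in reduced units, recovered within 2%."""
    rng = np.random.default_rng(42)
    k = 5.0
    temps = [0.8, 1.0, 1.25]
    energies = []
    for T in temps:
        x = rng.normal(0.0, np.sqrt(T / k), size=120_000)
        energies.append(0.5 * k * x**2)
    res = wham(energies, temps, n_bins=160)
    for T in (0.85, 1.0, 1.15):
        cv = res.Cv[np.argmin(np.abs(res.T_grid - T))]
        assert cv == pytest.approx(0.5, rel=0.02)


def test_wham_invariant_to_run_order():
    rng = np.random.default_rng(7)
    k = 5.0
    temps = [0.8, 1.0, 1.25]
    energies = [0.5 * k * rng.normal(0, np.sqrt(T / k), 50_000) ** 2
                for T in temps]
    r1 = wham(energies, temps, n_bins=120)
    r2 = wham(energies[::-1], temps[::-1], n_bins=120)
    np.testing.assert_allclose(r1.Cv, r2.Cv, rtol=1e-9)
    assert r1.Tf == r2.Tf


def test_wham_refuses_disjoint_histograms():
    with pytest.raises(AnalysisError, match="overlap"):
        wham([np.full(100, 0.0), np.full(100, 1000.0)], [0.5, 2.0])


def test_umbrella_wham_recovers_quadratic_curvature():
    """Windows sampled from F(q) = a (q - q0)^2 with harmonic biases: the
    reweighted profile reproduces the curvature within 5%."""
    rng = np.random.default_rng(11)
    a, q0, T, k_umb = 40.0, 0.5, 1.0, 200.0
    centers = np.linspace(0.2, 0.8, 7)
    samples = []
    for qc in centers:
        prec = (2 * a + k_umb) / T
        mean = (2 * a * q0 + k_umb * qc) / (2 * a + k_umb)
        samples.append(rng.normal(mean, 1 / np.sqrt(prec), 40_000))
    qgrid, F = wham_umbrella(samples, centers, k_umb, T, n_bins=50)
    sel = (qgrid > 0.3) & (qgrid < 0.7)
    coef = np.polyfit(qgrid[sel], F[sel], 2)
    assert coef[0] == pytest.approx(a, rel=0.05)


# ---------------------------------------------------------------------------
# mechanism curves


def test_whole_chain_curve_sits_on_the_diagonal(fixture):
    s, cm = fixture
    rng = np.random.default_rng(3)
    base = s.ca_coords * 0.1
    frames = base[None] + np.linspace(0, 0.35, 40)[:, None, None] * \
        rng.standard_normal((40, s.n_residues, 3)) * 0.3
    curves = mechanism_curves(frames, cm, {"all": (0, s.n_residues - 1)},
                              n_bins=8)
    c = curves["all"]
    ok = ~np.isnan(c.mean_q_segment)
    np.testing.assert_allclose(c.mean_q_segment[ok], c.q_bins[ok], atol=0.07)
    assert c.counts.sum() == 40


def test_curve_counts_partition_all_frames(fixture):
    s, cm = fixture
    rng = np.random.default_rng(5)
    frames = (s.ca_coords * 0.1)[None] + 0.1 * rng.standard_normal(
        (25, s.n_residues, 3))
    curves = mechanism_curves(frames, cm, {"A": s.meta["segments"]["A"]},
                              n_bins=10)
    assert curves["A"].counts.sum() == 25
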