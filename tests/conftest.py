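"""Shared fixtures. The expensive simulation campaigns (thermodynamic
scans, threading-transition harvests, native-basin sampling) are session
scoped so several acceptance checks can share one set of runs."""

import numpy as np
import pytest

from plasso.sbm import build_contact_map
from plasso.synth import default_spec, make_bundle

THERMO_TEMPS = (0.85, 0.95, 1.05, 1.15)


@pytest.fixture(scope="session")
def bundles():
    """One default bundle per lasso kind (cached)."""
    cache = {}

    def get(kind):
        if kind not in cache:
            cache[kind] = make_bundle(default_spec(kind))
        return cache[kind]

    return get


@pytest.fixture(scope="session")
def pierced_C(bundles):
    return bundles("pierced_C")


@pytest.fixture(scope="session")
def pierced_N(bundles):
    return bundles("pierced_N")


@pytest.fixture(scope="session")
def topology_ox_C(pierced_C):
    from plasso.sbm import build_topology
    from plasso.structure import DisulphideBridge

    i, j = pierced_C.meta["cys_pair"]
    cm = build_contact_map(pierced_C)
    return build_topology(pierced_C, cm, DisulphideBridge(i, j, "oxidized")), cm


@pytest.fixture(scope="session")
def thermo_N(pierced_N):
    """Multi-temperature scans of the N-lasso fixture, both bridge states.

    Returns {state: (ThermoResult, trajs)}; shared by the stability and
    folding-order checks.
    """
    from plasso.protocols import thermo_scan

    cm = build_contact_map(pierced_N)
    out = {}
    for k, state in enumerate(("oxidized", "reduced")):
        out[state] = thermo_scan(
            pierced_N, cm, state, THERMO_TEMPS, seed=11 + k, n_steps=800_000
        )
    return out


@pytest.fixture(scope="session")
def mechanism_records(bundles):
    """>= 30 classified threading transitions per pierced fixture."""
    from plasso.protocols import threading_transitions

    out = {}
    for kind, seed in (("pierced_N", 7), ("pierced_C", 7)):
        s = bundles(kind)
        cm = build_contact_map(s)
        records, attempts = threading_transitions(
            s, cm, n_transitions=30, seed=seed
        )
        out[kind] = (records, attempts)
    return out


@pytest.fixture(scope="session")
def nsd_ensembles(bundles):
    """Replica folded-basin amplitude profiles (reduced & oxidized) for the
    NSD contrast: the redundant-bridge cinch control and the pierced
    fixture."""
    from plasso.nsd import replica_profiles
    from plasso.protocols import tf_quick
    from plasso.sbm import build_topology
    from plasso.structure import DisulphideBridge

    out = {}
    for kind, tfrac in (("cinch", 0.5), ("pierced_C", 0.55)):
        s = bundles(kind)
        i, j = s.meta["cys_pair"]
        cm = build_contact_map(s)
        tf = tf_quick(s, cm, "oxidized", seed=5)
        profs = {}
        for k2, state in enumerate(("reduced", "oxidized")):
            t = build_topology(s, cm, DisulphideBridge(i, j, state))
            profs[state] = replica_profiles(
                t, t.x_native, cm, Tf=tf, T_frac=tfrac,
                n_replicas=5, n_steps=350_000, seed=5 + 1000 * k2,
                state=state,
            )
        out[kind] = {"profiles": profs, "bridge": (i, j), "structure": s}
    return out
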