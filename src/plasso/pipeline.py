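"""End-to-end pipeline: synth -> classify -> build -> fold -> analyze.

A single plain-text config drives all stages with explicit seeds; the
output is a directory of stage artifacts plus a JSON summary that is
byte-identical on rerun with the same config.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analysis import compute_Q, mechanism_curves
from .mechanism import mechanism_stats, records_to_json
from .nsd import nsd_difference, pca_fluctuations, sample_native
from .protocols import thermo_scan, tf_quick, threading_transitions
from .sbm import build_contact_map, build_topology, save_topology
from .structure import DisulphideBridge, detect_disulphides, read_structure, write_structure
from .synth import BundleSpec, default_spec, make_bundle
from .topology import classify_lasso

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


_SCHEMA = {
    "kind": str, "helix_length": int, "loop_length": int, "seed": int,
    "pdb": str, "chain": str, "ss_state": str,
    "contact_cutoff": float, "lam": float, "eps_ss": float,
    "temps": list, "thermo_steps": int,
    "n_transitions": int, "nsd_steps": int, "t_frac": float,
    "stages": list,
}

_DEFAULTS = {
    "kind": "pierced_C",
    "seed": 0,
    "ss_state": "oxidized",
    "contact_cutoff": 8.0,
    "lam": 1.2,
    "eps_ss": 1.0,
    "temps": [0.95, 1.1, 1.25, 1.4],
    "thermo_steps": 600_000,
    "n_transitions": 5,
    "nsd_steps": 300_000,
    "t_frac": 0.7,
    "stages": ["classify", "build", "thermo"],
}


@dataclass
class PipelineConfig:
    values: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        values = dict(_DEFAULTS)
        for key, val in raw.items():
            if key not in _SCHEMA:
                raise PipelineError(f"unknown config key {key!r}")
            want = _SCHEMA[key]
            if want is float and isinstance(val, int):
                val = float(val)
            if not isinstance(val, want):
                raise PipelineError(
                    f"config key {key!r}: expected {want.__name__}, "
                    f"got {type(val).__name__}"
                )
            values[key] = val
        return cls(values)

    def __getitem__(self, key):
        return self.values[key]

    def get(self, key, default=None):
        return self.values.get(key, default)


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run the configured stages; returns (and writes) the JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": dict(sorted(cfg.values.items(), key=lambda kv: kv[0]))}
    t_start = time.time()

    def log_stage(name):
        logger.info("stage=%s seed=%s wall=%.1fs", name, cfg["seed"],
                    time.time() - t_start)

    stage = "input"
    try:
        if cfg.get("pdb"):
            s = read_structure(cfg["pdb"], chain=cfg.get("chain"))
            bridges = detect_disulphides(s)
            if not bridges:
                raise PipelineError("no disulphide bridge found in input")
            s.meta = {"cys_pair": (bridges[0].i, bridges[0].j),
                      "kind": "input", "segments": {}}
        else:
            spec_kw = {}
            if cfg.get("helix_length"):
                spec_kw["helix_length"] = cfg["helix_length"]
            if cfg.get("loop_length"):
                spec_kw["loop_length"] = cfg["loop_length"]
            if spec_kw:
                s = make_bundle(BundleSpec(lasso_kind=cfg["kind"],
                                           seed=cfg["seed"], **spec_kw))
            else:
                s = make_bundle(default_spec(cfg["kind"], seed=cfg["seed"]))
        write_structure(s, outdir / "structure.pdb")
        summary["n_residues"] = s.n_residues
        log_stage(stage)

        i, j = s.meta["cys_pair"]
        cm = build_contact_map(s, cutoff=cfg["contact_cutoff"])
        summary["n_contacts"] = cm.n_contacts

        if "classify" in cfg["stages"]:
            stage = "classify"
            cls = classify_lasso(s, DisulphideBridge(i, j))
            summary["classification"] = cls.to_dict()
            log_stage(stage)

        if "build" in cfg["stages"]:
            stage = "build"
            t = build_topology(s, cm, DisulphideBridge(i, j, cfg["ss_state"]),
                               eps_ss=cfg["eps_ss"])
            save_topology(t, outdir / "topology.tsv")
            log_stage(stage)

        if "thermo" in cfg["stages"]:
            stage = "thermo"
            tf = {}
            for state in ("oxidized", "reduced"):
                thermo, trajs = thermo_scan(
                    s, cm, state, cfg["temps"], seed=cfg["seed"],
                    n_steps=cfg["thermo_steps"],
                )
                tf[state] = thermo.Tf
                np.savetxt(
                    outdir / f"cv_{state}.tsv",
                    np.column_stack([thermo.T_grid, thermo.Cv]),
                    header="T\tCv", delimiter="\t", comments="",
                )
            summary["Tf"] = tf
            log_stage(stage)

        if "mechanism" in cfg["stages"]:
            stage = "mechanism"
            records, attempts = threading_transitions(
                s, cm, n_transitions=cfg["n_transitions"], seed=cfg["seed"],
            )
            stats = mechanism_stats(records) if records else {"n": 0}
            summary["mechanism"] = {
                "attempts": attempts,
                "stats": {
                    k: (v if not isinstance(v, dict)
                        else {kk: (list(vv) if isinstance(vv, tuple) else vv)
                              for kk, vv in v.items()})
                    for k, v in stats.items()
                },
            }
            with open(outdir / "mechanism_records.json", "w") as fh:
                json.dump(records_to_json(records), fh, indent=1)
            log_stage(stage)

        if "nsd" in cfg["stages"]:
            stage = "nsd"
            tf_est = tf_quick(s, cm, "oxidized", seed=cfg["seed"])
            profiles = {}
            for state in ("oxidized", "reduced"):
                t = build_topology(s, cm, DisulphideBridge(i, j, state))
                tr = sample_native(
                    t, t.x_native, cm, Tf=tf_est, T_frac=cfg["t_frac"],
                    n_steps=cfg["nsd_steps"], seed=cfg["seed"],
                )
                profiles[state] = pca_fluctuations(tr, state=state)
            d = nsd_difference(profiles["reduced"], profiles["oxidized"],
                               bridge=(i, j))
            summary["nsd"] = {
                "mean_abs_local": d["mean_abs_local"],
                "mean_abs_nonlocal": d["mean_abs_nonlocal"],
            }
            log_stage(stage)

    except PipelineError:
        raise
    except Exception as exc:
        cfg_hash = hash(json.dumps(summary["config"], sort_keys=True)) & 0xFFFFFFFF
        raise PipelineError(
            f"stage {stage!r} failed (config {cfg_hash:08x}): {exc}"
        ) from exc

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return round(float(obj), 10)
        if isinstance(obj, float):
            return round(obj, 10)
        return obj

    summary = _clean(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
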