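"""Serialization: parameter/fixture files (YAML), PSA result tables
(CSV), and run manifests (JSON).

The parameter file is a hierarchical YAML document whose keys mirror
the ParameterSet fields; a fixture file additionally carries the PSA
configuration and a provenance manifest.  Fixtures round-trip without
loss: ``write_fixture`` → ``read_fixture`` reproduces an equal object.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from .markov import TransitionTable
from .parameters import (
    AccuracyProfile,
    CostTable,
    Distribution,
    ParameterSet,
    PSAConfig,
    RiskProfile,
)
from .synthetic import Fixture, FixtureManifest


def _dist_to_dict(d: Distribution) -> dict:
    out = {"kind": d.kind, "low": float(d.low), "high": float(d.high)}
    if d.mode is not None:
        out["mode"] = float(d.mode)
    return out


def _dist_from_dict(d: dict) -> Distribution:
    return Distribution(d["kind"], float(d["low"]), float(d["high"]), d.get("mode"))


def _accuracy_to_dict(a: AccuracyProfile) -> dict:
    return {
        "sensitivity_by_depth": {k: float(v) for k, v in a.sensitivity_by_depth.items()},
        "specificity": float(a.specificity),
    }


def _accuracy_from_dict(d: dict) -> AccuracyProfile:
    return AccuracyProfile(
        sensitivity_by_depth={k: float(v) for k, v in d["sensitivity_by_depth"].items()},
        specificity=float(d["specificity"]),
    )


def _risk_to_dict(r: RiskProfile) -> dict:
    return {
        "label": r.label,
        "initial_state_prevalence": {k: float(v) for k, v in r.initial_state_prevalence.items()},
        "progression_multiplier": float(r.progression_multiplier),
    }


def _risk_from_dict(d: dict) -> RiskProfile:
    return RiskProfile(
        label=d["label"],
        initial_state_prevalence={
            k: float(v) for k, v in d["initial_state_prevalence"].items()
        },
        progression_multiplier=float(d["progression_multiplier"]),
    )


def parameter_set_to_dict(p: ParameterSet) -> dict:
    return {
        "transitions": dataclasses.asdict(p.transitions),
        "dentist_accuracy": _accuracy_to_dict(p.dentist_accuracy),
        "ai_accuracy": _accuracy_to_dict(p.ai_accuracy),
        "visual_tactile_accuracy": _accuracy_to_dict(p.visual_tactile_accuracy),
        "costs": dataclasses.asdict(p.costs),
        "risk": _risk_to_dict(p.risk),
        "discount_rate": float(p.discount_rate),
        "ai_training_fraction": float(p.ai_training_fraction),
        "fp_advanced_share": float(p.fp_advanced_share),
    }


def parameter_set_from_dict(d: dict) -> ParameterSet:
    return ParameterSet(
        transitions=TransitionTable(**d["transitions"]),
        dentist_accuracy=_accuracy_from_dict(d["dentist_accuracy"]),
        ai_accuracy=_accuracy_from_dict(d["ai_accuracy"]),
        visual_tactile_accuracy=_accuracy_from_dict(d["visual_tactile_accuracy"]),
        costs=CostTable(**d["costs"]),
        risk=_risk_from_dict(d["risk"]),
        discount_rate=float(d["discount_rate"]),
        ai_training_fraction=float(d["ai_training_fraction"]),
        fp_advanced_share=float(d.get("fp_advanced_share", 0.2)),
    )


def fixture_to_dict(f: Fixture) -> dict:
    cfg = f.psa_config
    return {
        "version": f.manifest.version,
        "manifest": {
            "generator_seed": f.manifest.generator_seed,
            "provenance": dict(f.manifest.provenance),
        },
        "template": parameter_set_to_dict(f.template),
        "psa": {
            "n_draws": cfg.n_draws,
            "seed": cfg.seed,
            "risk_uncertain": cfg.risk_uncertain,
            "training_fraction_uncertain": cfg.training_fraction_uncertain,
            "ai_cost_dist": _dist_to_dict(cfg.ai_cost_dist) if cfg.ai_cost_dist else None,
            "risk_profiles": {k: _risk_to_dict(v) for k, v in cfg.risk_profiles.items()},
            "transition_dists": {
                k: _dist_to_dict(v) for k, v in cfg.transition_dists.items()
            },
            "ai_accuracy_dists": {
                str(frac): {m: _dist_to_dict(d) for m, d in dists.items()}
                for frac, dists in cfg.ai_accuracy_dists.items()
            },
        },
    }


def fixture_from_dict(d: dict) -> Fixture:
    template = parameter_set_from_dict(d["template"])
    psa = d["psa"]
    cfg = PSAConfig(
        template=template,
        transition_dists={
            k: _dist_from_dict(v) for k, v in psa.get("transition_dists", {}).items()
        },
        ai_accuracy_dists={
            float(frac): {m: _dist_from_dict(dd) for m, dd in dists.items()}
            for frac, dists in psa.get("ai_accuracy_dists", {}).items()
        },
        ai_cost_dist=_dist_from_dict(psa["ai_cost_dist"]) if psa.get("ai_cost_dist") else None,
        risk_profiles={k: _risk_from_dict(v) for k, v in psa.get("risk_profiles", {}).items()},
        risk_uncertain=bool(psa.get("risk_uncertain", False)),
        training_fraction_uncertain=bool(psa.get("training_fraction_uncertain", False)),
        n_draws=int(psa.get("n_draws", 500)),
        seed=int(psa.get("seed", 0)),
    )
    manifest = FixtureManifest(
        provenance=dict(d["manifest"]["provenance"]),
        generator_seed=int(d["manifest"]["generator_seed"]),
        version=str(d.get("version", "1")),
    )
    return Fixture(template, cfg, manifest)


def write_fixture(f: Fixture, path) -> None:
    Path(path).write_text(yaml.safe_dump(fixture_to_dict(f), sort_keys=True))


def read_fixture(path) -> Fixture:
    return fixture_from_dict(yaml.safe_load(Path(path).read_text()))


def default_fixture_path() -> Path:
    return Path(__file__).parent / "fixtures" / "fixture_synthetic.yaml"


def load_default_fixture() -> Fixture:
    return read_fixture(default_fixture_path())


# -- PSA results and run manifests --


def write_psa_results(psa, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    psa.to_frame().to_csv(out / "psa_results.csv", index=False)
    psa.sampled.to_csv(out / "sampled_params.csv", index=False)


def read_psa_results(out_dir):
    from .simulate import PSAResults

    out = Path(out_dir)
    frame = pd.read_csv(out / "psa_results.csv")
    sampled = pd.read_csv(out / "sampled_params.csv")
    strategies = list(dict.fromkeys(frame["strategy"]))
    costs = frame.pivot(index="draw", columns="strategy", values="mean_cost")[strategies]
    effects = frame.pivot(index="draw", columns="strategy", values="mean_effect")[strategies]
    return PSAResults(
        strategies, costs.to_numpy(float), effects.to_numpy(float), sampled
    )


def config_hash(obj: dict) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(out_dir, seed: int, config: dict, files) -> Path:
    """Run manifest: seed, config hash, inventory — enough to reproduce
    the run byte-identically with the same build."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": sorted(str(f) for f in files),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
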