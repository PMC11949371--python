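"""Persistence: fixture bundles (YAML), tidy CSV outputs, run manifests.

All tabular artifacts are written in tidy (long) format for cross-language
consumption; every run writes a JSON manifest carrying the seed, sample
size, bundle hash and software version, which together reproduce the run
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Dict, Sequence

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationResult, TargetSpec
from .core import AnnualOutputsBatch
from .errors import ConfigError
from .fixtures import FixtureBundle
from .inputs import FixedInputs
from .space import ParameterSpace
from .strata import HEALTH_STATES, OUD_STATES, StrataConfig

_FIXED_ARRAY_FIELDS = (
    "n0", "t0", "p0", "demo_props", "arrival_oud_split", "lambda_moud",
    "lambda_detox_base", "lambda_tp", "gamma_t", "rho_t", "baseline_od",
    "beta_n", "beta_t", "beta_p")


def fixed_to_dict(fx: FixedInputs) -> dict:
    d = {"strata": fx.strata.to_dict(), "years": list(fx.years),
         "lambda_pn": float(fx.lambda_pn),
         "inj_od_ratio": float(fx.inj_od_ratio)}
    for f in _FIXED_ARRAY_FIELDS:
        d[f] = np.asarray(getattr(fx, f)).tolist()
    return d


def fixed_from_dict(d: dict) -> FixedInputs:
    try:
        kwargs = {f: np.asarray(d[f], dtype=float) for f in _FIXED_ARRAY_FIELDS}
        return FixedInputs(
            strata=StrataConfig.from_dict(d["strata"]),
            years=tuple(int(y) for y in d["years"]),
            lambda_pn=float(d["lambda_pn"]),
            inj_od_ratio=float(d["inj_od_ratio"]), **kwargs)
    except KeyError as exc:
        raise ConfigError(f"fixed-inputs file missing field {exc}") from exc


def save_bundle(bundle: FixtureBundle, path) -> None:
    """Write a fixture bundle to a directory (YAML + JSON, all text)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "fixed_inputs.yaml").write_text(
        yaml.safe_dump(fixed_to_dict(bundle.fixed), sort_keys=True))
    (path / "parameter_space.yaml").write_text(
        yaml.safe_dump(bundle.space.to_records(), sort_keys=False))
    (path / "targets.yaml").write_text(
        yaml.safe_dump([t.to_dict() for t in bundle.targets], sort_keys=False))
    (path / "observed_overdoses.yaml").write_text(
        yaml.safe_dump({int(k): float(v)
                        for k, v in bundle.observed_overdoses.items()}))
    manifest = dict(bundle.manifest)
    manifest["seed"] = bundle.seed
    (path / "bundle_manifest.json").write_text(json.dumps(manifest, indent=2))


def load_bundle(path) -> FixtureBundle:
    path = Path(path)
    if not path.is_dir():
        raise ConfigError(f"bundle directory not found: {path}")
    try:
        fixed = fixed_from_dict(
            yaml.safe_load((path / "fixed_inputs.yaml").read_text()))
        space = ParameterSpace.from_records(
            yaml.safe_load((path / "parameter_space.yaml").read_text()))
        targets = [TargetSpec.from_dict(d) for d in
                   yaml.safe_load((path / "targets.yaml").read_text())]
        observed = {int(k): float(v) for k, v in yaml.safe_load(
            (path / "observed_overdoses.yaml").read_text()).items()}
        manifest = json.loads((path / "bundle_manifest.json").read_text())
    except FileNotFoundError as exc:
        raise ConfigError(f"incomplete bundle at {path}: {exc}") from exc
    return FixtureBundle(fixed=fixed, space=space, targets=targets,
                         observed_overdoses=observed,
                         seed=int(manifest.get("seed", 0)), manifest=manifest)


def bundle_hash(path) -> str:
    """SHA-256 over the bundle files, stable across platforms."""
    path = Path(path)
    h = hashlib.sha256()
    for name in sorted(p.name for p in path.iterdir() if p.is_file()):
        h.update(name.encode())
        h.update((path / name).read_bytes())
    return h.hexdigest()


def write_outputs_csv(outputs: AnnualOutputsBatch, path) -> None:
    outputs.to_frame().to_csv(path, index=False)


def write_cohort_csv(cohort: np.ndarray, strata: StrataConfig, path) -> None:
    """Tidy snapshot of a (9, 4, J, K) occupancy tensor."""
    rows = []
    for h, hs in enumerate(HEALTH_STATES):
        for s, os_ in enumerate(OUD_STATES):
            for j, ab in enumerate(strata.age_labels):
                for k, sex in enumerate(strata.sexes):
                    rows.append({"health_state": hs, "oud_state": os_,
                                 "age_band": ab, "sex": sex,
                                 "value": float(cohort[h, s, j, k])})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_run_manifest(path, seed: int, extra: dict | None = None,
                       bundle_dir=None) -> dict:
    from . import __version__
    manifest = {"seed": int(seed), "version": __version__,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    if bundle_dir is not None:
        manifest["bundle_hash"] = bundle_hash(bundle_dir)
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def write_calibration_result(result: CalibrationResult, out_dir,
                             bundle_dir=None) -> None:
    """Accepted sets as wide CSV (one row per set, one column per scalar),
    their outputs as tidy CSV, and the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.accepted_frame.to_csv(out / "accepted_sets.csv", index=False)
    if result.accepted_outputs is not None:
        write_outputs_csv(result.accepted_outputs, out / "accepted_outputs.csv")
    result.failure_histogram().to_csv(out / "failure_histogram.csv", index=False)
    write_run_manifest(out / "run_manifest.json", result.seed,
                       extra=result.manifest(), bundle_dir=bundle_dir)
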