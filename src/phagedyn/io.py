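"""Scenario files, result writers and run manifests.

Scenario files are YAML documents with the fixed schema below; unknown keys
anywhere are rejected so that typos fail loudly instead of silently falling
back to defaults.

.. code-block:: yaml

    label: passive
    params:            # all rates in 1/day, concentrations in model units
      beta0: 5.0
      gamma: 0.0
      alpha: 0.0
      Rm: 1.0
      q: 0.2
      k1: 0.2
      k2: 1.0
      mu: 0.0
      K: 1.0
    fixed_point:       # phage-free launch point (I = P = 0 implied)
      S: 1.0
      R: 0.01
    perturbation:      # applied at t = 0; must carry phages (P > 0)
      S: 0.0
      I: 0.0
      P: 0.001
      R: 0.0
    integration:
      dt: 0.001        # day
      horizon: 7.0     # day

Results are written as one CSV (trajectory with amplitude and approximation
tracks) plus two JSON documents (spectral report, metrics) and a run
manifest.  Floats are serialized with 17 significant digits so a write/read
round trip is lossless.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .model import ModelParams, SystemState, phage_free_fixed_point
from .simulate import Scenario, ScenarioResult, Trajectory
from .spectral import jacobian

__all__ = [
    "load_scenario",
    "packaged_scenario_path",
    "packaged_scenarios",
    "write_results",
    "read_trajectory",
    "spectral_report",
]

_PARAM_KEYS = {"beta0", "gamma", "alpha", "Rm", "q", "k1", "k2", "mu", "K"}
_FLOAT_FMT = "%.17g"

CSV_COLUMNS = [
    "t", "s", "i", "p", "r",
    "A1", "A2", "A3", "A4",
    "op_s", "op_i", "op_p", "op_r",
    "dexp_i", "dexp_p",
]


def _require_mapping(doc, name: str, allowed: set[str], problems: list[str]) -> dict:
    if not isinstance(doc, dict):
        problems.append(f"section {name!r} must be a mapping")
        return {}
    unknown = set(doc) - allowed
    for key in sorted(unknown):
        problems.append(f"unknown key {key!r} in section {name!r}")
    return doc


def _numbers(doc: dict, name: str, problems: list[str]) -> dict:
    out = {}
    for key, val in doc.items():
        if isinstance(val, bool) or not isinstance(val, (int, float)):
            problems.append(f"{name}.{key} must be a number, got {val!r}")
        else:
            out[key] = float(val)
    return out


def load_scenario(path) -> Scenario:
    """Parse and fully validate a scenario file; every violation is itemized."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"scenario file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"scenario file is not valid YAML: {exc}") from exc

    problems: list[str] = []
    doc = _require_mapping(
        doc, "<root>", {"label", "params", "fixed_point", "perturbation", "integration"}, problems
    )
    label = doc.get("label", path.stem)
    if not isinstance(label, str):
        problems.append(f"label must be a string, got {label!r}")
        label = path.stem

    raw_params = _require_mapping(doc.get("params", {}), "params", _PARAM_KEYS, problems)
    raw_fp = _require_mapping(doc.get("fixed_point", {}), "fixed_point", {"S", "R"}, problems)
    raw_pert = _require_mapping(
        doc.get("perturbation", {}), "perturbation", {"S", "I", "P", "R"}, problems
    )
    raw_int = _require_mapping(
        doc.get("integration", {}), "integration", {"dt", "horizon"}, problems
    )

    params_kw = _numbers(raw_params, "params", problems)
    fp_kw = _numbers(raw_fp, "fixed_point", problems)
    pert_kw = _numbers(raw_pert, "perturbation", problems)
    int_kw = _numbers(raw_int, "integration", problems)
    if "beta0" not in params_kw:
        problems.append("params.beta0 is required")
    if "S" not in fp_kw:
        problems.append("fixed_point.S is required")
    if problems:
        raise ValidationError(f"invalid scenario file {path}", items=problems)

    try:
        params = ModelParams(**params_kw)
        fp = phage_free_fixed_point(fp_kw["S"], fp_kw.get("R", 0.0), params)
        pert = SystemState(
            pert_kw.get("S", 0.0), pert_kw.get("I", 0.0), pert_kw.get("P", 0.0),
            pert_kw.get("R", 0.0),
        )
        return Scenario(
            params=params,
            fixed_point=fp,
            perturbation=pert,
            dt=int_kw.get("dt", 0.001),
            horizon=int_kw.get("horizon", 7.0),
            label=label,
        )
    except ValidationError as exc:
        raise ValidationError(f"invalid scenario file {path}", items=exc.items) from exc


def packaged_scenarios() -> list[str]:
    """Names of the scenario files shipped with the package."""
    pkg = resources.files("phagedyn") / "scenarios"
    return sorted(p.name.removesuffix(".yaml") for p in pkg.iterdir() if p.name.endswith(".yaml"))


def packaged_scenario_path(name: str) -> Path:
    """Filesystem path of a packaged scenario (``passive`` or ``active``)."""
    path = resources.files("phagedyn") / "scenarios" / f"{name}.yaml"
    if not path.is_file():
        raise ValidationError(
            f"unknown packaged scenario {name!r}; available: {packaged_scenarios()}"
        )
    return Path(str(path))


def spectral_report(result: ScenarioResult) -> dict:
    """JSON-ready spectral summary including residual diagnostics."""
    spec = result.spectral
    J = jacobian(result.scenario.fixed_point, result.scenario.params)
    return {
        "eigenvalues": spec.lambdas.tolist(),
        "eigenvectors": {f"v{j + 1}": spec.V[:, j].tolist() for j in range(4)},
        "biorthogonal": {f"w{j + 1}": spec.W[j].tolist() for j in range(4)},
        "F0": spec.F0,
        "fst0": spec.fst0,
        "R0": spec.R0,
        "alpha_star": spec.alpha_star,
        "B": spec.B,
        "case": spec.case_label,
        "residuals": spec.residuals(J),
    }


def _trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    data = np.column_stack(
        [traj.times, traj.states, traj.amplitudes, traj.op_track, traj.dexp_track]
    )
    return pd.DataFrame(data, columns=CSV_COLUMNS)


def write_results(result: ScenarioResult, out_dir) -> dict[str, Path]:
    """Write trajectory CSV, spectral JSON, metrics JSON and the manifest.

    Returns the mapping of artifact name to path.  Refuses to write an
    empty trajectory (Trajectory construction already forbids it, so this
    guards only hand-built objects).
    """
    if len(result.trajectory.times) == 0:
        raise ValidationError("refusing to write an empty trajectory")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    paths = {
        "trajectory": out / "trajectory.csv",
        "spectral": out / "spectral.json",
        "metrics": out / "metrics.json",
        "manifest": out / "manifest.json",
    }
    _trajectory_frame(result.trajectory).to_csv(
        paths["trajectory"], index=False, float_format=_FLOAT_FMT
    )
    paths["spectral"].write_text(json.dumps(spectral_report(result), indent=2))

    metrics = {
        key: (val.tolist() if isinstance(val, np.ndarray) else val)
        for key, val in result.metrics.items()
    }
    paths["metrics"].write_text(json.dumps(metrics, indent=2))

    from . import __version__

    manifest = {
        "label": result.scenario.label,
        "params": asdict(result.scenario.params),
        "fixed_point": asdict(result.scenario.fixed_point.state),
        "perturbation": asdict(result.scenario.perturbation),
        "dt": result.scenario.dt,
        "horizon": result.scenario.horizon,
        "software": {"name": "phagedyn", "version": __version__},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def read_trajectory(path) -> pd.DataFrame:
    """Read back a trajectory CSV written by :func:`write_results`.

    Uses round-trip float parsing so the 17-significant-digit serialization
    is recovered bit-exactly.
    """
    return pd.read_csv(path, float_precision="round_trip")
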