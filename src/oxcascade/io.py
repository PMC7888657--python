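"""Configuration files, shipped defaults and provenance-stamped tabular output.

Parameter sets and run options live in declarative YAML mappings; all
tabular results are written as tab-separated text with ``#`` header
lines carrying the package version, the parameter-file SHA-256 and the
seed, so any figure built from them can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd
import yaml

from .model import ParameterSet

__all__ = [
    "load_parameters",
    "save_parameters",
    "default_parameters",
    "default_noise_sigma",
    "params_digest",
    "write_table",
    "load_config",
]


def _load_defaults_doc() -> dict:
    text = resources.files("oxcascade.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def default_parameters() -> ParameterSet:
    """The shipped calibrated parameter set."""
    return ParameterSet.from_dict(_load_defaults_doc()["parameters"])


def default_noise_sigma() -> float:
    """The shipped Langevin noise amplitude (see the stochastic module)."""
    return float(_load_defaults_doc()["noise_sigma"])


def load_parameters(path) -> ParameterSet:
    """Read a parameter set from a YAML file.

    Accepts either a bare mapping of parameter names or a document with
    a ``parameters`` section; unknown keys are rejected by name.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    payload = doc.get("parameters", doc)
    return ParameterSet.from_dict(payload)


def save_parameters(params: ParameterSet, path, noise_sigma: float | None = None) -> None:
    doc: dict = {"parameters": params.to_dict()}
    if noise_sigma is not None:
        doc["noise_sigma"] = float(noise_sigma)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def params_digest(params: ParameterSet) -> str:
    """Short stable digest of a parameter set, for output provenance lines."""
    canonical = yaml.safe_dump(params.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def write_table(
    frame: pd.DataFrame,
    path,
    params: ParameterSet | None = None,
    seed: int | None = None,
    extra: dict | None = None,
    float_format: str = "%.10g",
) -> None:
    """Write a DataFrame as tab-separated text with provenance header lines."""
    from . import __version__

    lines = [f"# oxcascade {__version__}"]
    if params is not None:
        lines.append(f"# params_sha256 {params_digest(params)}")
    if seed is not None:
        lines.append(f"# seed {seed}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k} {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=float_format)


def load_config(path, allowed_keys: set[str]) -> dict:
    """Load a YAML run config, rejecting unknown keys by name."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    unknown = set(doc) - allowed_keys
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return doc
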