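"""Tab-separated table and YAML-config I/O for the pipeline."""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import fields
from pathlib import Path

import pandas as pd
import yaml

from .experiment import LabelCalibration, LabelingExperiment, NaturalAbundance
from .simulate import PopulationSpec

__all__ = [
    "read_table",
    "write_table",
    "load_config",
    "write_manifest",
]

#: >= 6 significant digits for all floating-point table output.
FLOAT_FORMAT = "%.8g"


def read_table(path) -> pd.DataFrame:
    """Read a tab-separated table with a header row; '#' lines are comments."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path, header_comments: list[str] | None = None) -> None:
    """Write a tab-separated table, optionally preceded by '#' comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _build(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} config keys: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path) -> dict:
    """Load a YAML config into experiment / calibration / population objects.

    Recognized top-level sections: ``experiment``, ``calibration``,
    ``natural_abundance``, ``population`` — each a mapping of the dataclass
    fields of :class:`LabelingExperiment`, :class:`LabelCalibration`,
    :class:`NaturalAbundance`, :class:`PopulationSpec`.  Missing sections
    fall back to defaults.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    return {
        "experiment": _build(LabelingExperiment, raw.get("experiment", {})),
        "calibration": _build(LabelCalibration, raw.get("calibration", {})),
        "natural_abundance": _build(NaturalAbundance, raw.get("natural_abundance", {})),
        "population": _build(PopulationSpec, raw.get("population", {})),
    }


def write_manifest(out_dir, seed, config_path=None, extra: dict | None = None) -> Path:
    """Write a machine-readable run manifest (seed, config hash, versions)."""
    import numpy
    import scipy

    from . import __version__

    config_hash = None
    if config_path is not None:
        config_hash = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    manifest = {
        "seed": seed,
        "config": str(config_path) if config_path else None,
        "config_sha256": config_hash,
        "python": sys.version.split()[0],
        "isocell": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
    }
    manifest.update(extra or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
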