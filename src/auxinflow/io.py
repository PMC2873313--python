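"""Output schemas and reproducibility plumbing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .config import RunConfig

__all__ = ["write_trajectory_csv", "write_json_report", "write_manifest",
           "config_hash"]

_CSV_COLUMNS = ["time_s", "compartment", "statistic", "value"]


def config_hash(cfg: RunConfig) -> str:
    canon = yaml.safe_dump(asdict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_trajectory_csv(frame, out_dir, name: str) -> Path:
    """Tidy trajectory/ensemble CSV with the fixed column order
    time_s, compartment, statistic, value."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.csv"
    frame[_CSV_COLUMNS].to_csv(path, index=False, float_format="%.10g")
    return path


def write_json_report(report: dict, out_dir, name: str) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path


def write_manifest(cfg: RunConfig, out_dir, command: str, seeds=None) -> Path:
    """Deterministic provenance record: one manifest per output directory.

    Contains no timestamps, so a given configuration and base seed determine
    every output byte.
    """
    from . import __version__
    manifest = {
        "command": command,
        "config_hash": config_hash(cfg),
        "config": asdict(cfg),
        "package_version": __version__,
        "seeds": list(map(int, seeds)) if seeds is not None else None,
    }
    return write_json_report(manifest, out_dir, "manifest")
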