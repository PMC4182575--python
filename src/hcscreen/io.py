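"""Tabular formats and run configuration.

All tables are UTF-8 comma-separated files with a header row.  Writers may
prepend ``#``-prefixed metadata lines (config hash, seed); readers skip
them.  Readers reject unknown columns unless ``lax=True``.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .scoring import ROLES, WELL_COLUMNS

__all__ = [
    "PlateMapError",
    "read_plate_map",
    "write_plate_map",
    "read_wells_csv",
    "write_table",
    "read_table",
    "RunConfig",
    "load_config",
    "config_hash",
]

WELL_ID_RE = re.compile(r"^[A-P]\d{2}$")

PLATE_MAP_COLUMNS = ["plate_id", "well_id", "role", "shrna_id", "gene_id"]


class PlateMapError(ValueError):
    """Plate map fails schema validation; message lists offending lines."""


def _read_csv(
    path: str | Path,
    required: list[str],
    lax: bool,
    optional: list[str] = (),
) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    unknown = [c for c in df.columns if c not in required and c not in optional]
    if unknown and not lax:
        raise ValueError(f"{path}: unknown columns {unknown} (pass lax=True to keep)")
    return df


def read_plate_map(path: str | Path, lax: bool = False) -> pd.DataFrame:
    """Read and validate a plate map (plate_id, well_id, role, shrna_id, gene_id).

    Well ids are letter + two-digit column ("B07").  (plate_id, well_id)
    must be unique, roles valid, and every test well must carry both a
    hairpin and a gene id.  Violations raise :class:`PlateMapError` naming
    1-based data line numbers.
    """
    df = _read_csv(path, PLATE_MAP_COLUMNS, lax)
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if not WELL_ID_RE.match(row.well_id):
            problems.append(f"line {i}: malformed well_id {row.well_id!r}")
        if row.role not in ROLES:
            problems.append(f"line {i}: unknown role {row.role!r}")
        if row.role == "test" and (not row.shrna_id or not row.gene_id):
            problems.append(f"line {i}: test well lacks shrna_id/gene_id")
    dup = df.duplicated(subset=["plate_id", "well_id"])
    for i in dup[dup].index:
        problems.append(
            f"line {i + 1}: duplicate (plate_id, well_id) "
            f"({df.at[i, 'plate_id']}, {df.at[i, 'well_id']})"
        )
    if problems:
        raise PlateMapError("invalid plate map:\n" + "\n".join(problems))
    return df


def write_plate_map(plate_map: pd.DataFrame, path: str | Path) -> None:
    plate_map[PLATE_MAP_COLUMNS].to_csv(path, index=False)


def read_wells_csv(path: str | Path, lax: bool = False) -> pd.DataFrame:
    """Read a per-well measurement table with numeric efficiency/cell_count."""
    df = _read_csv(path, WELL_COLUMNS, lax, optional=["valid"])
    df["efficiency"] = pd.to_numeric(df["efficiency"], errors="coerce")
    df["cell_count"] = pd.to_numeric(df["cell_count"], errors="coerce")
    if "valid" in df.columns:
        df["valid"] = df["valid"].astype(str).str.lower().isin(("true", "1"))
    return df


def write_table(
    df: pd.DataFrame, path: str | Path, metadata: Mapping[str, Any] | None = None
) -> None:
    """Write a CSV with optional ``# key: value`` metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, inferring dtypes."""
    return pd.read_csv(path, comment="#")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    Exactly one input source must be set: ``wells_csv`` (pre-computed
    per-well efficiencies), ``design`` (imageless screen simulation
    parameters, see :class:`hcscreen.simulate.ScreenDesign`), or
    ``images_dir`` + ``plate_map`` (segment fields and aggregate wells).
    """

    seed: int = 0
    out_dir: str = "results"
    wells_csv: str | None = None
    design: dict[str, Any] | None = None
    images_dir: str | None = None
    plate_map: str | None = None
    n_fields: int = 6
    hit_params: dict[str, Any] = field(default_factory=dict)
    seg_params: dict[str, Any] = field(default_factory=dict)
    expression_csv: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        sources = [
            self.wells_csv is not None,
            self.design is not None,
            self.images_dir is not None,
        ]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one of wells_csv, design, images_dir must be set"
            )
        if self.images_dir is not None and self.plate_map is None:
            raise ValueError("images_dir requires plate_map")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or JSON, rejecting unknown keys."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the analytic configuration, for output provenance.

    Output location and log level do not affect the results and are left out
    of the hash, so the same analysis written elsewhere hashes identically.
    """
    payload = asdict(config)
    payload.pop("out_dir", None)
    payload.pop("log_level", None)
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
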