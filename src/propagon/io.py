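"""Tabular I/O, run configuration and result serialization.

All tables are delimited text (TSV by default, CSV accepted), UTF-8,
'.' decimal.  Fractions are stored as 0-1 decimals; a ``soluble_percent``
column is accepted and converted explicitly.  Parsers reject malformed input
with the offending file and line rather than coercing it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import SolubleMeasurement

__all__ = [
    "ParseError",
    "RunConfig",
    "read_soluble_table",
    "write_soluble_table",
    "read_propagon_table",
    "write_propagon_table",
    "write_results",
]


class ParseError(ValueError):
    """Malformed table input, pointing at file and line."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: str | Path, required: list[str], optional: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimiter structure etc.
        raise ParseError(f"{path}: cannot parse table: {exc}") from exc
    missing = [c for c in required if c not in df.columns and c not in optional]
    have_alt = all(
        c in df.columns or any(a in df.columns for a in optional) for c in required
    )
    if missing and not have_alt:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_soluble_table(path: str | Path) -> list[SolubleMeasurement]:
    """Read (strain, replicate, soluble_fraction) rows grouped by strain.

    A ``soluble_percent`` column (0-100) is accepted in place of
    ``soluble_fraction`` and converted by an explicit /100.
    """
    path = Path(path)
    df = _read_table(path, ["strain", "soluble_fraction"], ["soluble_percent"])
    if "strain" not in df.columns:
        raise ParseError(f"{path}: missing required column 'strain'")
    percent = "soluble_fraction" not in df.columns
    col = "soluble_percent" if percent else "soluble_fraction"
    if col not in df.columns:
        raise ParseError(
            f"{path}: need a 'soluble_fraction' or 'soluble_percent' column"
        )
    groups: dict[str, list[float]] = {}
    order: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        raw = row[col]
        try:
            val = float(raw)
        except (TypeError, ValueError):
            raise ParseError(f"{path}: line {line}: non-numeric {col} {raw!r}")
        if percent:
            val /= 100.0
        if not (0.0 < val <= 1.0):
            raise ParseError(
                f"{path}: line {line}: soluble fraction {val:.6g} outside (0, 1]"
            )
        strain = str(row["strain"])
        if strain not in groups:
            groups[strain] = []
            order.append(strain)
        groups[strain].append(val)
    return [SolubleMeasurement(strain=s, replicates=tuple(groups[s])) for s in order]


def write_soluble_table(
    measurements: list[SolubleMeasurement], path: str | Path
) -> None:
    path = Path(path)
    rows = [
        (m.strain, i + 1, repr(f))
        for m in measurements
        for i, f in enumerate(m.replicates)
    ]
    df = pd.DataFrame(rows, columns=["strain", "replicate", "soluble_fraction"])
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_propagon_table(path: str | Path) -> pd.DataFrame:
    """Read (strain, time_min, cell_id, propagons), validated and sorted."""
    path = Path(path)
    df = _read_table(path, ["strain", "time_min", "cell_id", "propagons"], [])
    out_rows = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            t = float(row["time_min"])
            cell = int(row["cell_id"])
            raw = float(row["propagons"])
        except (TypeError, ValueError):
            raise ParseError(f"{path}: line {line}: non-numeric field in {dict(row)}")
        if raw < 0 or raw != int(raw):
            raise ParseError(
                f"{path}: line {line}: propagons must be a non-negative "
                f"integer, got {row['propagons']!r}"
            )
        out_rows.append((str(row["strain"]), t, cell, int(raw)))
    out = pd.DataFrame(out_rows, columns=["strain", "time_min", "cell_id", "propagons"])
    return out.sort_values(["strain", "time_min", "cell_id"]).reset_index(drop=True)


def write_propagon_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    need = ["strain", "time_min", "cell_id", "propagons"]
    if list(df.columns) != need:
        raise ValueError(f"propagon table must have columns {need}")
    df.to_csv(path, sep=_sep_for(path), index=False)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; every tunable is echoed into results headers."""

    alpha: float = 700.0
    beta: float = 0.4 / 1400.0
    n0: int = 4
    n_boot: int = 10_000
    ci_level: float = 0.95
    bootstrap_method: str = "studentized"
    p_keep: float = 0.5
    n_cells: int = 1200
    curing_min: float = 420.0
    recovery_min: float = 480.0
    seed: int = 0
    noise_sd: float = 0.01
    n_reps: int = 6

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            if path.suffix.lower() == ".json":
                data = json.load(fh)
            else:
                data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ParseError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ParseError(f"{path}: unknown config key(s) {unknown}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_results(payload: dict, config: RunConfig, path: str | Path) -> None:
    """Write a results JSON with a provenance header (version, config, seed)."""
    from . import __version__

    doc = {
        "header": {
            "package": "propagon",
            "version": __version__,
            "config_hash": config.config_hash,
            "config": config.to_dict(),
            "seed": config.seed,
        },
        "results": payload,
    }

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(doc, indent=2, default=default) + "\n")
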