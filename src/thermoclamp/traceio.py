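"""Dataset format: a directory of tab-separated sweep files plus a manifest.

Layout::

    dataset/
      manifest.json          # format version, preset snapshot, seed, cell table
      sweeps/<sweep_id>.tsv  # '#'-prefixed header lines, then 3 data columns

Numbers are serialized with 9 significant digits, which bounds round-trip
error well below every analysis tolerance. The format is plain text for
diffability and language neutrality. Units are fixed: ms, mV, pA, °C, pF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import ConditionPreset, preset_from_toml, preset_to_toml

__all__ = [
    "SweepRecord",
    "DatasetManifest",
    "TraceFormatError",
    "write_dataset",
    "read_dataset",
    "validate_dataset",
    "FORMAT_VERSION",
]

FORMAT_VERSION = "1.0"
_NUM_FMT = "%.9g"
_DT_RTOL = 1e-3  # on time-base uniformity; must absorb 9-sig-digit rounding


class TraceFormatError(ValueError):
    """Malformed sweep file or manifest; message names the offending file."""


@dataclass
class SweepRecord:
    """One stimulus epoch: sampled current and command voltage on a uniform timebase."""

    sweep_id: str
    cell_id: str
    condition: str
    protocol: str  # "step" | "ramp"
    step_level_mv: float | None
    temperature_c: float
    dt_ms: float
    time_ms: np.ndarray
    command_mv: np.ndarray
    current_pa: np.ndarray
    is_baseline: bool = False
    cm_pf: float | None = None
    meta: dict = field(default_factory=dict)

    def validate(self) -> list[str]:
        """Invariant violations as human-readable strings (empty = valid)."""
        out = []
        n = len(self.time_ms)
        if not (len(self.command_mv) == n and len(self.current_pa) == n):
            out.append(f"{self.sweep_id}: column lengths differ")
            return out
        if n < 2:
            out.append(f"{self.sweep_id}: fewer than 2 samples")
            return out
        if self.time_ms[0] != 0:
            out.append(f"{self.sweep_id}: time does not start at 0")
        dt = np.diff(self.time_ms)
        if np.any(dt <= 0):
            out.append(f"{self.sweep_id}: time not strictly increasing")
        elif np.max(np.abs(dt - self.dt_ms)) > _DT_RTOL * self.dt_ms:
            out.append(f"{self.sweep_id}: non-uniform sample interval")
        if self.protocol not in ("step", "ramp"):
            out.append(f"{self.sweep_id}: unknown protocol {self.protocol!r}")
        if self.protocol == "step" and self.step_level_mv is None:
            out.append(f"{self.sweep_id}: step sweep without step_level_mv")
        return out

    def copy_with_current(self, current_pa: np.ndarray) -> "SweepRecord":
        return SweepRecord(
            sweep_id=self.sweep_id, cell_id=self.cell_id, condition=self.condition,
            protocol=self.protocol, step_level_mv=self.step_level_mv,
            temperature_c=self.temperature_c, dt_ms=self.dt_ms,
            time_ms=self.time_ms, command_mv=self.command_mv,
            current_pa=np.asarray(current_pa, dtype=float),
            is_baseline=self.is_baseline, cm_pf=self.cm_pf, meta=dict(self.meta),
        )


@dataclass
class DatasetManifest:
    """Dataset-level metadata: preset snapshot, seed, and the per-cell table."""

    preset_name: str
    preset: ConditionPreset | None
    seed: int
    cells: list[dict]
    notes: dict = field(default_factory=dict)
    format_version: str = FORMAT_VERSION
    sweep_files: list[str] = field(default_factory=list)

    def validate(self) -> list[str]:
        out = []
        for c in self.cells:
            if c.get("cm_pf", 0) <= 0:
                out.append(f"manifest: cell {c.get('cell_id')} has cm_pf <= 0")
        return out

    def cm_for(self, cell_id: str) -> float:
        for c in self.cells:
            if c["cell_id"] == cell_id:
                return float(c["cm_pf"])
        raise KeyError(f"cell {cell_id!r} not in manifest")


_META_KEYS = ("sweep_id", "cell_id", "condition", "protocol", "step_level_mv",
              "temperature_c", "dt_ms", "is_baseline", "cm_pf")


def _sweep_text(sweep: SweepRecord) -> str:
    lines = []
    for key in _META_KEYS:
        val = getattr(sweep, key)
        if val is None:
            val = "none"
        elif isinstance(val, bool):
            val = int(val)
        elif isinstance(val, float):
            val = _NUM_FMT % val
        lines.append(f"# {key}: {val}")
    for key in sorted(sweep.meta):
        val = sweep.meta[key]
        if isinstance(val, float):
            val = _NUM_FMT % val
        lines.append(f"# meta.{key}: {val}")
    lines.append("time_ms\tcommand_mv\tcurrent_pa")
    cols = np.column_stack([sweep.time_ms, sweep.command_mv, sweep.current_pa])
    for row in cols:
        lines.append("\t".join(_NUM_FMT % x for x in row))
    return "\n".join(lines) + "\n"


def write_dataset(sweeps, manifest: DatasetManifest, path, overwrite: bool = False
                  ) -> Path:
    """Write sweeps + manifest; refuses an existing non-empty directory.

    Any invariant violation aborts before the first file is written.
    """
    path = Path(path)
    problems = list(manifest.validate())
    for sw in sweeps:
        problems += sw.validate()
    if problems:
        raise TraceFormatError("; ".join(problems))
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise FileExistsError(f"{path} exists and is not empty (use overwrite)")
    sweep_dir = path / "sweeps"
    sweep_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for sw in sorted(sweeps, key=lambda s: s.sweep_id):
        fname = f"{sw.sweep_id}.tsv"
        (sweep_dir / fname).write_text(_sweep_text(sw), encoding="utf-8")
        files.append(f"sweeps/{fname}")
    doc = {
        "format_version": manifest.format_version,
        "preset_name": manifest.preset_name,
        "preset_toml": preset_to_toml(manifest.preset) if manifest.preset else None,
        "seed": manifest.seed,
        "cells": manifest.cells,
        "notes": manifest.notes,
        "sweep_files": files,
    }
    (path / "manifest.json").write_text(
        json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8"
    )
    return path


def _parse_header_value(key: str, raw: str, fname: str):
    raw = raw.strip()
    if key in ("sweep_id", "cell_id", "condition", "protocol"):
        return raw
    if key == "is_baseline":
        return bool(int(raw))
    if raw == "none":
        return None
    try:
        return float(raw)
    except ValueError as e:
        raise TraceFormatError(f"{fname}: bad header value {key}={raw!r}") from e


def _read_sweep(fpath: Path) -> SweepRecord:
    fname = fpath.name
    header: dict = {}
    meta: dict = {}
    rows = []
    saw_columns = False
    with open(fpath, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" not in body:
                    raise TraceFormatError(f"{fname}:{lineno}: malformed header line")
                key, raw = body.split(":", 1)
                key = key.strip()
                if key.startswith("meta."):
                    meta[key[5:]] = _parse_header_value(key, raw, fname)
                else:
                    header[key] = _parse_header_value(key, raw, fname)
            elif not saw_columns:
                cols = line.split("\t")
                if cols != ["time_ms", "command_mv", "current_pa"]:
                    raise TraceFormatError(
                        f"{fname}:{lineno}: expected columns "
                        f"time_ms/command_mv/current_pa, got {cols}"
                    )
                saw_columns = True
            else:
                parts = line.split("\t")
                if len(parts) != 3:
                    raise TraceFormatError(
                        f"{fname}:{lineno}: expected 3 columns, got {len(parts)}"
                    )
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as e:
                    raise TraceFormatError(
                        f"{fname}:{lineno}: non-numeric value"
                    ) from e
    missing = [k for k in _META_KEYS if k not in header]
    if missing:
        raise TraceFormatError(f"{fname}: missing header keys {missing}")
    if not rows:
        raise TraceFormatError(f"{fname}: no data rows")
    arr = np.array(rows, dtype=float)
    sweep = SweepRecord(
        sweep_id=header["sweep_id"], cell_id=header["cell_id"],
        condition=header["condition"], protocol=header["protocol"],
        step_level_mv=header["step_level_mv"],
        temperature_c=header["temperature_c"], dt_ms=header["dt_ms"],
        time_ms=arr[:, 0], command_mv=arr[:, 1], current_pa=arr[:, 2],
        is_baseline=header["is_baseline"], cm_pf=header["cm_pf"], meta=meta,
    )
    problems = sweep.validate()
    if problems:
        raise TraceFormatError(f"{fname}: " + "; ".join(problems))
    return sweep


def read_dataset(path) -> tuple[list[SweepRecord], DatasetManifest]:
    """Read a dataset directory back; unknown sweep header keys are preserved."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise TraceFormatError(f"{mpath}: manifest not found")
    doc = json.loads(mpath.read_text(encoding="utf-8"))
    preset = preset_from_toml(doc["preset_toml"]) if doc.get("preset_toml") else None
    manifest = DatasetManifest(
        preset_name=doc["preset_name"], preset=preset, seed=int(doc["seed"]),
        cells=doc["cells"], notes=doc.get("notes", {}),
        format_version=doc.get("format_version", "?"),
        sweep_files=doc.get("sweep_files", []),
    )
    problems = manifest.validate()
    if problems:
        raise TraceFormatError("; ".join(problems))
    sweeps = []
    for rel in manifest.sweep_files:
        fpath = path / rel
        if not fpath.exists():
            raise TraceFormatError(f"{rel}: referenced by manifest but missing")
        sweeps.append(_read_sweep(fpath))
    return sweeps, manifest


def validate_dataset(path) -> list[str]:
    """Structural violations as data (empty list iff the dataset is valid)."""
    path = Path(path)
    try:
        sweeps, manifest = read_dataset(path)
    except (TraceFormatError, OSError, json.JSONDecodeError, KeyError) as e:
        return [str(e)]
    out = manifest.validate()
    for sw in sweeps:
        out += sw.validate()
    return out
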