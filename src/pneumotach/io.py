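"""Readers/writers for the signal CSV dialect, JSON reports, and run config.

CSV dialect: UTF-8, header ``time_s,value``, decimal point ``.``, comment
lines starting with ``#`` (an optional ``# units: <u>`` comment carries the
unit). Readers validate strict time monotonicity and finiteness and cite
the offending line number on failure — calibration results are only as
trustworthy as the signals behind them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import yaml

from .errors import InputError, ParseError
from .signals import FlowSignal, PressureSignal, Signal

__all__ = ["RunConfig", "read_signal", "write_signal", "write_report"]

try:
    __version__ = version("pneumotach")
except PackageNotFoundError:  # pragma: no cover - not installed
    __version__ = "unknown"

_HEADER = "time_s,value"
_KINDS = {"pressure": PressureSignal, "flow": FlowSignal, None: Signal}


def read_signal(path: str | Path, expected_kind: str | None = None) -> Signal:
    """Read a signal CSV, returning a validated Pressure/Flow/plain Signal.

    ``expected_kind`` of ``"pressure"`` or ``"flow"`` selects the typed
    container and cross-checks any ``# units:`` comment in the file.
    """
    if expected_kind not in _KINDS:
        raise InputError("expected_kind must be 'pressure', 'flow' or None")
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    units = None
    header_seen = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("units:"):
                    units = body.split(":", 1)[1].strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != _HEADER:
                    raise ParseError(
                        f"{path}:{lineno}: expected header '{_HEADER}', got '{line}'"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric field") from None
            if not (math.isfinite(t) and math.isfinite(v)):
                raise ParseError(f"{path}:{lineno}: non-finite value")
            if times:
                if t == times[-1]:
                    raise ParseError(f"{path}:{lineno}: duplicate timestamp {t}")
                if t < times[-1]:
                    raise ParseError(f"{path}:{lineno}: time not increasing ({t})")
            times.append(t)
            values.append(v)
    if not header_seen:
        raise ParseError(f"{path}: missing header '{_HEADER}'")
    if len(times) < 2:
        raise InputError(f"{path}: empty or single-sample data section")
    cls = _KINDS[expected_kind]
    sig = cls(t=np.array(times), y=np.array(values), meta={"source": str(path)})
    if units is not None and expected_kind is not None and units != sig.units:
        raise ParseError(
            f"{path}: unit mismatch: file says '{units}', expected '{sig.units}'"
        )
    return sig


def write_signal(signal: Signal, path: str | Path) -> None:
    """Write a signal in the CSV dialect (full float precision, lossless)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if signal.units:
            fh.write(f"# units: {signal.units}\n")
        fh.write(_HEADER + "\n")
        for t, v in zip(signal.t, signal.y):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def _jsonable(obj):
    """Recursively convert results (dataclasses, numpy, enums) to JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
        return obj.value  # enums
    return obj


def write_report(result, path: str | Path, config: "RunConfig | None" = None) -> None:
    """Write a deterministic, key-sorted JSON report.

    Includes the tool version and, when a config is given, a hash of it so
    a report can be traced back to the exact settings that produced it.
    Writing the same result twice yields byte-identical files.
    """
    payload = {
        "result": _jsonable(result),
        "tool_version": __version__,
    }
    if config is not None:
        payload["config_hash"] = config.digest()
        payload["seed"] = config.seed
    text = json.dumps(payload, sort_keys=True, indent=2)
    Path(path).write_text(text + "\n", encoding="utf-8")


@dataclass
class RunConfig:
    """All defaulted knobs of a pipeline run, serializable to one YAML file."""

    # solver
    rel_tol: float = 1e-10
    bracket_tol: float = 1e-12
    condition_threshold: float = 1e3
    # preprocessing
    auto_offset: bool = False
    baseline_window: float = 1.0
    noise_floor: float = 0.0
    # breath detection
    breath_threshold: float = 0.05
    min_breath_duration: float = 0.1
    # sensor defaults
    sample_rate: float = 200.0
    noise_sd: float = 0.01
    offset: float = 0.02
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
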