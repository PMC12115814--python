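"""Time-series and configuration file formats.

1-D records travel as two-column CSV with header ``t,v``; run
configurations and reports as JSON (complex numbers as [re, im] pairs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .memory import MemoryConstants
from .riemann import Characteristics, PeriodMatrix
from .solitons import PinchPulse, SolitonTrain, TimeSeries

__all__ = [
    "ParseError",
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "read_train",
    "write_train",
    "complex_to_json",
    "json_to_complex",
    "characteristics_to_json",
    "characteristics_from_json",
    "period_matrix_to_json",
    "period_matrix_from_json",
]


class ParseError(ValueError):
    """Malformed input file; carries the first offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass
class RunConfig:
    """Pipeline configuration: constants overrides, band scales and seeds."""

    constants: MemoryConstants = field(default_factory=MemoryConstants)
    base_frequency: float = 1.0
    base_amplitude: float = 200.0
    dihedral_n: int = 20
    seed: int = 0
    n_pulses: int = 3
    W: int = 5

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        consts = MemoryConstants(**raw.pop("constants", {}))
        return cls(constants=consts, **raw)


def read_timeseries(path) -> TimeSeries:
    """Read a ``t,v`` CSV into a validated TimeSeries.

    Raises ParseError naming the first offending line for empty files,
    ragged rows, non-numeric cells or non-monotone time.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ParseError("empty file", line=1)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # ragged rows etc.
        raise ParseError(f"cannot parse CSV: {exc}") from exc
    if list(df.columns[:2]) != ["t", "v"]:
        raise ParseError(f"expected header 't,v', got {list(df.columns)}", line=1)
    t = pd.to_numeric(df["t"], errors="coerce").to_numpy()
    v = pd.to_numeric(df["v"], errors="coerce").to_numpy()
    bad = np.flatnonzero(np.isnan(t) | np.isnan(v))
    if bad.size:
        raise ParseError("non-numeric value", line=int(bad[0]) + 2)
    dec = np.flatnonzero(np.diff(t) <= 0)
    if dec.size:
        raise ParseError("time not strictly increasing", line=int(dec[0]) + 3)
    return TimeSeries(t, v, {"source": str(path)})


def write_timeseries(series: TimeSeries, path) -> None:
    pd.DataFrame({"t": series.t, "v": series.v}).to_csv(path, index=False)


def read_train(path) -> SolitonTrain:
    """Load a pulse-spec JSON: {"pulses": [{"a":..,"b":..,"c":..,"V0":..,"W":..}, ...]}."""
    raw = json.loads(Path(path).read_text())
    return SolitonTrain([PinchPulse(**p) for p in raw["pulses"]])


def write_train(train: SolitonTrain, path) -> None:
    payload = {"pulses": [
        {"a": p.a, "b": p.b, "c": p.c, "V0": p.V0, "W": p.W} for p in train.pulses
    ]}
    Path(path).write_text(json.dumps(payload, indent=2))


def complex_to_json(z: complex) -> list[float]:
    return [float(np.real(z)), float(np.imag(z))]


def json_to_complex(pair) -> complex:
    re, im = pair
    return complex(re, im)


def characteristics_to_json(chars: Characteristics) -> dict:
    return {"alpha": list(chars.alpha), "beta": list(chars.beta)}


def characteristics_from_json(payload: dict) -> Characteristics:
    return Characteristics(payload["alpha"], payload["beta"])


def period_matrix_to_json(pm: PeriodMatrix) -> list:
    """g x g nested list of [re, im] pairs."""
    return [[complex_to_json(z) for z in row] for row in pm.omega]


def period_matrix_from_json(payload) -> PeriodMatrix:
    return PeriodMatrix(np.array([[json_to_complex(p) for p in row]
                                  for row in payload]))
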