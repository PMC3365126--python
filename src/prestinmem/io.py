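"""CSV readers/writers and run-record metadata.

Sweep CSVs carry columns ``freq_hz, amplitude_norm[, phase_rad]``;
time-course CSVs carry ``t_s, q_C_per_m2``.  Every writer drops a JSON
``RunRecord`` sidecar (``<output>.run.json``) with the command line, config
hash, seed, package version and timestamp, so outputs are reproducible.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import ChargeTimeCourse, FrequencySweep, ValidationError

__all__ = [
    "RunRecord",
    "read_sweep_csv",
    "write_sweep_csv",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "SchemaError",
]

TWO_PI = 2.0 * np.pi


class SchemaError(ValueError):
    """Raised when a CSV does not conform to the documented schema."""


@dataclass
class RunRecord:
    """Reproducibility metadata written alongside every CLI output."""

    command: str
    outputs: list[str]
    config_sha256: str | None = None
    seed: int | None = None
    version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, output_path: str | Path) -> Path:
        path = Path(str(output_path) + ".run.json")
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")
        return path


def make_run_record(
    outputs: list[str | Path],
    config_path: str | Path | None = None,
    seed: int | None = None,
    argv: list[str] | None = None,
) -> RunRecord:
    from . import __version__

    digest = None
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    return RunRecord(
        command=" ".join(argv if argv is not None else sys.argv),
        outputs=[str(p) for p in outputs],
        config_sha256=digest,
        seed=seed,
        version=__version__,
    )


# ---------------------------------------------------------------------------
# Frequency sweeps
# ---------------------------------------------------------------------------

def read_sweep_csv(path: str | Path) -> FrequencySweep:
    """Read a force sweep CSV (``freq_hz, amplitude_norm[, phase_rad]``).

    Frequencies are converted from Hz to angular rad/s internally.  Raises
    :class:`SchemaError` naming the offending column or row.
    """
    df = pd.read_csv(path, comment="#")
    for col in ("freq_hz", "amplitude_norm"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    freq = df["freq_hz"].to_numpy(dtype=float)
    diffs = np.diff(freq)
    if np.any(diffs == 0):
        row = int(np.argmax(diffs == 0)) + 1
        raise SchemaError(f"duplicated frequency at data row {row} in {path}")
    if np.any(diffs < 0):
        row = int(np.argmax(diffs < 0)) + 1
        raise SchemaError(f"non-monotone frequency at data row {row} in {path}")
    phase = df["phase_rad"].to_numpy(dtype=float) if "phase_rad" in df.columns else None
    try:
        return FrequencySweep(omega=TWO_PI * freq, amplitude=df["amplitude_norm"].to_numpy(dtype=float), phase=phase)
    except ValidationError as exc:
        raise SchemaError(f"invalid sweep in {path}: {exc}") from exc


def write_sweep_csv(sweep: FrequencySweep, path: str | Path) -> Path:
    """Write a sweep CSV; round-trips through read_sweep_csv."""
    path = Path(path)
    data = {"freq_hz": sweep.omega / TWO_PI, "amplitude_norm": sweep.amplitude}
    if sweep.phase is not None:
        data["phase_rad"] = sweep.phase
    with open(path, "w") as fh:
        fh.write("# columns: freq_hz [Hz], amplitude_norm [-], phase_rad [rad]\n")
        pd.DataFrame(data).to_csv(fh, index=False, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# Charge time courses
# ---------------------------------------------------------------------------

def write_timecourse_csv(tc: ChargeTimeCourse, path: str | Path) -> Path:
    """Write a charge time course CSV with units in the header."""
    if tc.t.size == 0:
        raise ValueError("empty time grid")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# units: t_s [s], q_C_per_m2 [C/m^2]\n")
        pd.DataFrame({"t_s": tc.t, "q_C_per_m2": tc.q}).to_csv(
            fh, index=False, float_format="%.12g"
        )
    return path


def read_timecourse_csv(path: str | Path) -> ChargeTimeCourse:
    df = pd.read_csv(path, comment="#")
    for col in ("t_s", "q_C_per_m2"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    try:
        return ChargeTimeCourse(
            t=df["t_s"].to_numpy(dtype=float), q=df["q_C_per_m2"].to_numpy(dtype=float)
        )
    except ValidationError as exc:
        raise SchemaError(f"invalid time course in {path}: {exc}") from exc
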