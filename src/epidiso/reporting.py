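"""Run records, text/CSV reports, and longitudinal trend tracking.

The text report mirrors what a physicist files after monthly QA: every
per-image jaw-to-phantom distance, then the averaged shift per dimension
and the couch move.  A CSV twin with a fixed column order feeds trend
analysis; TG-142 asks for lasers within +-1 mm of isocenter, so any shift
beyond 1 mm is flagged.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import MachineConfig
from .geometry import ROOM_AXES
from .measurement import JawMeasurement
from .solver import IsocenterResult

TOLERANCE_MM = 1.0  # TG-142 laser/isocenter monthly tolerance

CSV_COLUMNS = ["image", "gantry", "collimator", "jaw", "d_mm"]
SHIFT_COLUMNS = ["dimension", "n", "S_bar_mm", "couch_shift_mm"]


@dataclass
class RunRecord:
    timestamp: str
    machine: str
    measurements: list[JawMeasurement]
    result: IsocenterResult
    config_digest: str = ""

    @classmethod
    def create(
        cls,
        result: IsocenterResult,
        config: MachineConfig,
        timestamp: str | None = None,
    ) -> "RunRecord":
        return cls(
            timestamp=timestamp or _dt.datetime.now().isoformat(timespec="seconds"),
            machine=config.name,
            measurements=list(result.measurements),
            result=result,
            config_digest=config.digest(),
        )

    def shifts(self) -> dict[str, float]:
        return dict(self.result.couch_shift_mm)


def measurements_frame(measurements: list[JawMeasurement]) -> pd.DataFrame:
    rows = [
        {
            "image": m.image_ref,
            "gantry": m.gantry_deg,
            "collimator": m.collimator_deg,
            "jaw": m.jaw,
            "d_mm": m.d_mm,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def shifts_frame(result: IsocenterResult) -> pd.DataFrame:
    rows = [
        {
            "dimension": dim,
            "n": result.n_per_dimension[dim],
            "S_bar_mm": result.S_bar_mm[dim],
            "couch_shift_mm": result.couch_shift_mm[dim],
        }
        for dim in ROOM_AXES
    ]
    return pd.DataFrame(rows, columns=SHIFT_COLUMNS)


def write_text_report(record: RunRecord, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "EPID isocenter localization report",
        f"machine: {record.machine}    acquired: {record.timestamp}",
        f"config digest: {record.config_digest}",
        "",
        "per-image distances (mm at isocenter plane)",
        f"{'image':<28} {'gantry':>7} {'coll':>6} {'jaw':>4} {'d_mm':>8}",
    ]
    for m in record.measurements:
        lines.append(
            f"{Path(m.image_ref).name:<28} {m.gantry_deg:>7.1f} "
            f"{m.collimator_deg:>6.1f} {m.jaw:>4} {m.d_mm:>8.3f}"
        )
    lines += ["", "averaged shifts", f"{'dimension':<14} {'n':>3} {'S_bar':>8} {'couch':>8}"]
    for dim in ROOM_AXES:
        lines.append(
            f"{dim:<14} {record.result.n_per_dimension[dim]:>3d} "
            f"{record.result.S_bar_mm[dim]:>8.3f} {record.result.couch_shift_mm[dim]:>8.3f}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_csv_report(record: RunRecord, path: str | Path) -> Path:
    """Machine-readable twin: measurement rows, then shift rows."""
    path = Path(path)
    meas = measurements_frame(record.measurements)
    shifts = shifts_frame(record.result)
    shifts.insert(0, "timestamp", record.timestamp)
    shifts.insert(1, "machine", record.machine)
    with open(path, "w") as fh:
        meas.to_csv(fh, index=False)
        fh.write("\n")
        shifts.to_csv(fh, index=False)
    return path


def trend(records: list[RunRecord]) -> pd.DataFrame:
    """Shift-vs-date table with out-of-tolerance flags at 1 mm.

    One row per run; ``flagged`` marks any |shift| beyond the TG-142
    tolerance.  Returns an empty table for an empty history.
    """
    cols = ["timestamp", "machine", *ROOM_AXES, "flagged"]
    if not records:
        return pd.DataFrame(columns=cols)
    rows = []
    for r in records:
        shifts = r.shifts()
        rows.append(
            {
                "timestamp": r.timestamp,
                "machine": r.machine,
                **shifts,
                "flagged": any(abs(shifts[d]) > TOLERANCE_MM for d in ROOM_AXES),
            }
        )
    df = pd.DataFrame(rows, columns=cols)
    summary = {
        dim: {"min": df[dim].min(), "max": df[dim].max(), "mean": df[dim].mean()}
        for dim in ROOM_AXES
    }
    df.attrs["summary"] = summary
    return df
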