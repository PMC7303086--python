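"""Dataset and report I/O.

Dataset CSV schema (UTF-8, '.' decimal, header required; all lengths mm):

    scenario_id,grid_index,elevation,rotation_deg,x_mm,y_mm,z_mm,quality
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .phantom import CalibratedPhantom, DataError, Measurement

CSV_COLUMNS = [
    "scenario_id", "grid_index", "elevation", "rotation_deg",
    "x_mm", "y_mm", "z_mm", "quality",
]


def measurements_to_frame(measurements: Sequence[Measurement]) -> pd.DataFrame:
    rows = [
        {
            "scenario_id": m.scenario_id,
            "grid_index": m.grid_index,
            "elevation": m.elevation_level,
            "rotation_deg": m.rotation,
            "x_mm": m.position[0],
            "y_mm": m.position[1],
            "z_mm": m.position[2] if len(m.position) > 2 else 0.0,
            "quality": m.quality,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_measurements(df: pd.DataFrame) -> list[Measurement]:
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"dataset is missing columns: {sorted(missing)}")
    return [
        Measurement(
            scenario_id=str(r.scenario_id),
            grid_index=int(r.grid_index),
            elevation_level=int(r.elevation),
            rotation=float(r.rotation_deg),
            position=np.array([r.x_mm, r.y_mm, r.z_mm], dtype=float),
            quality=float(r.quality),
        )
        for r in df.itertuples(index=False)
    ]


def write_measurements(path: str | Path, measurements: Sequence[Measurement]) -> None:
    measurements_to_frame(measurements).to_csv(path, index=False)


def read_measurements(path: str | Path) -> list[Measurement]:
    return frame_to_measurements(pd.read_csv(path))


def write_phantom(path: str | Path, phantom: CalibratedPhantom) -> None:
    doc = {
        "grid_positions": phantom.grid_positions.tolist(),
        "stud_pitch": phantom.stud_pitch,
        "brick_height": phantom.brick_height,
        "n_elevations": phantom.n_elevations,
        "repeatability": phantom.repeatability,
    }
    text = (
        yaml.safe_dump(doc)
        if str(path).endswith((".yaml", ".yml"))
        else json.dumps(doc, indent=1)
    )
    Path(path).write_text(text)


def read_phantom(path: str | Path) -> CalibratedPhantom:
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return CalibratedPhantom(
        grid_positions=np.asarray(doc["grid_positions"], dtype=float),
        stud_pitch=float(doc["stud_pitch"]),
        brick_height=float(doc["brick_height"]),
        n_elevations=int(doc["n_elevations"]),
        repeatability=float(doc.get("repeatability", 0.02)),
    )


def write_report(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))
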