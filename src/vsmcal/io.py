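"""Result serialization: trajectory CSV (with a unit row under the header)
and JSON summaries carrying the fully resolved parameter set."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .params import ParameterSet
from .simulate import Trajectory

__all__ = ["write_trajectory_csv", "write_json_summary", "write_table_csv"]


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """RFC-4180 CSV: header, unit row, then one row per output time."""
    frame = traj.to_frame()
    units = Trajectory.column_units()
    unit_row = pd.DataFrame([[units.get(c, "") for c in frame.columns]],
                            columns=frame.columns)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        unit_row.to_csv(fh, index=False)
        frame.to_csv(fh, index=False, header=False)


def write_table_csv(frame: pd.DataFrame, path: str | Path,
                    units: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        if units:
            pd.DataFrame([[units.get(c, "") for c in frame.columns]],
                         columns=frame.columns).to_csv(fh, index=False)
            frame.to_csv(fh, index=False, header=False)
        else:
            frame.to_csv(fh, index=False)


def write_json_summary(payload: dict, params: ParameterSet,
                       path: str | Path) -> None:
    """JSON summary with the resolved parameters for provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = dict(payload)
    out["parameters"] = params.to_dict()
    path.write_text(json.dumps(out, indent=2, sort_keys=True))
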