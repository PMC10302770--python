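"""CSV / JSON / image round-tripping for the pipeline's file formats.

Formats (all text, UTF-8, '.' decimal separator, LF endings):

* RTCA CSV: header ``time_h,nci`` with nci = 1.0 at time 0.
* Flow CSV: header ``time_h,viable_pct,early_pct,late_pct,necrosis_pct``;
  each row sums to 100.
* Trajectory CSV: header ``time_h,viability_pct`` (optional ``nci``).
* Field dump CSV: ``node_x,node_y,alpha,c`` per recorded time.
* Parameter JSON: flat object with keys s1..s4, Q, Q1.
* Images: 8-bit grayscale PGM or PNG.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import ViabilitySeries
from .solver import SimGrid, StateField, Trajectory
from .synthetic import FlowFractions

__all__ = [
    "read_rtca_csv", "write_rtca_csv",
    "read_flow_csv", "write_flow_csv",
    "write_trajectory_csv", "write_fields_csv",
    "write_image", "write_json",
]


def _write_csv(df: pd.DataFrame, path: str | Path) -> None:
    # repr-precision floats so numeric round-trips are lossless
    with open(path, "w", newline="\n") as fh:
        fh.write(",".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def write_rtca_csv(series: ViabilitySeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_h": series.times, "nci": series.values / 100.0})
    _write_csv(df, path)


def read_rtca_csv(path: str | Path) -> ViabilitySeries:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_h", "nci"]:
        raise ValueError(f"{path}: expected header 'time_h,nci'")
    return ViabilitySeries(times=df["time_h"].to_numpy(),
                           values=100.0 * df["nci"].to_numpy(),
                           modality="rtca")


def write_flow_csv(snapshots: list[FlowFractions], path: str | Path) -> None:
    df = pd.DataFrame([
        {"time_h": f.t, "viable_pct": f.viable_pct, "early_pct": f.early_pct,
         "late_pct": f.late_pct, "necrosis_pct": f.necrosis_pct}
        for f in snapshots
    ])
    _write_csv(df, path)


def read_flow_csv(path: str | Path) -> list[FlowFractions]:
    df = pd.read_csv(path)
    cols = ["time_h", "viable_pct", "early_pct", "late_pct", "necrosis_pct"]
    if list(df.columns) != cols:
        raise ValueError(f"{path}: expected header '{','.join(cols)}'")
    return [
        FlowFractions(t=row.time_h, viable_pct=row.viable_pct,
                      early_pct=row.early_pct, late_pct=row.late_pct,
                      necrosis_pct=row.necrosis_pct)
        for row in df.itertuples(index=False)
    ]


def write_trajectory_csv(traj: Trajectory, path: str | Path,
                         include_nci: bool = False) -> None:
    data = {"time_h": traj.times, "viability_pct": traj.viability_pct}
    if include_nci:
        data["nci"] = traj.viability_pct / 100.0
    _write_csv(pd.DataFrame(data), path)


def write_fields_csv(state: StateField, grid: SimGrid,
                     path: str | Path) -> None:
    xs = np.linspace(0.0, 1.0, grid.nx)
    ys = np.linspace(0.0, 1.0, grid.ny)
    xx, yy = np.meshgrid(xs, ys)
    df = pd.DataFrame({
        "node_x": xx.ravel(), "node_y": yy.ravel(),
        "alpha": state.alpha.ravel(), "c": state.c.ravel(),
    })
    _write_csv(df, path)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale raster as PGM (P2, plain text) or PNG."""
    path = Path(path)
    img = np.asarray(img, dtype=np.uint8)
    if path.suffix.lower() == ".pgm":
        lines = [f"P2\n{img.shape[1]} {img.shape[0]}\n255\n"]
        for row in img:
            lines.append(" ".join(str(int(v)) for v in row) + "\n")
        path.write_text("".join(lines))
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
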