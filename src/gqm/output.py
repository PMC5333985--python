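"""File outputs: trajectory CSV, summary JSON, phase-map TSV.

All floats are serialized in scientific notation with 9 significant digits
so replay runs can be diffed byte-for-byte.  CSV is comma-separated, LF,
UTF-8; field contents never need quoting by construction.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .binding import EngagementClass
from .engine import TrajectoryRecord

__all__ = ["write_outputs", "write_trajectory", "read_trajectory", "write_phase_map"]

TRAJECTORY_HEADER = (
    "step,niche,clone_id,stage,n_cells,kd_apparent,occupancy,ag_free,action"
)


def _fmt(x: float) -> str:
    return f"{x:.8e}"


def write_trajectory(records: Sequence[TrajectoryRecord], path: Path) -> None:
    lines = [TRAJECTORY_HEADER]
    for r in records:
        lines.append(
            f"{r.step},{r.niche},{r.clone_id},{r.stage},{r.n_cells},"
            f"{_fmt(r.kd_apparent)},{_fmt(r.occupancy)},{_fmt(r.ag_free)},{r.action}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_trajectory(path: Path) -> list[TrajectoryRecord]:
    """Round-trip reader for the trajectory CSV."""
    lines = path.read_text(encoding="utf-8").strip().splitlines()
    if not lines or lines[0] != TRAJECTORY_HEADER:
        raise ValueError(f"bad trajectory header in {path}")
    records = []
    for line in lines[1:]:
        step, niche, clone_id, stage, n_cells, kd, occ, ag, action = line.split(",")
        records.append(
            TrajectoryRecord(
                step=int(step),
                niche=niche,
                clone_id=clone_id,
                stage=stage,
                n_cells=int(n_cells),
                kd_apparent=float(kd),
                occupancy=float(occ),
                ag_free=float(ag),
                action=action,
            )
        )
    return records


def write_phase_map(
    grid: np.ndarray,
    grid_ag: np.ndarray,
    grid_kd: np.ndarray,
    path: Path,
) -> None:
    """TSV grid of class labels; first row/column carry the axis values."""
    header = "kd_molar\\ag_molar\t" + "\t".join(_fmt(a) for a in np.asarray(grid_ag))
    lines = [header]
    for i, kd in enumerate(np.asarray(grid_kd)):
        labels = "\t".join(EngagementClass(v).name for v in grid[i])
        lines.append(f"{_fmt(kd)}\t{labels}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def write_outputs(
    records: Sequence[TrajectoryRecord],
    summary: dict,
    out_dir: str | Path,
    phase: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> dict[str, Path]:
    """Write the standard file set and return the paths by role.

    ``phase`` is an optional ``(grid, grid_ag, grid_kd)`` triple; when given
    a ``phase_map.tsv`` is produced alongside trajectory and summary.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    paths = {
        "trajectory": out / "trajectory.csv",
        "summary": out / "summary.json",
    }
    write_trajectory(records, paths["trajectory"])
    paths["summary"].write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    if phase is not None:
        grid, grid_ag, grid_kd = phase
        paths["phase_map"] = out / "phase_map.tsv"
        write_phase_map(grid, grid_ag, grid_kd, paths["phase_map"])
    return paths
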