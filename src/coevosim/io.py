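"""Plain-text serialisation: tidy TSV trajectories, histograms, manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SimResult, Trajectory
from .stats import Histogram

__all__ = [
    "write_trajectory", "read_trajectory",
    "write_histogram", "read_histogram",
    "write_run_metadata", "write_cells", "read_cells",
]


def write_trajectory(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    return Trajectory(
        times=df["time"].to_numpy(), C=df["C"].to_numpy(),
        E=df["E"].to_numpy(), mean_A=df["mean_A"].to_numpy(),
        mean_I=df["mean_I"].to_numpy(),
        mean_burden=df["mean_burden"].to_numpy(),
        dominant_type=df["dominant_type"].to_numpy() if "dominant_type" in df else None,
        dominant_E=df["dominant_E"].to_numpy() if "dominant_E" in df else None,
    )


def write_histogram(hist: Histogram, path, index_name: str = "index",
                    counts_name: str = "count", header_comment: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        hist.to_frame(index_name, counts_name).to_csv(fh, sep="\t", index=False)


def read_histogram(path) -> Histogram:
    df = pd.read_csv(path, sep="\t", comment="#")
    idx, cnt = df.columns[:2]
    return Histogram(df[idx].to_numpy(), df[cnt].to_numpy())


def write_run_metadata(result: SimResult, path) -> None:
    """JSON manifest: full parameter set, seed, outcome, event counts."""
    meta = {
        "params": result.params.to_dict(),
        "seed": result.seed,
        "outcome": result.outcome.outcome,
        "suppressed": result.outcome.suppressed,
        "end_time": result.outcome.end_time,
        "final_C": result.outcome.final_C,
        "final_E": result.outcome.final_E,
        "event_counts": result.event_counts,
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_cells(state, path) -> None:
    """One row per living cell: id plus comma-joined mutation ids by class."""
    rows = []
    for cell in state.cells.values():
        rows.append((cell.cell_id,
                     ",".join(map(str, sorted(cell.antigenic))),
                     ",".join(map(str, sorted(cell.neutral)))))
    pd.DataFrame(rows, columns=["cell_id", "antigenic", "neutral"]).to_csv(
        path, sep="\t", index=False)


class _CellRow:
    __slots__ = ("cell_id", "antigenic", "neutral")

    def __init__(self, cell_id, antigenic, neutral):
        self.cell_id = cell_id
        self.antigenic = antigenic
        self.neutral = neutral


def read_cells(path):
    """Read a cells table back as lightweight cell records."""
    df = pd.read_csv(path, sep="\t", dtype={"antigenic": str, "neutral": str},
                     keep_default_na=False)
    cells = []
    for row in df.itertuples(index=False):
        ant = {int(x) for x in row.antigenic.split(",")} if row.antigenic else set()
        neu = {int(x) for x in row.neutral.split(",")} if row.neutral else set()
        cells.append(_CellRow(int(row.cell_id), ant, neu))
    return cells
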