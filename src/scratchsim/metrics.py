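"""Monitor quantities, interval-resampled motility means, CSV export.

One :class:`MetricsFrame` is collected per tick (including tick 0): counts
per color class, cleaved/uncleaved totals, ligand count, cell-cycle phase
occupancy, and the reported average motility of the tracked cohort — the
cells that sat at the scratch edge when the scratch was made, exactly the
cells tracked in the wet-lab assay. Daughter cells are excluded from the
cohort.

The reported average motility is the cohort mean of the cells' signaling
motility mu (parameter value plus fluctuation), mirroring how the original
interface plots it; it can go negative under a large deviation setting
when the pathways are inhibited, unless ``motility_check`` clamps it at
zero. The separate ``realized_speed`` column gives the kinematic ground
truth (mean per-tick cohort displacement, converted to μm/min).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .world import COLOR_NAMES, World

__all__ = [
    "MetricsFrame",
    "collect_frame",
    "interval_average_motility",
    "frames_to_dataframe",
    "export_csv",
]


@dataclass(frozen=True)
class MetricsFrame:
    """One tick's monitor readout."""

    tick: int
    hours: float
    cell_count: int
    n_blue: int
    n_periwinkle: int
    n_green: int
    n_light_green: int
    n_red: int
    n_orange: int
    cleaved_count: int
    uncleaved_count: int
    ligand_count: int
    n_g1: int
    n_s: int
    n_g2: int
    n_m: int
    pct_in_S: float
    theo_pct_S: float
    reported_avg_motility: float
    realized_speed: float


def collect_frame(world: World) -> MetricsFrame:
    """Compute the full monitor readout for the world's current tick."""
    p = world.params
    n = world.n_cells
    colors = np.bincount(world.color, minlength=6) if n else np.zeros(6, dtype=int)
    cleaved = int(world.released.sum()) if n else 0

    schedule = world.schedule
    if n:
        bins = np.array([schedule.g1_end, schedule.s_end, schedule.g2_end])
        phase_idx = np.digitize(world.cycle, bins)
        phases = np.bincount(phase_idx, minlength=4)
        pct_s = 100.0 * phases[1] / n
    else:
        phases = np.zeros(4, dtype=int)
        pct_s = math.nan

    tracked = world.tracked
    if n and tracked.any():
        reported = float(world.mu[tracked].mean())
        if p.motility_check:
            reported = max(reported, 0.0)
        tx, ty = world.x[tracked].copy(), world.y[tracked].copy()
        prev = getattr(world, "_last_tracked_xy", None)
        if prev is not None and prev[0].shape == tx.shape:
            realized = float(
                np.hypot(tx - prev[0], ty - prev[1]).mean() * p.patch_scale
            )
        else:
            realized = math.nan
        world._last_tracked_xy = (tx, ty)
    else:
        reported = math.nan
        realized = math.nan

    if p.trailers and n and tracked.any():
        ids = np.flatnonzero(tracked)
        world.trails.append(
            (world.tick, ids, world.x[ids].copy(), world.y[ids].copy())
        )

    return MetricsFrame(
        tick=world.tick,
        hours=world.hours,
        cell_count=n,
        n_blue=int(colors[0]),
        n_periwinkle=int(colors[1]),
        n_green=int(colors[2]),
        n_light_green=int(colors[3]),
        n_red=int(colors[4]),
        n_orange=int(colors[5]),
        cleaved_count=cleaved,
        uncleaved_count=n - cleaved,
        ligand_count=world.n_ligands,
        n_g1=int(phases[0]),
        n_s=int(phases[1]),
        n_g2=int(phases[2]),
        n_m=int(phases[3]),
        pct_in_S=pct_s,
        theo_pct_S=schedule.pct_s_effective,
        reported_avg_motility=reported,
        realized_speed=realized,
    )


def interval_average_motility(
    frames: "Sequence[MetricsFrame] | pd.Series | np.ndarray",
    interval_min: int,
) -> float:
    """Mean reported motility sampled every ``interval_min`` ticks.

    Mirrors averaging tracked velocities at 1, 5 or 10 minute imaging
    intervals: the per-tick series is subsampled at ticks k, 2k, ...
    (tick 0 excluded) and averaged. Raises if the run is shorter than one
    interval.
    """
    if interval_min < 1:
        raise ValueError("interval_min must be a positive number of ticks")
    if isinstance(frames, (pd.Series, np.ndarray)):
        series = np.asarray(frames, dtype=float)
    else:
        series = np.array([f.reported_avg_motility for f in frames], dtype=float)
    samples = series[interval_min::interval_min]
    if samples.size == 0:
        raise ValueError(
            f"interval of {interval_min} ticks is longer than the "
            f"{series.size - 1}-tick series"
        )
    return float(samples.mean())


def frames_to_dataframe(frames: Sequence[MetricsFrame]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(f) for f in frames])


def export_csv(result, out_dir: str | Path) -> dict[str, Path]:
    """Write frames.csv, trails.csv and params.csv for a finished run.

    frames.csv has one row per tick (tick 0 included); trails.csv is tidy
    long format (cell_id, tick, x, y, trailer_color, color); params.csv
    records the fully resolved parameter set including the seed, so the
    exact run can be reproduced. Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    frames_path = out / "frames.csv"
    frames_to_dataframe(result.frames).to_csv(frames_path, index=False)
    paths["frames"] = frames_path

    world = result.world
    rows = []
    for tick, ids, xs, ys in world.trails:
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": ids,
                    "tick": tick,
                    "x": xs,
                    "y": ys,
                    "trailer_color": world.trailer_color[ids],
                    "color": [COLOR_NAMES[c] for c in world.color[ids]],
                }
            )
        )
    trails_path = out / "trails.csv"
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(trails_path, index=False)
    else:
        pd.DataFrame(
            columns=["cell_id", "tick", "x", "y", "trailer_color", "color"]
        ).to_csv(trails_path, index=False)
    paths["trails"] = trails_path

    params_path = out / "params.csv"
    items = dataclasses.asdict(result.params)
    pd.DataFrame(
        {"parameter": list(items), "value": [items[k] for k in items]}
    ).to_csv(params_path, index=False)
    paths["params"] = params_path
    return paths
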