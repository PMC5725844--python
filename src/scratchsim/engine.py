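"""Run orchestration: initialize → populate → make-scratch and the tick loop.

A run is fully determined by its parameter set (which includes the RNG
seed): two runs with equal parameters produce bitwise-identical frame
series. The tick loop mirrors the original go procedure — refresh patch
densities, let every cell update its parameters, move and produce ligand,
apply adhesion springs when enabled, move ligands, advance the clock —
and halts when the configured time scale is reached, when any cell
reaches the right edge of the world (the run "ends prematurely"), or if
the population ever empties (a defensive guard: no rule removes cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from . import adhesion, cells, ligands
from .metrics import MetricsFrame, collect_frame
from .params import SimulationParams, validate_params
from .signaling import CycleSchedule, effective_motility, pathway_centers, phase_boundaries
from .world import GREEN, World, cell_capacity, update_density

__all__ = ["RunResult", "initialize", "populate", "make_scratch", "step", "run", "stepper"]

HALT_TIME = "time_scale_reached"
HALT_EDGE = "right_edge_reached"
HALT_EXTINCT = "extinction_guard"


@dataclass
class RunResult:
    """A finished simulation: final world, per-tick monitor series, halt cause."""

    world: World
    frames: list[MetricsFrame]
    halt_reason: str
    params: SimulationParams
    schedule: CycleSchedule


def initialize(params: SimulationParams) -> World:
    """Build the tick-0 world: derived signaling quantities, cells, scratch."""
    params = validate_params(params)
    rng = np.random.default_rng(params.seed)
    world = World(params, rng)
    world.schedule = phase_boundaries(params)
    world.centers = pathway_centers(params)
    world.mu0 = effective_motility(world.centers)
    populate(world)
    make_scratch(world)
    update_density(world)
    if params.cellular_adhesion:
        adhesion.rebuild_links(world)
    return world


def populate(world: World) -> None:
    """Place the monolayer behind the scratch line.

    The cell count comes from the confluent-density calculation; cells are
    placed on distinct uniformly chosen patches strictly left of the
    scratch line, each with randomized pathway deviations (within the
    variance range) and a uniform-random position in the cell cycle, so
    the expected phase mix matches the phase-duration proportions. All
    start blue and unreleased.
    """
    p = world.params
    n = cell_capacity(p)
    if n == 0:
        warnings.warn("populating an empty world (zero cells)", stacklevel=2)
        return
    cols = np.arange(p.x_min, p.scratch_line)
    ys = np.arange(p.y_min, p.y_max + 1)
    gx, gy = np.meshgrid(cols, ys)
    sites = np.column_stack([gx.ravel(), gy.ravel()])
    if n > sites.shape[0]:
        warnings.warn(
            f"requested {n} cells but only {sites.shape[0]} open patches "
            "behind the scratch line; placing as many as fit",
            stacklevel=2,
        )
        n = sites.shape[0]
    chosen = sites[world.rng.choice(sites.shape[0], size=n, replace=False)]

    v = p.deviation_from_avg
    jit = world.rng.uniform(-v, v, size=(2, n))
    world.append_cells(
        x=chosen[:, 0].astype(np.float64),
        y=chosen[:, 1].astype(np.float64),
        jit_a=jit[0],
        jit_b=jit[1],
        mu=world.mu0 + 0.5 * (jit[0] + jit[1]),
        cycle=world.rng.integers(0, world.schedule.total_ticks, size=n),
        color=np.zeros(n, dtype=np.int8),
        released=np.zeros(n, dtype=bool),
        tracked=np.zeros(n, dtype=bool),
        trailer_color=world.rng.integers(0, 2**31 - 1, size=n).astype(np.int32),
    )


def make_scratch(world: World) -> None:
    """Mark the scratch-edge cohort: cells within one patch west of the line
    turn green and released — these are the tracked cells."""
    line = world.params.scratch_line
    if world.n_cells == 0:
        return
    _, col = world.patch_indices(world.x, world.y)
    edge = col == (line - 1 - world.x_min)
    world.color[edge] = GREEN
    world.released |= edge
    world.tracked |= edge


def step(world: World) -> None:
    """Advance the world one tick; sets ``world.halt_reason`` when done."""
    p = world.params
    update_density(world)
    cells.update_params(world)
    cells.cell_diffuse(world)
    cells.l_production(world)
    if p.cellular_adhesion:
        adhesion.rebuild_links(world)
        adhesion.apply_springs(world)
    ligands.ligand_step(world)
    world.tick += 1

    if world.n_cells == 0:
        world.halt_reason = HALT_EXTINCT
    elif world.tick >= p.ticks_total:
        world.halt_reason = HALT_TIME
    elif world.right_edge_reached():
        world.halt_reason = HALT_EDGE


def stepper(params: SimulationParams) -> Iterator[tuple[World, MetricsFrame]]:
    """Generator interface: yields (world, frame) at tick 0 and after every
    tick, for embedding the simulation in other tooling."""
    world = initialize(params)
    if world.n_cells == 0:
        world.halt_reason = HALT_EXTINCT
    yield world, collect_frame(world)
    while world.halt_reason is None:
        step(world)
        yield world, collect_frame(world)


def run(params: SimulationParams | dict) -> RunResult:
    """Initialize and step to completion; returns the full frame series.

    The frame series has one entry per tick plus the initial tick-0 frame.
    """
    params = validate_params(params)
    frames: list[MetricsFrame] = []
    world = None
    for world, frame in stepper(params):
        frames.append(frame)
    assert world is not None
    return RunResult(
        world=world,
        frames=frames,
        halt_reason=world.halt_reason,
        params=params,
        schedule=world.schedule,
    )
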