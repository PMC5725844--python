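"""Per-tick cell behaviors: parameter fluctuation, cycle advance, mitosis,
movement, ligand release and the release/re-adhesion transitions.

Each rule is defined per cell but evaluated with numpy across the whole
population. All rules read only the patch densities computed at the start
of the tick, so the simultaneous vectorized update is equivalent to
updating cells one at a time in random order; mitosis placements, which do
interact through patch occupancy, are resolved sequentially in RNG-shuffled
order against a live occupancy grid.

The movement hierarchy per cell per tick:

1. if the patch behind (west of) the cell holds more than two cells, the
   cell steps east to make room for the dense pack behind it;
2. otherwise, with probability ``randomness`` the cell steps in a uniformly
   random direction;
3. otherwise it steps toward the least-crowded open neighbor patch (ties
   broken uniformly at random); when every neighbor is at or above the
   crowding threshold the cell is stationary until space opens up.

Steps have length √2·mu·dt in patch units; a cell whose fluctuating
motility dips below zero simply does not move that tick. Decisions are
independent across cells and ticks.
"""

from __future__ import annotations

import numpy as np

from .world import (
    NEIGHBOR_OFFSETS,
    NEIGHBOR_UNITS,
    ORANGE,
    PERIWINKLE,
    RED,
    BLUE,
    WEST,
    World,
)

__all__ = ["update_params", "update_phase", "cell_diffuse", "l_production"]

_SQRT2 = float(np.sqrt(2.0))


def _recompute_mu(world: World) -> None:
    """Converged motility = min deliverable pathway rate + arm fluctuation.

    The deterministic convergence of the inhibition-determined centers
    carries the mean of the two upstream arms' symmetric deviations, so the
    population-average motility equals the configured rate exactly; the
    signaling value may dip below zero under a large deviation setting (the
    kinematic step speed is floored at zero separately).
    """
    world.mu = world.mu0 + 0.5 * (world.jit_a + world.jit_b)


def update_params(world: World) -> None:
    """Fluctuate pathway arms, advance the cycle, update phase and mu.

    With probability 1/2 per cell per tick both arm deviations are redrawn
    uniformly from [−v, +v] (v = ``deviation_from_avg``), emulating the
    slight tick-to-tick wobble of receptor signaling around the
    inhibition-determined rate; the cycle counter then advances one tick
    and cells completing the cycle undergo mitosis.
    """
    p = world.params
    n = world.n_cells
    if n == 0:
        return
    v = p.deviation_from_avg
    refresh = world.rng.random(n) < 0.5
    draws = world.rng.uniform(-v, v, size=(2, n))
    world.jit_a = np.where(refresh, draws[0], world.jit_a)
    world.jit_b = np.where(refresh, draws[1], world.jit_b)
    world.cycle = world.cycle + 1
    update_phase(world)
    _recompute_mu(world)


def update_phase(world: World) -> None:
    """Map cycle counters onto phases; divide cells that completed M.

    On the last tick of the cycle a cell attempts mitosis: a daughter is
    hatched onto a uniformly chosen open Moore-neighbor patch if one
    exists, inheriting the parent's released state and taking the lighter
    color variant of the parent's lineage; with no open space the division
    is skipped. Either way the parent's cycle restarts at zero, as does a
    daughter's. Placements update a live occupancy grid so simultaneous
    divisions cannot overfill a patch.
    """
    p = world.params
    schedule = world.schedule
    dividing = np.flatnonzero(world.cycle >= schedule.total_ticks)
    if dividing.size == 0:
        return
    order = world.rng.permutation(dividing)
    live = world.cell_count  # updated in place as daughters land
    threshold = p.crowding_threshold
    v = p.deviation_from_avg

    new_x: list[float] = []
    new_y: list[float] = []
    new_color: list[int] = []
    new_released: list[bool] = []
    for i in order:
        world.cycle[i] = 0
        row, col = world.patch_indices(world.x[i : i + 1], world.y[i : i + 1])
        counts = world.neighbor_counts(live, row, col)[:, 0]
        open_dirs = np.flatnonzero(counts < threshold)
        if open_dirs.size == 0:
            continue  # no room: the daughter is not created
        d = int(world.rng.choice(open_dirs))
        dx, dy = NEIGHBOR_OFFSETS[d]
        px = float(np.clip(world.x[i] + dx, world.x_min, world.x_max))
        py = float(np.clip(world.y[i] + dy, world.y_min, world.y_max))
        prow, pcol = world.patch_indices(np.array([px]), np.array([py]))
        live[prow[0], pcol[0]] += 1
        new_x.append(px)
        new_y.append(py)
        new_color.append(world.daughter_color(world.color[i]))
        new_released.append(bool(world.released[i]))

    if not new_x:
        return
    k = len(new_x)
    jit = world.rng.uniform(-v, v, size=(2, k))
    world.append_cells(
        x=np.array(new_x),
        y=np.array(new_y),
        jit_a=jit[0],
        jit_b=jit[1],
        mu=world.mu0 + 0.5 * (jit[0] + jit[1]),
        cycle=np.zeros(k, dtype=np.int64),
        color=np.array(new_color, dtype=np.int8),
        released=np.array(new_released, dtype=bool),
        tracked=np.zeros(k, dtype=bool),
        trailer_color=world.rng.integers(0, 2**31 - 1, size=k, dtype=np.int64).astype(
            np.int32, casting="unsafe"
        ),
    )


def cell_diffuse(world: World) -> None:
    """Move every cell one step according to the movement hierarchy."""
    p = world.params
    n = world.n_cells
    if n == 0:
        return
    row, col = world.patch_indices(world.x, world.y)
    counts8 = world.neighbor_counts(world.cell_count, row, col)

    rand_mask = world.rng.random(n) < p.randomness
    angles = world.rng.uniform(0.0, 2.0 * np.pi, n)
    tiebreak = world.rng.random((8, n))

    forced_east = counts8[WEST] > 2
    open8 = counts8 < p.crowding_threshold
    any_open = open8.any(axis=0)
    keys = counts8.astype(np.float64) + tiebreak
    keys[~open8] = np.inf
    least_dir = np.argmin(keys, axis=0)

    step = _SQRT2 * np.maximum(world.mu, 0.0) * p.dt_effective
    dx = np.zeros(n)
    dy = np.zeros(n)

    toward = ~forced_east & ~rand_mask & any_open
    dx[toward] = NEIGHBOR_UNITS[least_dir[toward], 0]
    dy[toward] = NEIGHBOR_UNITS[least_dir[toward], 1]

    wander = ~forced_east & rand_mask
    dx[wander] = np.cos(angles[wander])
    dy[wander] = np.sin(angles[wander])

    dx[forced_east] = 1.0
    dy[forced_east] = 0.0

    world.x, world.y = world.clamp_positions(
        world.x + dx * step, world.y + dy * step
    )


def l_production(world: World) -> int:
    """Release state transitions and ligand production; returns spawn count.

    A cell strictly past the scratch line with fewer than two cells in the
    patch ahead (east) sheds its surface ligand: an unreleased cell turns
    red (lineage light variant for daughters) and immediately hatches four
    ligand molecules; an already-released cell there has a 5% chance per
    tick of hatching a uniform 1–4 new molecules. With cellular adhesion
    enabled, a red-lineage cell that finds two or more cells ahead rejoins
    the adherent pack: it reverts to unreleased blue/periwinkle and stops
    producing. Green-lineage cells never revert.
    """
    p = world.params
    n = world.n_cells
    if n == 0:
        return 0
    row, col = world.patch_indices(world.x, world.y)
    padded = world.padded_counts(world.cell_count)
    ahead = padded[row + 1, col + 2]  # east neighbor
    past = world.x > p.scratch_line
    ahead_clear = ahead < 2

    was_released = world.released.copy()

    newly = past & ahead_clear & ~was_released
    if newly.any():
        world.released |= newly
        colors = world.color
        colors[newly & (colors == BLUE)] = RED
        colors[newly & (colors == PERIWINKLE)] = ORANGE

    gate = world.rng.random(n) < 0.05
    amounts = world.rng.integers(1, 5, size=n)
    producing = past & ahead_clear & was_released & gate

    spawn_x: list[np.ndarray] = []
    spawn_y: list[np.ndarray] = []
    if newly.any():
        spawn_x.append(np.repeat(world.x[newly], 4))
        spawn_y.append(np.repeat(world.y[newly], 4))
    if producing.any():
        spawn_x.append(np.repeat(world.x[producing], amounts[producing]))
        spawn_y.append(np.repeat(world.y[producing], amounts[producing]))

    if p.cellular_adhesion:
        red_lineage = (world.color == RED) | (world.color == ORANGE)
        revert = world.released & red_lineage & ~ahead_clear
        if revert.any():
            world.released &= ~revert
            world.color[revert & (world.color == RED)] = BLUE
            world.color[revert & (world.color == ORANGE)] = PERIWINKLE

    if not spawn_x:
        return 0
    lx = np.concatenate(spawn_x)
    ly = np.concatenate(spawn_y)
    world.append_ligands(lx, ly)
    return lx.shape[0]
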