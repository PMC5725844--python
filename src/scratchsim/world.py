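"""Bounded 2-D patch world: agent storage, density fields, spatial queries.

The world is a non-wrapping grid of patches indexed by integer coordinates
(x east, y north); agents live at continuous positions and belong to the
patch their position rounds into. Patches hold per-tick cell and ligand
counts used by the movement rules. The left, top and bottom walls are
impassable; a cell reaching the rightmost column ends the run.

Cell state is stored struct-of-arrays (positions, pathway jitter, cycle
counters, color codes, flags) so the per-tick rules can be evaluated with
numpy over the whole population; :meth:`World.cell` exposes a per-agent
view for inspection and tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import SimulationParams

__all__ = [
    "World",
    "Cell",
    "OpenSpace",
    "cell_capacity",
    "update_density",
    "open_space",
    "COLOR_NAMES",
    "BLUE",
    "PERIWINKLE",
    "GREEN",
    "LIGHT_GREEN",
    "RED",
    "ORANGE",
    "RELEASED_COLORS",
    "NEIGHBOR_OFFSETS",
]

# Color classes. Division produces the lighter variant of the parent's
# lineage; the released flag is true exactly for the green/red lineages.
BLUE, PERIWINKLE, GREEN, LIGHT_GREEN, RED, ORANGE = range(6)
COLOR_NAMES = ("blue", "periwinkle", "green", "light_green", "red", "orange")
RELEASED_COLORS = frozenset({GREEN, LIGHT_GREEN, RED, ORANGE})
_DAUGHTER_COLOR = {
    BLUE: PERIWINKLE,
    PERIWINKLE: PERIWINKLE,
    GREEN: LIGHT_GREEN,
    LIGHT_GREEN: LIGHT_GREEN,
    RED: ORANGE,
    ORANGE: ORANGE,
}

# Moore neighborhood, east first: (dx, dy) for E, NE, N, NW, W, SW, S, SE.
NEIGHBOR_OFFSETS = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)],
    dtype=np.int64,
)
NEIGHBOR_UNITS = NEIGHBOR_OFFSETS / np.linalg.norm(NEIGHBOR_OFFSETS, axis=1)[:, None]
EAST, WEST = 0, 4

_FULL = np.iinfo(np.int32).max  # sentinel density for out-of-bounds patches


@dataclass
class Cell:
    """Read-only per-agent view assembled from the world's arrays."""

    index: int
    x: float
    y: float
    rate_A: float
    rate_B: float
    mu: float
    cycle: int
    phase: str
    released: bool
    color: str
    tracked: bool
    trailer_color: int


@dataclass
class OpenSpace:
    """Assessment of the 8-patch Moore shell around a position.

    ``open_dirs`` flags, per direction (east first, counter-clockwise),
    neighbors under the crowding threshold; ``least_density_dir`` is the
    index of the least-crowded open neighbor (ties broken uniformly at
    random), or ``None`` when nothing is open; ``surrounded_equally`` is
    true when all eight neighbors are open with identical density.
    """

    open_dirs: np.ndarray
    counts: np.ndarray
    least_density_dir: int | None
    center_open: bool
    surrounded_equally: bool

    @property
    def any_open(self) -> bool:
        return bool(self.open_dirs.any())


class World:
    """Mutable simulation state for one run."""

    def __init__(self, params: SimulationParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.tick = 0
        self.halt_reason: str | None = None

        self.width = params.world_width
        self.height = params.world_height
        self.x_min, self.x_max = params.x_min, params.x_max
        self.y_min, self.y_max = params.y_min, params.y_max

        # per-patch fields, indexed [row=y - y_min, col=x - x_min]
        self.cell_count = np.zeros((self.height, self.width), dtype=np.int32)
        self.ligand_count = np.zeros((self.height, self.width), dtype=np.int32)

        # cell population (struct of arrays)
        self.x = np.empty(0, dtype=np.float64)
        self.y = np.empty(0, dtype=np.float64)
        self.jit_a = np.empty(0, dtype=np.float64)  # A-arm deviation from center
        self.jit_b = np.empty(0, dtype=np.float64)
        self.mu = np.empty(0, dtype=np.float64)     # signaling motility, μm/min
        self.cycle = np.empty(0, dtype=np.int64)
        self.color = np.empty(0, dtype=np.int8)
        self.released = np.empty(0, dtype=bool)
        self.tracked = np.empty(0, dtype=bool)      # original scratch-edge cohort
        self.trailer_color = np.empty(0, dtype=np.int32)

        # ligand population
        self.lx = np.empty(0, dtype=np.float64)
        self.ly = np.empty(0, dtype=np.float64)

        # adhesion links, (k, 2) array of cell indices
        self.links = np.empty((0, 2), dtype=np.int64)

        # trail records: one (tick, ids, xs, ys) tuple per recorded tick
        self.trails: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = []

    # -- basic queries ----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.x.shape[0]

    @property
    def n_ligands(self) -> int:
        return self.lx.shape[0]

    @property
    def hours(self) -> float:
        return self.tick / 60.0

    def patch_indices(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) grid indices for continuous positions (round-half-up)."""
        col = np.floor(np.asarray(x) + 0.5).astype(np.int64) - self.x_min
        row = np.floor(np.asarray(y) + 0.5).astype(np.int64) - self.y_min
        return row, col

    def clamp_positions(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Clamp continuous positions so they round into the grid."""
        eps = 1e-9
        x = np.clip(x, self.x_min - 0.5 + eps, self.x_max + 0.5 - eps)
        y = np.clip(y, self.y_min - 0.5 + eps, self.y_max + 0.5 - eps)
        return x, y

    def padded_counts(self, grid: np.ndarray, fill: int = _FULL) -> np.ndarray:
        """Grid padded by one patch on each side; the pad reads as ``fill``."""
        return np.pad(grid, 1, constant_values=fill)

    def neighbor_counts(self, grid: np.ndarray, row: np.ndarray, col: np.ndarray,
                        fill: int = _FULL) -> np.ndarray:
        """Counts on the 8 Moore neighbors of each (row, col), shape (8, n).

        Out-of-bounds neighbors read as ``fill`` (the walls are full).
        """
        padded = self.padded_counts(grid, fill)
        out = np.empty((8, row.shape[0]), dtype=padded.dtype)
        for d, (dx, dy) in enumerate(NEIGHBOR_OFFSETS):
            out[d] = padded[row + 1 + dy, col + 1 + dx]
        return out

    def right_edge_reached(self) -> bool:
        if self.n_cells == 0:
            return False
        _, col = self.patch_indices(self.x, self.y)
        return bool((col >= self.width - 1).any())

    # -- agent views ------------------------------------------------------

    def cell(self, i: int) -> Cell:
        from .signaling import pathway_centers  # local import, no cycle at module load

        centers = pathway_centers(self.params)
        schedule = getattr(self, "schedule", None)
        phase = schedule.phase_of(int(self.cycle[i])) if schedule is not None else "G1"
        return Cell(
            index=i,
            x=float(self.x[i]),
            y=float(self.y[i]),
            rate_A=centers.rate_A + float(self.jit_a[i]),
            rate_B=centers.rate_B + float(self.jit_b[i]),
            mu=float(self.mu[i]),
            cycle=int(self.cycle[i]),
            phase=phase,
            released=bool(self.released[i]),
            color=COLOR_NAMES[self.color[i]],
            tracked=bool(self.tracked[i]),
            trailer_color=int(self.trailer_color[i]),
        )

    def cells(self) -> list[Cell]:
        return [self.cell(i) for i in range(self.n_cells)]

    def color_counts(self) -> dict[str, int]:
        counts = np.bincount(self.color, minlength=6)
        return dict(zip(COLOR_NAMES, (int(c) for c in counts)))

    def daughter_color(self, parent_color: int) -> int:
        return _DAUGHTER_COLOR[int(parent_color)]

    # -- mutation helpers -------------------------------------------------

    def append_cells(self, **arrays: np.ndarray) -> None:
        """Append a batch of cells; every cell array must be provided."""
        self.x = np.concatenate([self.x, arrays["x"]])
        self.y = np.concatenate([self.y, arrays["y"]])
        self.jit_a = np.concatenate([self.jit_a, arrays["jit_a"]])
        self.jit_b = np.concatenate([self.jit_b, arrays["jit_b"]])
        self.mu = np.concatenate([self.mu, arrays["mu"]])
        self.cycle = np.concatenate([self.cycle, arrays["cycle"]])
        self.color = np.concatenate([self.color, arrays["color"].astype(np.int8)])
        self.released = np.concatenate([self.released, arrays["released"]])
        self.tracked = np.concatenate([self.tracked, arrays["tracked"]])
        self.trailer_color = np.concatenate(
            [self.trailer_color, arrays["trailer_color"].astype(np.int32)]
        )

    def append_ligands(self, lx: np.ndarray, ly: np.ndarray) -> None:
        cap = self.params.ligand_cap
        if cap is not None:
            room = max(cap - self.n_ligands, 0)
            lx, ly = lx[:room], ly[:room]
        self.lx = np.concatenate([self.lx, lx])
        self.ly = np.concatenate([self.ly, ly])


def cell_capacity(params: SimulationParams,
                  confluent_density: float | None = None) -> int:
    """Number of cells filling the area behind the scratch line.

    The monolayer occupies every column strictly left of ``scratch_line``
    at the near-confluent density (cells/patch); the count is the rounded
    area × density product. A scratch line at or beyond the left wall
    leaves no area and yields zero cells (with a warning).
    """
    density = params.confluent_density if confluent_density is None else confluent_density
    n_cols = params.scratch_line - params.x_min
    if n_cols <= 0:
        warnings.warn(
            "scratch_line at or beyond the left edge: no room for a monolayer",
            stacklevel=2,
        )
        return 0
    return int(round(density * n_cols * params.world_height))


def update_density(world: World) -> World:
    """Refresh the per-patch cell and ligand counts from agent positions.

    Idempotent: each patch count equals the number of agents whose position
    rounds into it, so the grid totals always match the population sizes.
    """
    world.cell_count[:] = 0
    if world.n_cells:
        row, col = world.patch_indices(world.x, world.y)
        np.add.at(world.cell_count, (row, col), 1)
    world.ligand_count[:] = 0
    if world.n_ligands:
        row, col = world.patch_indices(world.lx, world.ly)
        np.add.at(world.ligand_count, (row, col), 1)
    return world


def open_space(world: World, position: tuple[float, float],
               rng: np.random.Generator | None = None) -> OpenSpace:
    """Assess crowding around one position (current density fields).

    A neighbor patch is open when its cell count is below the crowding
    threshold; out-of-bounds patches are treated as full, so a boundary
    cell never sees an open direction through a wall.
    """
    rng = world.rng if rng is None else rng
    row, col = world.patch_indices(np.array([position[0]]), np.array([position[1]]))
    counts = world.neighbor_counts(world.cell_count, row, col)[:, 0]
    threshold = world.params.crowding_threshold
    open_dirs = counts < threshold
    center = int(world.cell_count[row[0], col[0]])
    if open_dirs.any():
        keys = counts.astype(np.float64) + rng.random(8)
        keys[~open_dirs] = np.inf
        least = int(np.argmin(keys))
    else:
        least = None
    surrounded = bool(open_dirs.all() and (counts == counts[0]).all())
    return OpenSpace(
        open_dirs=open_dirs,
        counts=counts,
        least_density_dir=least,
        center_open=center < threshold,
        surrounded_equally=surrounded,
    )
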