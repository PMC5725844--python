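"""Ligand (released ectodomain) movement.

Ligand molecules are visual/accounting agents: they carry no binding
kinetics and never decay (receptors are assumed saturated near releasing
cells). Each tick a ligand either takes a uniformly random step (with
probability ``l_randomness``) or drifts toward the neighboring patch with
the highest cell count — keeping molecules concentrated around the cells
interacting with them at the default speed of 0.25 patch units/tick. Steps
are clamped to the world bounds.
"""

from __future__ import annotations

import numpy as np

from .world import NEIGHBOR_UNITS, World

__all__ = ["ligand_step"]


def ligand_step(world: World) -> None:
    """Advance every ligand one step (current density fields)."""
    p = world.params
    m = world.n_ligands
    if m == 0 or p.ligand_speed == 0.0:
        return
    row, col = world.patch_indices(world.lx, world.ly)
    # walls read as -1 so a boundary ligand never drifts out of the world
    counts8 = world.neighbor_counts(world.cell_count, row, col, fill=-1)

    rand_mask = world.rng.random(m) < p.l_randomness
    angles = world.rng.uniform(0.0, 2.0 * np.pi, m)
    tiebreak = world.rng.random((8, m))

    keys = counts8.astype(np.float64) + tiebreak
    densest = np.argmax(keys, axis=0)

    dx = np.where(rand_mask, np.cos(angles), NEIGHBOR_UNITS[densest, 0])
    dy = np.where(rand_mask, np.sin(angles), NEIGHBOR_UNITS[densest, 1])
    world.lx, world.ly = world.clamp_positions(
        world.lx + dx * p.ligand_speed, world.ly + dy * p.ligand_speed
    )
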