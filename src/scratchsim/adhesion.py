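"""Spring-link adhesion network for the unreleased monolayer.

When cellular adhesion is enabled, unreleased neighboring cells are tied
by Hooke-like springs (NetLogo layout-spring style). Released cells carry
no links — shedding the surface ligand is what frees a cell from the pack
— and a red cell that reverts to blue regains links on the next rebuild.
The springs confine the monolayer "wiggle": each tick every linked cell is
displaced along the sum of restoring vectors, capped at its own per-tick
step length.

Rebuilding uses a k-d tree over the unreleased cells, so the cost per tick
is near-linear in monolayer size; adhesion-on runs are nonetheless much
slower than adhesion-off runs for a large monolayer, and shifting the
scratch line left (smaller monolayer) is the recommended mitigation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .world import World

__all__ = ["rebuild_links", "apply_springs"]

_SQRT2 = float(np.sqrt(2.0))


def rebuild_links(world: World) -> np.ndarray:
    """Recompute the link set: unreleased pairs within the link radius.

    Returns (and stores on the world) a (k, 2) array of cell-index pairs;
    at most one link per unordered pair, no self-links.
    """
    idx = np.flatnonzero(~world.released)
    if idx.size < 2:
        world.links = np.empty((0, 2), dtype=np.int64)
        return world.links
    pos = np.column_stack([world.x[idx], world.y[idx]])
    pairs = cKDTree(pos).query_pairs(r=world.params.link_radius, output_type="ndarray")
    world.links = idx[pairs].astype(np.int64)
    return world.links


def apply_springs(world: World) -> np.ndarray:
    """Displace linked cells along their net Hooke restoring vectors.

    Each link of extension ``distance − rest_length`` contributes
    ``spring_constant · extension`` along the connecting line, pulling the
    endpoints together when stretched and apart when compressed; the two
    endpoint displacements of a single link are equal and opposite. A
    cell's net displacement is capped at its per-tick step length. Returns
    the applied (n, 2) displacement array.
    """
    p = world.params
    disp = np.zeros((world.n_cells, 2))
    links = world.links
    if links.shape[0] == 0:
        return disp
    i, j = links[:, 0], links[:, 1]
    d = np.column_stack([world.x[j] - world.x[i], world.y[j] - world.y[i]])
    dist = np.linalg.norm(d, axis=1)
    ok = dist > 1e-12  # coincident endpoints give no direction to pull along
    force = np.zeros_like(d)
    force[ok] = (
        p.spring_constant * (dist[ok] - p.rest_length) / dist[ok]
    )[:, None] * d[ok]
    np.add.at(disp, i, force)
    np.add.at(disp, j, -force)

    cap = _SQRT2 * np.maximum(world.mu, 0.0) * p.dt_effective
    mag = np.linalg.norm(disp, axis=1)
    scale = np.ones_like(mag)
    over = mag > cap
    scale[over] = cap[over] / mag[over]
    disp *= scale[:, None]

    world.x, world.y = world.clamp_positions(
        world.x + disp[:, 0], world.y + disp[:, 1]
    )
    return disp
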