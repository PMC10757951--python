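"""Osteoid-to-mineral conversion and the latent TGF-beta pool.

Osteoid (deposited by osteoblasts, tracked in the same mg HA/cm^3 units as
mineral) converts to mineral at a fixed rate of 30 mg HA/cm^3/day, capped at
the cortical density of 720.  This transfer introduces the time-delay between
matrix deposition and the voxel becoming load-bearing/mineralised.  A
fraction of the mineralising matrix banks latent TGF-beta, which is released
into the free field when osteoclasts resorb the voxel.
"""

from __future__ import annotations

import numpy as np

from .config import MineralConfig
from .geometry import SimulationLattice

__all__ = ["mineralise", "release_tgfb"]


def mineralise(lattice: SimulationLattice, dt_h: float,
               config: MineralConfig | None = None) -> SimulationLattice:
    """Convert osteoid to mineral at the configured rate over ``dt_h`` hours."""
    if dt_h <= 0:
        raise ValueError("dt must be positive")
    config = config or MineralConfig()
    increment = config.rate_per_day * dt_h / 24.0
    room = np.maximum(config.density_cap - lattice.mineral, 0.0)
    transfer = np.minimum(np.minimum(lattice.osteoid, increment), room)
    lattice.osteoid -= transfer
    lattice.mineral += transfer
    lattice.tgfb_store += config.tgfb_banking_mol_per_density * transfer
    return lattice


def release_tgfb(lattice: SimulationLattice, voxel_flat: int,
                 tgfb_field: np.ndarray, voxel_volume_m3: float) -> None:
    """Release a resorbed voxel's stored latent TGF-beta into the free field."""
    stored = lattice.tgfb_store.ravel()[voxel_flat]
    if stored > 0:
        tgfb_field.ravel()[voxel_flat] += stored / voxel_volume_m3
        lattice.tgfb_store.ravel()[voxel_flat] = 0.0
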