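"""Lattice angiogenesis: VEGF-driven tip-cell extension, bifurcation,
anastomosis, and vessels as oxygen sources.

Tip cells are agents (they occupy lattice voxels); the trail a tip leaves
behind becomes stalk voxels flagged on the lattice (``occupancy == VESSEL``).
A segment graph (networkx, voxel flat indices as nodes) records connectivity
for loop counting and audits.  Vessel growth is purely chemotactic - it is
not gated by mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import MINERAL_THRESHOLD
from .config import VesselConfig
from .geometry import EMPTY, VESSEL, SimulationLattice
from .agents import AgentPopulation, TIP, MOBILE, _FACE_STEPS

__all__ = ["VesselNetwork", "extend_tips", "branch", "anastomose",
           "oxygen_sources", "vascular_volume"]


@dataclass
class VesselNetwork:
    """Tip agents + stalk voxels + segment graph."""

    pop: AgentPopulation
    graph: nx.Graph = field(default_factory=nx.Graph)
    loop_count: int = 0

    @classmethod
    def create(cls, pop: AgentPopulation) -> "VesselNetwork":
        net = cls(pop=pop)
        for r in pop.alive_rows(TIP):
            net.graph.add_node(int(pop.pos[r]), seed=True)
        return net

    @property
    def lattice(self) -> SimulationLattice:
        return self.pop.lattice

    def tip_rows(self) -> np.ndarray:
        return self.pop.alive_rows(TIP)

    def vessel_mask(self) -> np.ndarray:
        """Stalk voxels plus current tip positions."""
        mask = self.lattice.vessel.copy()
        mask.ravel()[self.pop.pos[self.tip_rows()]] = True
        return mask

    def to_edgelist(self):
        """Segment graph as a tabular edge list (voxel coordinates)."""
        import pandas as pd

        dims = self.lattice.dims
        rows = []
        for a, b in self.graph.edges:
            (ax, ay, az) = np.unravel_index(a, dims)
            (bx, by, bz) = np.unravel_index(b, dims)
            rows.append((ax, ay, az, bx, by, bz))
        return pd.DataFrame(rows, columns=["x0", "y0", "z0", "x1", "y1", "z1"])

    def audit_connectivity(self) -> bool:
        """Every vessel voxel reachable from a seed node."""
        seeds = [n for n, d in self.graph.nodes(data=True) if d.get("seed")]
        if not seeds:
            return self.graph.number_of_nodes() == 0
        reachable = set()
        for s in seeds:
            reachable |= nx.node_connected_component(self.graph, s)
        return reachable == set(self.graph.nodes)


def _admissible(lattice: SimulationLattice, nb: np.ndarray) -> np.ndarray:
    ok = nb >= 0
    safe = np.where(ok, nb, 0)
    ok &= lattice.mineral.ravel()[safe] <= MINERAL_THRESHOLD
    ok &= ~lattice.vessel.ravel()[safe]
    return ok


def extend_tips(net: VesselNetwork, vegf: np.ndarray, rng: np.random.Generator,
                config: VesselConfig | None = None) -> int:
    """Advance every tip one voxel by the three-way direction choice.

    With probabilities ``p_grad``/``p_persist``/``p_rand`` a tip follows the
    steepest local VEGF increase, its previous direction, or a random
    direction.  The vacated voxel becomes a stalk.  Tips below the
    sprout-maintenance VEGF level stay dormant.  A resident mobile cell in
    the destination voxel is displaced to a free neighbour (or removed).
    """
    config = config or VesselConfig()
    pop = net.pop
    lattice = net.lattice
    occ = lattice.occupancy.ravel()
    vegf_flat = vegf.ravel()
    moved = 0
    rows = pop.alive_rows(TIP)
    rows = rows[rng.permutation(rows.size)]
    for r in rows:
        src = pop.pos[r]
        if vegf_flat[src] < config.maintenance_vegf:
            continue
        if rng.random() >= config.move_probability:
            continue
        nb = pop.neighbours(np.array([src]))[0]
        ok = _admissible(lattice, nb)
        # disallow stepping onto another tip
        safe = np.where(nb >= 0, nb, 0)
        ok &= ~((occ[safe] >= 0) & (pop.type[np.maximum(occ[safe], 0)] == TIP) & (nb >= 0))
        if not ok.any():
            continue
        u = rng.random()
        choice = -1
        if u < config.p_grad:
            cand = np.flatnonzero(ok)
            choice = cand[np.argmax(vegf_flat[nb[cand]])]
        elif u < config.p_grad + config.p_persist and pop.prev_dir[r] >= 0 \
                and ok[pop.prev_dir[r]]:
            choice = int(pop.prev_dir[r])
        else:
            cand = np.flatnonzero(ok)
            choice = int(cand[rng.integers(cand.size)])
        dest = nb[choice]
        resident = occ[dest]
        if resident >= 0:
            if MOBILE[pop.type[resident]]:
                # push the resident to a free soft-tissue neighbour, else it dies
                rb = pop.neighbours(np.array([dest]))[0]
                rok = rb[(rb >= 0)]
                rok = rok[(occ[rok] == EMPTY)
                          & (lattice.mineral.ravel()[rok] <= MINERAL_THRESHOLD)
                          & ~lattice.vessel.ravel()[rok]]
                if rok.size:
                    new = rok[rng.integers(rok.size)]
                    occ[dest] = EMPTY
                    occ[new] = resident
                    pop.pos[resident] = new
                else:
                    pop.kill(np.array([resident]))
            else:
                continue
        # vacated voxel becomes stalk
        lattice.vessel.ravel()[src] = True
        lattice.osteoid.ravel()[src] = 0.0
        occ[src] = VESSEL
        occ[dest] = r
        pop.pos[r] = dest
        pop.prev_dir[r] = choice
        net.graph.add_edge(int(src), int(dest))
        moved += 1
    return moved


def branch(net: VesselNetwork, vegf: np.ndarray, rng: np.random.Generator,
           config: VesselConfig | None = None) -> int:
    """Spawn new tips by bifurcation at stalk voxels above the branching
    VEGF threshold, at the configured rate per stalk voxel per step."""
    config = config or VesselConfig()
    if config.branching_rate <= 0:
        return 0
    lattice = net.lattice
    pop = net.pop
    occ = lattice.occupancy.ravel()
    vegf_flat = vegf.ravel()
    stalks = np.flatnonzero(lattice.vessel.ravel())
    if stalks.size == 0:
        return 0
    eligible = stalks[vegf_flat[stalks] >= config.branching_vegf]
    if eligible.size == 0:
        return 0
    chosen = eligible[rng.random(eligible.size) < config.branching_rate]
    born = 0
    for s in chosen:
        nb = pop.neighbours(np.array([s]))[0]
        ok = _admissible(lattice, nb)
        safe = np.where(nb >= 0, nb, 0)
        ok &= (occ[safe] == EMPTY) & (nb >= 0)
        cand = np.flatnonzero(ok)
        if cand.size == 0:
            continue
        dest = nb[cand[rng.integers(cand.size)]]
        rows = pop.add(TIP, np.array([dest]))
        pop.prev_dir[rows] = -1
        net.graph.add_edge(int(s), int(dest))
        born += 1
    return born


def anastomose(net: VesselNetwork) -> int:
    """Fuse tips that touch the vessel network elsewhere: the tip becomes a
    stalk, an edge joins the segments, and the loop count increases by the
    number of independent cycles created."""
    pop = net.pop
    lattice = net.lattice
    occ = lattice.occupancy.ravel()
    fused = 0
    for r in net.tip_rows():
        p = pop.pos[r]
        nb = pop.neighbours(np.array([p]))[0]
        nb = nb[nb >= 0]
        touching = [int(v) for v in nb
                    if lattice.vessel.ravel()[v] and not net.graph.has_edge(int(p), int(v))]
        closed = 0
        for v in touching:
            if net.graph.has_node(int(p)) and net.graph.has_node(v) \
                    and nx.has_path(net.graph, int(p), v):
                closed += 1  # edge joins already-connected nodes: a new loop
            net.graph.add_edge(int(p), v)
        if touching:
            net.loop_count += closed
            # tip terminates: convert to stalk
            lattice.vessel.ravel()[p] = True
            occ[p] = VESSEL
            pop.alive[r] = False
            fused += 1
    return fused


def oxygen_sources(net: VesselNetwork, o2_field: np.ndarray,
                   config: VesselConfig | None = None) -> np.ndarray:
    """Hold vessel voxels at the normoxic oxygen set-point; returns the
    source mask."""
    config = config or VesselConfig()
    mask = net.vessel_mask()
    o2_field[mask] = np.maximum(o2_field[mask], config.o2_setpoint)
    return mask


def vascular_volume(vessel_mask: np.ndarray, voi: np.ndarray | None = None,
                    voxel_size_um: float = 10.5,
                    min_component: int = 2) -> tuple[float, float]:
    """Connected vascular volume (um^3) and VV/TV inside a VOI.

    Components are found under 26-connectivity; singletons are excluded from
    the "connected" count.
    """
    from scipy import ndimage

    labels, n = ndimage.label(vessel_mask, structure=np.ones((3, 3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())
    keep = np.zeros_like(vessel_mask)
    for lab in range(1, n + 1):
        if sizes[lab] >= min_component:
            keep |= labels == lab
    if voi is not None:
        keep &= voi
        tv = int(voi.sum())
    else:
        tv = vessel_mask.size
    count = int(keep.sum())
    vv_um3 = count * voxel_size_um ** 3
    return vv_um3, (count / tv if tv else 0.0)
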