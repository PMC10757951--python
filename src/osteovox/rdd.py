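"""Implicit (BTCS) reaction-diffusion-decay of cytokines and oxygen.

Each species obeys dc/dt = div(D grad c) - lambda*c on the voxel lattice with
Dirichlet values on the two longitudinal (z) faces and zero-flux (reflective)
lateral faces.  The backward-time centred-space step is unconditionally
stable, so the 30-min RDD substep can far exceed the explicit CFL limit.
Diffusivity is per-voxel and follows the mineral field: cytokines diffuse two
orders of magnitude slower through mineralised tissue, oxygen is unaffected.

The reaction step applies linear mass-action receptor-ligand kinetics on each
cell (dB/dt = k_on*c*(N-B) - k_off*B, with matching depletion/replenishment
of the local free ligand) and the OPG + RANKL -> RANKL-OPG ligand-ligand
complexation.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import factorized

from .config import RDDConfig, SpeciesConfig
from .geometry import SimulationLattice
from . import MINERAL_THRESHOLD

__all__ = [
    "CytokineState",
    "update_diffusivity",
    "step_diffusion_decay",
    "react",
    "secrete_and_consume",
    "build_btcs_matrix",
]

AVOGADRO = 6.02214076e23


@dataclass
class CytokineState:
    """Concentration fields (mol/m^3) plus per-species diffusivity maps.

    Species with identical diffusion/decay coefficients (all plain cytokines
    by default) share one system matrix and factorisation; their implicit
    steps are solved as a batched multi-RHS backsolve.
    """

    fields: dict[str, np.ndarray]
    diffusivity: dict[str, np.ndarray]       # um^2/s per voxel
    config: RDDConfig
    voxel_size_um: float
    boundary: str = "dirichlet-z"            # or "closed" (all reflective)
    _solvers: dict = field(default_factory=dict, repr=False)
    _map_version: int = 0

    @classmethod
    def create(cls, lattice: SimulationLattice, config: RDDConfig | None = None,
               boundary: str = "dirichlet-z") -> "CytokineState":
        config = config or RDDConfig()
        fields = {name: np.full(lattice.dims, sp.initial_value)
                  for name, sp in config.species.items()}
        state = cls(fields=fields, diffusivity={}, config=config,
                    voxel_size_um=lattice.voxel_size_um, boundary=boundary)
        update_diffusivity(state, lattice.mineral)
        return state

    @property
    def voxel_volume_m3(self) -> float:
        return (self.voxel_size_um * 1e-6) ** 3

    def invalidate(self, species: str | None = None) -> None:
        self._solvers.clear()

    def total_moles(self, species: str) -> float:
        return float(self.fields[species].sum()) * self.voxel_volume_m3

    def matrix_signature(self, species: str, dt_s: float):
        sp = self.config.species[species]
        return (sp.d_soft_um2_s, sp.d_mineral_um2_s, sp.decay_per_s, dt_s)


def update_diffusivity(state: CytokineState, mineral: np.ndarray) -> CytokineState:
    """Refresh per-voxel diffusivity maps from the current mineral field."""
    mineralised = mineral > MINERAL_THRESHOLD
    changed = False
    for name, sp in state.config.species.items():
        new = np.where(mineralised, sp.d_mineral_um2_s, sp.d_soft_um2_s)
        old = state.diffusivity.get(name)
        if old is None or not np.array_equal(old, new):
            state.diffusivity[name] = new
            changed = True
    if changed:
        state._map_version += 1
    return state


def build_btcs_matrix(diffusivity: np.ndarray, decay_per_s: float, dt_s: float,
                      voxel_size_um: float, boundary: str = "dirichlet-z") -> csr_matrix:
    """System matrix A such that A c_{n+1} = c_n (+ boundary terms).

    Fluxes use harmonic-mean face diffusivities, which makes the closed-domain
    operator exactly conservative.
    """
    dims = diffusivity.shape
    n = int(np.prod(dims))
    h2 = voxel_size_um ** 2                   # um^2; D in um^2/s -> 1/s
    idx = np.arange(n).reshape(dims)
    rows, cols, vals = [], [], []
    diag = np.full(n, 1.0 + decay_per_s * dt_s)

    dirichlet = np.zeros(dims, dtype=bool)
    if boundary == "dirichlet-z":
        dirichlet[:, :, 0] = True
        dirichlet[:, :, -1] = True
    dir_flat = dirichlet.ravel()

    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        d_lo = diffusivity[tuple(sl_lo)].ravel()
        d_hi = diffusivity[tuple(sl_hi)].ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            d_face = np.where(d_lo + d_hi > 0, 2 * d_lo * d_hi / (d_lo + d_hi), 0.0)
        w = d_face * dt_s / h2
        i_lo = idx[tuple(sl_lo)].ravel()
        i_hi = idx[tuple(sl_hi)].ravel()
        rows += [i_lo, i_hi]
        cols += [i_hi, i_lo]
        vals += [-w, -w]
        np.add.at(diag, i_lo, w)
        np.add.at(diag, i_hi, w)

    rows = np.concatenate(rows + [np.arange(n)])
    cols = np.concatenate(cols + [np.arange(n)])
    vals = np.concatenate(vals + [diag])
    keep = ~dir_flat[rows]                     # Dirichlet rows become identity
    A = csr_matrix((vals[keep], (rows[keep], cols[keep])), shape=(n, n))
    if dir_flat.any():
        d = np.flatnonzero(dir_flat)
        A += csr_matrix((np.ones(d.size), (d, d)), shape=(n, n))
    return A


def _get_solver(state: CytokineState, species: str, dt_s: float) -> dict:
    """Cached system matrix + LU for this species' coefficient signature.

    The factorisation follows the tissue-class (soft/mineralised) map; to
    avoid refactorising on every single threshold crossing during active
    mineralisation, the operator is rebuilt only once more than
    ``rebuild_threshold_voxels`` voxels have flipped class since the last
    factorisation.  Within that tolerance the solve is an exact BTCS step
    with a coefficient map that lags by at most that many voxels.
    """
    sig = state.matrix_signature(species, dt_s)
    mineralised = state.diffusivity[species] != state.config.species[species].d_soft_um2_s
    entry = state._solvers.get(sig)
    threshold = getattr(state.config, "rebuild_threshold_voxels", 32)
    if entry is not None and entry["version"] != state._map_version:
        drift = int(np.count_nonzero(entry["class_map"] != mineralised))
        if drift > threshold:
            entry = None
        else:
            entry["version"] = state._map_version
    if entry is None:
        A = build_btcs_matrix(state.diffusivity[species], sig[2], dt_s,
                              state.voxel_size_um, state.boundary)
        entry = {"A": A, "lu": factorized(A.tocsc()),
                 "class_map": mineralised.copy(),
                 "version": state._map_version}
        state._solvers[sig] = entry
    return entry


def _implicit_solve(entry: dict, rhs: np.ndarray, state: CytokineState) -> np.ndarray:
    """Solve A x = rhs (multi-RHS capable) with the cached factorisation."""
    return entry["lu"](rhs)


def step_diffusion_decay(state: CytokineState, species: str, dt_s: float) -> CytokineState:
    """One implicit step for one species (unconditionally stable)."""
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    sp: SpeciesConfig = state.config.species[species]
    entry = _get_solver(state, species, dt_s)
    c = state.fields[species]
    rhs = c.ravel().copy()
    if state.boundary == "dirichlet-z":
        rhs.reshape(c.shape)[:, :, 0] = sp.boundary_value
        rhs.reshape(c.shape)[:, :, -1] = sp.boundary_value
    out = _implicit_solve(entry, rhs, state).reshape(c.shape)
    np.maximum(out, 0.0, out=out)
    state.fields[species] = out
    return state


def step_all(state: CytokineState, dt_s: float) -> CytokineState:
    """One implicit step for every species, batching species that share a
    system matrix into one multi-RHS solve."""
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    groups: dict[tuple, list[str]] = {}
    for name in state.fields:
        groups.setdefault(state.matrix_signature(name, dt_s), []).append(name)
    for sig, names in groups.items():
        entry = _get_solver(state, names[0], dt_s)
        shape = state.fields[names[0]].shape
        rhs = np.stack([state.fields[n].ravel() for n in names], axis=1)
        if state.boundary == "dirichlet-z":
            r3 = rhs.reshape(*shape, len(names))
            for i, n in enumerate(names):
                bv = state.config.species[n].boundary_value
                r3[:, :, 0, i] = bv
                r3[:, :, -1, i] = bv
        out = _implicit_solve(entry, rhs, state)
        np.maximum(out, 0.0, out=out)
        for i, n in enumerate(names):
            state.fields[n] = out[:, i].reshape(shape).copy()
    return state


# ---------------------------------------------------------------------------
# reaction step


def react(state: CytokineState, population, dt_s: float) -> CytokineState:
    """Receptor-ligand binding on cells plus RANKL-OPG complexation.

    The per-cell linear binding ODE is advanced by its exact exponential
    relaxation (local ligand frozen over the step, consistent with the
    operator splitting); free-ligand pools are depleted/replenished to
    conserve ligand mass, with net binding capped by voxel availability.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    binding = state.config.binding
    V = state.voxel_volume_m3
    receptors = list(binding.receptors.values())
    if population is not None and population.n_alive > 0:
        pos = population.positions_alive()
        rec_occ = population.receptor_occupancy_alive()    # [n, n_receptors]
        for r_i, rc in enumerate(receptors):
            c_field = state.fields[rc.ligand]
            c_flat = c_field.ravel()
            c_local = c_flat[pos]
            B = rec_occ[:, r_i] * rc.n_sites
            # exact relaxation of dB/dt = k_on c (N-B) - k_off B with the
            # local ligand held constant over the step (operator splitting)
            rate = rc.k_on_m3_mol_s * c_local + rc.k_off_per_s
            B_eq = rc.n_sites * rc.k_on_m3_mol_s * c_local / rate
            dB = (B_eq - B) * (1.0 - np.exp(-rate * dt_s))
            # net binding cannot exceed the ligand available in the voxel
            dB = np.minimum(dB, c_local * AVOGADRO * V)
            dB = np.clip(dB, -B, rc.n_sites - B)
            B = B + dB
            # one cell per voxel -> positions are unique, direct update
            c_flat[pos] = np.maximum(c_local - dB / (AVOGADRO * V), 0.0)
            population.set_receptor_occupancy(r_i, np.clip(B / rc.n_sites, 0.0, 1.0))

    # ligand-ligand complexation: OPG + RANKL -> RANKL_OPG
    k = binding.rankl_opg_k_m3_mol_s
    if k > 0:
        cr = state.fields["RANKL"]
        co = state.fields["OPG"]
        dx = k * cr * co * dt_s
        dx = np.minimum(dx, np.minimum(cr, co))
        cr -= dx
        co -= dx
        state.fields["RANKL_OPG"] += dx
    return state


def secrete_and_consume(state: CytokineState, population, production_rates,
                        o2_consumption_mol_s: float, dt_s: float) -> CytokineState:
    """Apply per-cell secretion and oxygen consumption to the fields.

    ``production_rates`` maps species name -> per-alive-cell rates (mol/s).
    Oxygen is floored at zero and each cell's oxygen-sufficiency flag is set
    to (local O2 amount > per-step consumption).
    """
    if population is None or population.n_alive == 0:
        return state
    V = state.voxel_volume_m3
    pos = population.positions_alive()
    for species, rates in production_rates.items():
        if np.any(rates):
            # one cell per voxel -> positions unique, direct indexed add
            state.fields[species].ravel()[pos] += rates * dt_s / V

    o2 = state.fields["O2"].ravel()
    need = o2_consumption_mol_s * dt_s / V     # mol/m^3 removed per cell
    avail = o2[pos]
    # resolve multiple... a voxel hosts a single cell by construction
    sufficient = avail > need
    o2_new = np.maximum(avail - need, 0.0)
    o2[pos] = o2_new
    population.set_oxygen_sufficient(sufficient)
    return state
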