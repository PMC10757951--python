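"""Single-cell agents: migration, differentiation, population dynamics,
cytokine production, osteoid deposition and cluster-gated resorption.

Agents live in a structure-of-arrays table; each occupies exactly one lattice
voxel (``lattice.occupancy`` holds the agent's row index).  Soft-tissue
voxels (mineral <= 395 mg HA/cm^3) host SSPC, HSC, immune (M2) cells, OBL,
OCL, lining cells and vascular cells; mineralised voxels host only
pre-osteocytes and osteocytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import MINERAL_THRESHOLD
from .config import CellConfig, ProductionConfig, SignalThresholds
from .geometry import EMPTY, SimulationLattice

__all__ = [
    "SSPC", "HSC", "IMMUNE", "OBL", "OCL", "LINING", "PREOCY", "OCY", "TIP",
    "TYPE_NAMES", "AgentPopulation", "Environment",
    "migrate", "differentiate", "proliferate_or_die", "produce_cytokines",
    "deposit_osteoid", "resorb", "detect_clusters",
]

SSPC, HSC, IMMUNE, OBL, OCL, LINING, PREOCY, OCY, TIP = range(9)
TYPE_NAMES = ["SSPC", "HSC", "Immune", "OBL", "OCL", "Lining", "preOCY", "OCY", "Tip"]
N_TYPES = 9
RECEPTORS = ["RANK", "VEGFR", "TGFBR1", "LRP56"]
RANK, VEGFR, TGFBR1, LRP56 = range(4)

MOBILE = np.zeros(N_TYPES, dtype=bool)
MOBILE[[SSPC, HSC, IMMUNE, OBL, OCL, LINING]] = True
SOFT_ONLY = MOBILE.copy()
APOPTOTIC = np.zeros(N_TYPES, dtype=bool)
APOPTOTIC[[SSPC, HSC, IMMUNE, OBL, OCL]] = True
VEGF_PRODUCERS = np.zeros(N_TYPES, dtype=bool)
VEGF_PRODUCERS[[SSPC, IMMUNE, OBL, OCL, PREOCY, LINING]] = True

_FACE_STEPS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]])


class AgentPopulation:
    """Structure-of-arrays agent table bound to a lattice occupancy grid."""

    def __init__(self, lattice: SimulationLattice, capacity: int = 1024):
        self.lattice = lattice
        self.dims = lattice.dims
        self._grow_to(capacity)
        self.n = 0
        self.events: dict[str, int] = {}

    @classmethod
    def create(cls, lattice: SimulationLattice) -> "AgentPopulation":
        return cls(lattice)

    def _grow_to(self, capacity: int):
        for name, dtype, shape in [
            ("type", np.int8, (capacity,)),
            ("pos", np.int64, (capacity,)),
            ("recept", np.float64, (capacity, len(RECEPTORS))),
            ("age_h", np.float64, (capacity,)),
            ("prev_dir", np.int8, (capacity,)),
            ("alive", bool, (capacity,)),
            ("o2_ok", bool, (capacity,)),
        ]:
            old = getattr(self, name, None)
            new = np.zeros(shape, dtype=dtype)
            if name == "prev_dir":
                new[:] = -1
            if old is not None:
                new[: old.shape[0]] = old
            setattr(self, name, new)
        self.capacity = capacity

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_alive(self) -> int:
        return int(self.alive[: self.n].sum())

    def alive_rows(self, cell_type: int | None = None) -> np.ndarray:
        rows = np.flatnonzero(self.alive[: self.n])
        if cell_type is not None:
            rows = rows[self.type[rows] == cell_type]
        return rows

    def counts(self) -> dict[str, int]:
        rows = self.alive_rows()
        c = np.bincount(self.type[rows], minlength=N_TYPES)
        return {TYPE_NAMES[t]: int(c[t]) for t in range(N_TYPES)}

    def add(self, cell_type: int, flat_positions) -> np.ndarray:
        flat_positions = np.atleast_1d(np.asarray(flat_positions, dtype=np.int64))
        k = flat_positions.size
        if self.n + k > self.capacity:
            self._grow_to(max(2 * self.capacity, self.n + k))
        occ = self.lattice.occupancy.ravel()
        if np.any(occ[flat_positions] != EMPTY):
            raise ValueError("voxel already occupied")
        rows = np.arange(self.n, self.n + k)
        self.type[rows] = cell_type
        self.pos[rows] = flat_positions
        self.recept[rows] = 0.0
        self.age_h[rows] = 0.0
        self.prev_dir[rows] = -1
        self.alive[rows] = True
        self.o2_ok[rows] = False
        occ[flat_positions] = rows
        self.n += k
        return rows

    def kill(self, rows) -> None:
        rows = np.atleast_1d(rows)
        if rows.size == 0:
            return
        self.lattice.occupancy.ravel()[self.pos[rows]] = EMPTY
        self.alive[rows] = False

    def transition(self, rows, new_type: int) -> None:
        rows = np.atleast_1d(rows)
        self.type[rows] = new_type
        self.age_h[rows] = 0.0

    # -- views used by the RDD reaction step ------------------------------

    def positions_alive(self) -> np.ndarray:
        return self.pos[self.alive_rows()]

    def receptor_occupancy_alive(self) -> np.ndarray:
        return self.recept[self.alive_rows()]

    def set_receptor_occupancy(self, receptor_index: int, values: np.ndarray) -> None:
        self.recept[self.alive_rows(), receptor_index] = values

    def set_oxygen_sufficient(self, flags: np.ndarray) -> None:
        self.o2_ok[self.alive_rows()] = flags

    # -- geometry helpers --------------------------------------------------

    def neighbours(self, flat: np.ndarray) -> np.ndarray:
        """Face-adjacent flat indices, -1 outside the domain. [n, 6]"""
        nx, ny, nz = self.dims
        i, rem = np.divmod(flat, ny * nz)
        j, k = np.divmod(rem, nz)
        out = np.empty((flat.size, 6), dtype=np.int64)
        for d, (di, dj, dk) in enumerate(_FACE_STEPS):
            ii, jj, kk = i + di, j + dj, k + dk
            ok = (ii >= 0) & (ii < nx) & (jj >= 0) & (jj < ny) & (kk >= 0) & (kk < nz)
            out[:, d] = np.where(ok, (ii * ny + jj) * nz + kk, -1)
        return out

    def check_invariants(self) -> None:
        rows = self.alive_rows()
        occ = self.lattice.occupancy.ravel()
        if not np.array_equal(occ[self.pos[rows]], rows):
            raise AssertionError("occupancy grid out of sync with agent table")
        if np.unique(self.pos[rows]).size != rows.size:
            raise AssertionError("more than one agent in a voxel")
        mineralised = self.lattice.mineral.ravel()[self.pos[rows]] > MINERAL_THRESHOLD
        bad_hard = mineralised & ~np.isin(self.type[rows], (PREOCY, OCY))
        bad_soft = ~mineralised & np.isin(self.type[rows], (PREOCY, OCY))
        if bad_hard.any() or bad_soft.any():
            raise AssertionError("cell type incompatible with tissue class")

    def to_dataframe(self):
        import pandas as pd

        rows = self.alive_rows()
        nx, ny, nz = self.dims
        i, rem = np.divmod(self.pos[rows], ny * nz)
        j, k = np.divmod(rem, nz)
        data = {"id": rows, "type": [TYPE_NAMES[t] for t in self.type[rows]],
                "x": i, "y": j, "z": k, "age_h": self.age_h[rows]}
        for r_i, name in enumerate(RECEPTORS):
            data[f"occ_{name}"] = self.recept[rows, r_i]
        return pd.DataFrame(data)


@dataclass
class Environment:
    """Per-step view of the fields the behaviours read."""

    sed: np.ndarray                          # MPa, element field
    eff: np.ndarray
    cytokines: "object"                      # CytokineState
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)


def _local(fieldarr: np.ndarray, flat: np.ndarray) -> np.ndarray:
    return fieldarr.ravel()[flat]


# ---------------------------------------------------------------------------
# migration


def migrate(pop: AgentPopulation, lattice: SimulationLattice, env: Environment,
            rng: np.random.Generator, config: CellConfig | None = None) -> None:
    """One migration sub-step for all mobile agents (shuffled order).

    Mobile cells take one face-adjacent step within soft tissue; an occupied
    destination triggers a position swap, except OBL may never swap with OCL
    (and vice versa).  OCL drift up the RANKL gradient and OBL toward
    higher-EFF voxels with the configured bias probability; everyone else
    walks randomly.
    """
    config = config or CellConfig()
    rows = pop.alive_rows()
    rows = rows[MOBILE[pop.type[rows]]]
    if rows.size == 0:
        return
    move_mask = rng.random(rows.size) < config.migration_probability
    rows = rows[move_mask]
    if rows.size == 0:
        return
    rows = rows[rng.permutation(rows.size)]

    occ = lattice.occupancy.ravel()
    mineral = lattice.mineral.ravel()
    vessel = lattice.vessel.ravel()
    nbrs = pop.neighbours(pop.pos[rows])
    valid = (nbrs >= 0)
    nb_safe = np.where(valid, nbrs, 0)
    valid &= (mineral[nb_safe] <= MINERAL_THRESHOLD) & ~vessel[nb_safe]

    rankl = env.cytokines.fields["RANKL"].ravel() if env is not None else None
    eff = env.eff.ravel() if env is not None and env.eff is not None else None
    rand_dir = rng.integers(0, 6, size=rows.size)
    use_bias = rng.random(rows.size)

    for idx in range(rows.size):
        r = rows[idx]
        v = valid[idx]
        if not v.any():
            continue
        t = pop.type[r]
        choice = -1
        if t == OCL and rankl is not None and use_bias[idx] < config.ocl_bias_probability:
            cand = np.flatnonzero(v)
            choice = cand[np.argmax(rankl[nbrs[idx, cand]])]
        elif t == OBL and eff is not None and use_bias[idx] < config.obl_bias_probability:
            cand = np.flatnonzero(v)
            choice = cand[np.argmax(eff[nbrs[idx, cand]])]
        else:
            d = rand_dir[idx]
            if not v[d]:
                continue  # blocked random step: stay
            choice = d
        dest = nbrs[idx, choice]
        resident = occ[dest]
        src = pop.pos[r]
        if resident == EMPTY:
            occ[src] = EMPTY
            occ[dest] = r
            pop.pos[r] = dest
        elif resident >= 0:
            rt = pop.type[resident]
            if {t, rt} == {OBL, OCL}:
                continue  # OBL and OCL never swap
            if not MOBILE[rt]:
                continue
            occ[src], occ[dest] = resident, r
            pop.pos[r], pop.pos[resident] = dest, src
        # resident == VESSEL: blocked


# ---------------------------------------------------------------------------
# differentiation


def differentiate(pop: AgentPopulation, lattice: SimulationLattice, env: Environment,
                  rng: np.random.Generator, config: CellConfig | None = None,
                  dt_h: float | None = None) -> dict[str, int]:
    """Apply the differentiation map once; returns transition counts."""
    config = config or CellConfig()
    dt_h = config.dt_h if dt_h is None else dt_h
    thr = env.thresholds
    flows: dict[str, int] = {}
    mineral = lattice.mineral.ravel()
    sed = env.sed.ravel()
    eff = env.eff.ravel()

    def record(name, n):
        if n:
            flows[name] = flows.get(name, 0) + int(n)

    # SSPC -> OBL: oxygen-saturated, osteogenic mechanics, TGFBR1 engaged
    rows = pop.alive_rows(SSPC)
    if rows.size:
        p = pop.pos[rows]
        mech = (sed[p] > thr.sed_for_mpa) | (eff[p] > thr.eff_for)
        tgf = pop.recept[rows, TGFBR1] > config.tgfbr1_activation
        go = pop.o2_ok[rows] & mech & tgf
        pop.transition(rows[go], OBL)
        record("SSPC->OBL", go.sum())

    # SSPC/OBL lining mineral in a quiescent niche -> Lining
    surface = ndimage.binary_dilation(lattice.mineralised()).ravel()
    for src in (SSPC, OBL):
        rows = pop.alive_rows(src)
        if rows.size == 0:
            continue
        p = pop.pos[rows]
        on_surface = surface[p] & (mineral[p] <= MINERAL_THRESHOLD)
        quiescent = eff[p] <= thr.eff_for
        go = on_surface & quiescent & (rng.random(rows.size) < config.lining_probability)
        pop.transition(rows[go], LINING)
        record(f"{TYPE_NAMES[src]}->Lining", go.sum())

    # Lining -> OBL unless sclerostin occupies LRP5/6
    rows = pop.alive_rows(LINING)
    if rows.size:
        p = pop.pos[rows]
        go = (eff[p] > thr.eff_for) & (pop.recept[rows, LRP56] < config.lrp56_inhibition)
        pop.transition(rows[go], OBL)
        record("Lining->OBL", go.sum())

    # HSC -> OCL (oxygen-sufficient) and Immune -> OCL (even hypoxic)
    for src, need_o2 in ((HSC, True), (IMMUNE, False)):
        rows = pop.alive_rows(src)
        if rows.size == 0:
            continue
        go = pop.recept[rows, RANK] > config.rank_activation
        if need_o2:
            go &= pop.o2_ok[rows]
        pop.transition(rows[go], OCL)
        record(f"{TYPE_NAMES[src]}->OCL", go.sum())

    # OBL -> preOCY: own voxel mineralised, embedding rate, osteocyte-density gate
    rows = pop.alive_rows(OBL)
    if rows.size:
        p = pop.pos[rows]
        in_mineral = mineral[p] > MINERAL_THRESHOLD
        if in_mineral.any():
            ocy_mask = np.zeros(lattice.dims, dtype=bool)
            ocy_rows = pop.alive_rows()
            ocy_rows = ocy_rows[np.isin(pop.type[ocy_rows], (PREOCY, OCY))]
            ocy_mask.ravel()[pop.pos[ocy_rows]] = True
            w = 2 * config.ocy_gate_radius_vox + 1
            local_count = ndimage.uniform_filter(
                ocy_mask.astype(float), size=w, mode="constant") * w**3
            local_bone = ndimage.uniform_filter(
                lattice.mineralised().astype(float), size=w, mode="constant") * w**3
            # embed only while the osteocyte density of the local mineralised
            # tissue, counting the embedding cell itself, stays within the
            # calibration target
            target = config.ocy_target_per_mm3 * lattice.voxel_volume_mm3
            below = (local_count.ravel()[p] + 1.0
                     <= target * np.maximum(local_bone.ravel()[p], 1.0))
            embed = in_mineral & below & (rng.random(rows.size) < config.embedding_probability)
            pop.transition(rows[embed], PREOCY)
            record("OBL->preOCY", embed.sum())
            # OBL overtaken by the mineral front that do not embed step aside or die
            stuck = in_mineral & ~embed
            for r in rows[stuck]:
                nb = pop.neighbours(pop.pos[r][None])[0]
                ok = nb[(nb >= 0)]
                ok = ok[(mineral[ok] <= MINERAL_THRESHOLD)
                        & (lattice.occupancy.ravel()[ok] == EMPTY)
                        & ~lattice.vessel.ravel()[ok]]
                if ok.size:
                    dest = ok[rng.integers(ok.size)]
                    lattice.occupancy.ravel()[pop.pos[r]] = EMPTY
                    lattice.occupancy.ravel()[dest] = r
                    pop.pos[r] = dest
                else:
                    pop.kill(np.array([r]))
                    record("OBL engulfed", 1)

    # preOCY -> OCY after maturation
    rows = pop.alive_rows(PREOCY)
    if rows.size:
        go = pop.age_h[rows] >= config.maturation_h
        pop.transition(rows[go], OCY)
        record("preOCY->OCY", go.sum())

    pop.age_h[pop.alive_rows()] += dt_h
    return flows


# ---------------------------------------------------------------------------
# proliferation / apoptosis


def proliferate_or_die(pop: AgentPopulation, lattice: SimulationLattice,
                       env: Environment, rng: np.random.Generator,
                       config: CellConfig | None = None) -> dict[str, int]:
    """Stochastic division (SSPC/HSC) and spontaneous apoptosis."""
    config = config or CellConfig()
    dt = config.dt_h
    flows: dict[str, int] = {"births": 0, "deaths": 0}
    occ = lattice.occupancy.ravel()
    mineral = lattice.mineral.ravel()
    vessel = lattice.vessel.ravel()
    eff = env.eff.ravel()
    thr = env.thresholds

    # apoptosis first (freed voxels can host daughters this same step)
    rows = pop.alive_rows()
    rows = rows[APOPTOTIC[pop.type[rows]]]
    if rows.size:
        rate = np.array([config.apoptosis_per_h.get(TYPE_NAMES[t], 0.0)
                         for t in pop.type[rows]])
        dies = rng.random(rows.size) < rate * dt
        pop.kill(rows[dies])
        flows["deaths"] = int(dies.sum())

    for src in (SSPC, HSC):
        rows = pop.alive_rows(src)
        if rows.size == 0:
            continue
        p = pop.pos[rows]
        favourable = pop.o2_ok[rows] & (eff[p] > thr.eff_for)
        divides = favourable & (rng.random(rows.size) < config.proliferation_per_h * dt)
        for r in rows[divides]:
            nb = pop.neighbours(pop.pos[r][None])[0]
            ok = nb[nb >= 0]
            ok = ok[(occ[ok] == EMPTY) & (mineral[ok] <= MINERAL_THRESHOLD) & ~vessel[ok]]
            if ok.size:
                pop.add(src, np.array([ok[rng.integers(ok.size)]]))
                flows["births"] += 1
    return flows


# ---------------------------------------------------------------------------
# cytokine production


def produce_cytokines(pop: AgentPopulation, env: Environment,
                      config: ProductionConfig | None = None,
                      o2_need: float = 0.0) -> dict[str, np.ndarray]:
    """Per-alive-cell secretion rates (mol/s) for every species.

    Osteocytes couple RANKL/Scl (decreasing) and OPG (increasing) to local
    SED; OBL and lining cells couple RANKL/OPG to local EFF; VEGF follows the
    oxygen deficit; immune cells secrete TGF-beta at a constant rate.
    """
    config = config or ProductionConfig()
    rows = pop.alive_rows()
    t = pop.type[rows]
    p = pop.pos[rows]
    sed = env.sed.ravel()[p]
    eff = env.eff.ravel()[p]
    n = rows.size
    rates = {s: np.zeros(n) for s in ("VEGF", "RANKL", "OPG", "Scl", "TGFb")}

    is_ocy = t == OCY
    sed_rel = sed / config.sed_ref_mpa
    rates["RANKL"][is_ocy] = config.ocy_rankl_base * np.maximum(0.0, 1.0 - sed_rel[is_ocy])
    rates["Scl"][is_ocy] = config.ocy_scl_base * np.maximum(0.0, 1.0 - sed_rel[is_ocy])
    rates["OPG"][is_ocy] = config.ocy_opg_base * np.maximum(0.0, sed_rel[is_ocy])

    is_surface = (t == OBL) | (t == LINING)
    eff_rel = eff / config.eff_ref
    rates["RANKL"][is_surface] = config.obl_rankl_base * np.maximum(0.0, 1.0 - eff_rel[is_surface])
    rates["OPG"][is_surface] = config.obl_opg_base * np.maximum(0.0, eff_rel[is_surface])

    producers = VEGF_PRODUCERS[t]
    if o2_need > 0:
        o2 = env.cytokines.fields["O2"].ravel()[p]
        fulfilment = np.minimum(o2 / o2_need, 1.0)
    else:
        fulfilment = pop.o2_ok[rows].astype(float)
    rates["VEGF"][producers] = config.vegf_max * (1.0 - fulfilment[producers])

    rates["TGFb"][t == IMMUNE] = config.immune_tgfb
    return rates


# ---------------------------------------------------------------------------
# matrix deposition and resorption


def _softmax_choice(weights: np.ndarray, rng: np.random.Generator, beta: float) -> int:
    w = np.asarray(weights, dtype=float)
    w = w - w.max()
    prob = np.exp(beta * w)
    prob /= prob.sum()
    return int(rng.choice(w.size, p=prob))


def deposit_osteoid(pop: AgentPopulation, lattice: SimulationLattice,
                    env: Environment, rng: np.random.Generator,
                    config: CellConfig | None = None) -> int:
    """OBL above the osteogenic EFF threshold lay osteoid in their own voxel
    plus one strain-polarised neighbour (never into vessel voxels)."""
    config = config or CellConfig()
    thr = env.thresholds
    rows = pop.alive_rows(OBL)
    if rows.size == 0:
        return 0
    eff = env.eff.ravel()
    p = pop.pos[rows]
    active = eff[p] > thr.eff_for
    rows, p = rows[active], p[active]
    if rows.size == 0:
        return 0
    mineral = lattice.mineral.ravel()
    osteoid = lattice.osteoid.ravel()
    vessel = lattice.vessel.ravel()
    inc = config.osteoid_increment
    beta = config.polarisation_beta
    nbrs = pop.neighbours(p)
    valid = nbrs >= 0
    safe = np.where(valid, nbrs, 0)
    valid &= (mineral[safe] <= MINERAL_THRESHOLD) & ~vessel[safe]

    # own voxel (positions are unique: one OBL per voxel)
    osteoid[p] = np.minimum(osteoid[p] + inc, np.maximum(720.0 - mineral[p], 0.0))

    # softmax polarisation over neighbour EFF via the Gumbel-max trick
    scale = max(env.thresholds.eff_for, 1e-12)
    logits = np.where(valid, beta * eff[safe] / scale, -np.inf)
    logits = logits + rng.gumbel(size=logits.shape)
    has_tgt = valid.any(axis=1)
    tgt = nbrs[np.arange(rows.size), np.argmax(logits, axis=1)][has_tgt]
    # several OBL may polarise to the same voxel: accumulate then cap
    add = np.bincount(tgt, weights=np.full(tgt.size, inc), minlength=osteoid.size)
    nz = np.flatnonzero(add)
    osteoid[nz] = np.minimum(osteoid[nz] + add[nz],
                             np.maximum(720.0 - mineral[nz], 0.0))
    return int(rows.size)


def detect_clusters(pop_or_positions, dims=None) -> list[np.ndarray]:
    """Connected components (face adjacency) of OCL positions, size >= 3."""
    if isinstance(pop_or_positions, AgentPopulation):
        pop = pop_or_positions
        positions = pop.pos[pop.alive_rows(OCL)]
        dims = pop.dims
    else:
        positions = np.asarray(pop_or_positions, dtype=np.int64)
    mask = np.zeros(dims, dtype=bool)
    mask.ravel()[positions] = True
    labels, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    flat = labels.ravel()
    clusters = []
    for lab in range(1, n + 1):
        members = np.flatnonzero(flat == lab)
        if members.size >= 3:
            clusters.append(members)
    return clusters


def resorb(pop: AgentPopulation, lattice: SimulationLattice, env: Environment,
           rng: np.random.Generator, config: CellConfig | None = None,
           sed_gradient: np.ndarray | None = None) -> int:
    """Cluster-gated resorption: each OCL cluster (>= 3, mean RANK occupancy
    > 50%) may remove one adjacent mineralised voxel inside the osteolytic
    window (SED < SED_RES), polarised toward minimal SED-gradient magnitude.
    Stored latent TGF-beta is released to the field."""
    config = config or CellConfig()
    thr = env.thresholds
    clusters = detect_clusters(pop)
    if not clusters:
        return 0
    mineral = lattice.mineral.ravel()
    sed = env.sed.ravel()
    if sed_gradient is None:
        g = np.gradient(env.sed)
        sed_gradient = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
    grad = sed_gradient.ravel()
    occ = lattice.occupancy.ravel()
    V = lattice.voxel_volume_m3
    resorbed = 0
    # map voxel -> agent row for RANK occupancy lookup
    for members in clusters:
        agent_rows = occ[members]
        agent_rows = agent_rows[agent_rows >= 0]
        if agent_rows.size == 0:
            continue
        if pop.recept[agent_rows, RANK].mean() <= config.rank_activation:
            continue
        if rng.random() >= config.resorption_probability:
            continue
        nb = pop.neighbours(members).ravel()
        nb = np.unique(nb[nb >= 0])
        cand = nb[(mineral[nb] > MINERAL_THRESHOLD) & (sed[nb] < thr.sed_res_mpa)]
        if cand.size == 0:
            continue
        scale = max(grad[cand].max(), 1e-30)
        j = _softmax_choice(-grad[cand] / scale, rng, config.polarisation_beta)
        voxel = cand[j]
        from .mineral import release_tgfb

        release_tgfb(lattice, voxel, env.cytokines.fields["TGFb"], V)
        mineral[voxel] = 0.0
        lattice.osteoid.ravel()[voxel] = 0.0
        resident = occ[voxel]
        if resident >= 0:  # embedded (pre-)osteocyte is resorbed with its matrix
            pop.kill(np.array([resident]))
        resorbed += 1
    return resorbed
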