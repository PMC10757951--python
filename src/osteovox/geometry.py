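"""Lattice container, synthetic osteotomy phantoms, VOI masks, seeding, volume I/O.

Axis convention: arrays are indexed ``[x, y, z]`` with ``z`` the longitudinal
(proximal -> distal) axis; voxel centres sit at ``(i + 1/2) * voxel_size``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from . import MINERAL_MAX, MINERAL_THRESHOLD, VOXEL_SIZE_UM
from .config import PhantomSpec, SeedingPlan

__all__ = [
    "SimulationLattice",
    "VOIMasks",
    "build_phantom",
    "make_vois",
    "make_haematoma",
    "periosteum_mask",
    "endosteum_mask",
    "read_volume",
    "write_volume",
    "initialise",
]

# occupancy sentinel values
EMPTY = -1
VESSEL = -2


@dataclass
class SimulationLattice:
    """Voxel grid holding the physical state shared by all sub-models.

    ``occupancy`` stores the row index of the resident agent in the agent
    table, ``EMPTY`` for free voxels and ``VESSEL`` for vessel (stalk) voxels.
    """

    mineral: np.ndarray                      # mg HA/cm^3, float64 [nx,ny,nz]
    osteoid: np.ndarray                      # mg HA/cm^3-equivalent
    occupancy: np.ndarray                    # int32 agent ids
    vessel: np.ndarray                       # bool
    tgfb_store: np.ndarray                   # mol, latent TGF-beta per voxel
    voxel_size_um: float = VOXEL_SIZE_UM

    @classmethod
    def empty(cls, dims: tuple[int, int, int], voxel_size_um: float = VOXEL_SIZE_UM):
        return cls(
            mineral=np.zeros(dims),
            osteoid=np.zeros(dims),
            occupancy=np.full(dims, EMPTY, dtype=np.int32),
            vessel=np.zeros(dims, dtype=bool),
            tgfb_store=np.zeros(dims),
            voxel_size_um=voxel_size_um,
        )

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.mineral.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um * 1e-3) ** 3

    @property
    def voxel_volume_m3(self) -> float:
        return (self.voxel_size_um * 1e-6) ** 3

    def mineralised(self) -> np.ndarray:
        return self.mineral > MINERAL_THRESHOLD

    def copy(self) -> "SimulationLattice":
        return SimulationLattice(
            self.mineral.copy(), self.osteoid.copy(), self.occupancy.copy(),
            self.vessel.copy(), self.tgfb_store.copy(), self.voxel_size_um,
        )

    def check_invariants(self) -> None:
        if self.mineral.min() < 0 or self.mineral.max() > MINERAL_MAX + 1e-9:
            raise AssertionError("mineral density out of [0, 720]")
        if np.any(self.vessel & (self.osteoid > 0)):
            raise AssertionError("vessel voxels must carry no osteoid")
        if np.any(self.vessel & (self.occupancy >= 0)):
            raise AssertionError("vessel voxel also hosts an agent")


@dataclass
class VOIMasks:
    """Volumes of interest: defect centre/periphery, fragment centre/periphery."""

    DC: np.ndarray
    DP: np.ndarray
    FC: np.ndarray
    FP: np.ndarray

    @property
    def TOT(self) -> np.ndarray:
        return self.DC | self.DP | self.FC | self.FP

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"DC": self.DC, "DP": self.DP, "FC": self.FC, "FP": self.FP}


def _vox(length_um: float, voxel_size_um: float) -> int:
    return int(round(length_um / voxel_size_um))


def build_phantom(spec: PhantomSpec) -> SimulationLattice:
    """Deterministically voxelise a hollow-cylinder osteotomy phantom.

    Two cortical fragments at cortical density are separated by a transverse
    gap; marrow, gap and surroundings start at density zero.
    """
    spec.validate()
    h = spec.voxel_size_um
    r_out = spec.outer_radius_um / h
    r_in = spec.inner_radius_um / h
    n_frag = _vox(spec.fragment_length_um, h)
    n_gap = _vox(spec.gap_width_um, h)
    n_per = _vox(spec.periosteum_um, h)
    n_mxy = _vox(spec.margin_xy_um, h)
    n_mz = _vox(spec.margin_z_um, h)
    half = int(np.ceil(r_out)) + n_per + n_mxy
    nx = ny = 2 * half
    nz = 2 * n_frag + n_gap + 2 * n_mz
    if n_gap >= nz:
        raise ValueError("gap wider than domain")

    lat = SimulationLattice.empty((nx, ny, nz), h)
    cx = cy = nx / 2.0
    xs = np.arange(nx) + 0.5
    ys = np.arange(ny) + 0.5
    rr = np.hypot(xs[:, None] - cx, ys[None, :] - cy)
    annulus = (rr <= r_out) & (rr > r_in)
    z = np.arange(nz)
    proximal = (z >= n_mz) & (z < n_mz + n_frag)
    distal = (z >= n_mz + n_frag + n_gap) & (z < n_mz + 2 * n_frag + n_gap)
    fragment_z = proximal | distal
    lat.mineral[:, :, fragment_z] = np.where(annulus, spec.cortical_density, 0.0)[:, :, None]
    return lat


def _radial_grid(dims) -> np.ndarray:
    nx, ny = dims[0], dims[1]
    xs = np.arange(nx) + 0.5
    ys = np.arange(ny) + 0.5
    return np.hypot(xs[:, None] - nx / 2.0, ys[None, :] - ny / 2.0)


def _gap_slices(lattice: SimulationLattice) -> np.ndarray:
    """z indices with no mineralised bone, between the two fragments."""
    has_bone = (lattice.mineral > MINERAL_THRESHOLD).any(axis=(0, 1))
    bone_z = np.flatnonzero(has_bone)
    if bone_z.size == 0:
        raise ValueError("no mineralised tissue: cannot identify an osteotomy gap")
    interior = np.arange(bone_z[0], bone_z[-1] + 1)
    gap = interior[~has_bone[interior]]
    if gap.size == 0:
        raise ValueError("no identifiable gap between the cortical fragments")
    return gap


def make_vois(lattice: SimulationLattice, callus_margin_um: float = 105.0) -> VOIMasks:
    """Construct the four VOIs from a POD 0 geometry.

    DC/DP split the gap-spanning slab into the region inside the cortical
    envelope (endosteal + cortical footprint) and a periosteal shell of
    ``callus_margin_um``; FC/FP do the same at fragment level.
    """
    gap_z = _gap_slices(lattice)
    bone = lattice.mineral > MINERAL_THRESHOLD
    rr = _radial_grid(lattice.dims)
    r_out = rr[bone.any(axis=2)].max()
    r_cal = r_out + callus_margin_um / lattice.voxel_size_um

    nz = lattice.dims[2]
    frag_z = np.zeros(nz, dtype=bool)
    frag_z[bone.any(axis=(0, 1))] = True
    gap_mask_z = np.zeros(nz, dtype=bool)
    gap_mask_z[gap_z] = True

    inner = rr <= r_out
    shell = (rr > r_out) & (rr <= r_cal)
    DC = inner[:, :, None] & gap_mask_z[None, None, :]
    DP = shell[:, :, None] & gap_mask_z[None, None, :]
    FC = inner[:, :, None] & frag_z[None, None, :]
    FP = shell[:, :, None] & frag_z[None, None, :]
    return VOIMasks(DC=DC, DP=DP, FC=FC, FP=FP)


def make_haematoma(defect_centre: np.ndarray, dilation_um: float = 210.0,
                   voxel_size_um: float = VOXEL_SIZE_UM) -> np.ndarray:
    """Dilate the defect-centre mask by a Euclidean ball (default 210 um)."""
    if not defect_centre.any():
        raise ValueError("defect-centre mask is empty")
    radius = dilation_um / voxel_size_um
    if radius <= 0:
        return defect_centre.copy()
    dist = ndimage.distance_transform_edt(~defect_centre)
    return dist <= radius


def periosteum_mask(lattice: SimulationLattice, thickness_um: float = 52.5) -> np.ndarray:
    """Outward shell of the cortical surface (default 5 voxels thick)."""
    bone = lattice.mineral > MINERAL_THRESHOLD
    n = _vox(thickness_um, lattice.voxel_size_um)
    grown = ndimage.binary_dilation(bone, ndimage.generate_binary_structure(3, 1), iterations=n)
    # exclude the medullary side: keep only voxels radially outside the cortex
    rr = _radial_grid(lattice.dims)
    r_out_z = np.zeros(lattice.dims[2])
    for k in range(lattice.dims[2]):
        if bone[:, :, k].any():
            r_out_z[k] = rr[bone[:, :, k]].mean()
    r_ref = r_out_z[r_out_z > 0].mean() if (r_out_z > 0).any() else 0.0
    return grown & ~bone & (rr[:, :, None] > r_ref)


def endosteum_mask(lattice: SimulationLattice) -> np.ndarray:
    """One-voxel inward (medullary) shell of the cortical surface."""
    bone = lattice.mineral > MINERAL_THRESHOLD
    grown = ndimage.binary_dilation(bone, ndimage.generate_binary_structure(3, 1))
    rr = _radial_grid(lattice.dims)
    r_out_z = rr[bone.any(axis=2)].mean() if bone.any() else 0.0
    return grown & ~bone & (rr[:, :, None] <= r_out_z)


def marrow_mask(lattice: SimulationLattice) -> np.ndarray:
    """Medullary cavity: soft tissue radially inside the cortex at fragment levels."""
    bone = lattice.mineral > MINERAL_THRESHOLD
    frag_z = bone.any(axis=(0, 1))
    rr = _radial_grid(lattice.dims)
    r_in = rr[bone.any(axis=2)].min() if bone.any() else 0.0
    return (~bone) & (rr[:, :, None] < r_in) & frag_z[None, None, :]


# ---------------------------------------------------------------------------
# volume I/O

def write_volume(array: np.ndarray, path, voxel_size_um: float = VOXEL_SIZE_UM) -> None:
    """Write a density (or any scalar) field as MetaImage/NIfTI with spacing."""
    if array.ndim != 3:
        raise ValueError("expected a 3D volume")
    img = sitk.GetImageFromArray(np.ascontiguousarray(array.T))  # sitk is z,y,x
    mm = voxel_size_um * 1e-3
    img.SetSpacing((mm, mm, mm))
    sitk.WriteImage(img, str(path))


def read_volume(path, expected_voxel_um: float | None = VOXEL_SIZE_UM):
    """Read a density volume; returns ``(array, voxel_size_um)``.

    Spacing metadata from the file wins over the configured voxel size (a
    warning is emitted on mismatch).
    """
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError("expected a 3D volume")
    spacing = img.GetSpacing()
    if max(spacing) - min(spacing) > 1e-9 * max(spacing):
        raise ValueError("anisotropic spacing is not supported")
    voxel_um = spacing[0] * 1e3
    if expected_voxel_um is not None and abs(voxel_um - expected_voxel_um) > 1e-6:
        warnings.warn(
            f"file spacing {voxel_um:.4f} um differs from configured "
            f"{expected_voxel_um:.4f} um; using the file's spacing", stacklevel=2)
    return sitk.GetArrayFromImage(img).T.astype(float), voxel_um


def lattice_from_volume(path) -> SimulationLattice:
    arr, voxel_um = read_volume(path)
    lat = SimulationLattice.empty(arr.shape, voxel_um)
    lat.mineral[:] = np.clip(arr, 0.0, MINERAL_MAX)
    return lat


# ---------------------------------------------------------------------------
# initial condition

def initialise(lattice: SimulationLattice, plan: SeedingPlan, rng_seed,
               rdd_config=None, thresholds=None):
    """Seed agents and chemical fields on a POD 0 lattice.

    Order of events: fields set (haematoma multipliers applied), an RDD
    pre-run of ``plan.prerun_iterations`` implicit steps equilibrates the
    fields, then cells are placed uniformly at random within their regions
    with all receptors unbound.  Returns ``(population, cytokine_state,
    haematoma_mask)``.
    """
    from . import agents as agents_mod
    from . import rdd as rdd_mod
    from .config import RDDConfig

    rng = np.random.default_rng(rng_seed)
    rdd_config = rdd_config or RDDConfig()

    vois = make_vois(lattice)
    haem = make_haematoma(vois.DC, voxel_size_um=lattice.voxel_size_um)
    # haematoma is soft tissue only
    haem &= ~lattice.mineralised()

    state = rdd_mod.CytokineState.create(lattice, rdd_config)
    state.fields["VEGF"][haem] *= plan.vegf_haematoma_multiplier
    state.fields["O2"][haem] *= plan.o2_haematoma_multiplier
    state.fields["O2"][~haem] = plan.o2_background

    for _ in range(plan.prerun_iterations):
        rdd_mod.step_all(state, rdd_config.dt_s)

    pop = agents_mod.AgentPopulation.create(lattice)
    peri = periosteum_mask(lattice) & ~haem
    marrow = marrow_mask(lattice)
    bone = lattice.mineralised()

    def seed(mask, fraction, cell_type):
        free = np.flatnonzero(mask.ravel() & (lattice.occupancy.ravel() == EMPTY))
        n = int(round(fraction * free.size))
        if n > free.size:
            raise ValueError(f"requested density exceeds free voxels for {cell_type}")
        if n > 0:
            chosen = rng.choice(free, size=n, replace=False)
            pop.add(cell_type, chosen)

    seed(peri, plan.sspc_periosteum_fraction, agents_mod.SSPC)
    seed(haem, plan.sspc_haematoma_fraction, agents_mod.SSPC)
    seed(haem, plan.immune_haematoma_fraction, agents_mod.IMMUNE)
    seed(marrow, plan.hsc_marrow_fraction, agents_mod.HSC)
    surface = ndimage.binary_dilation(bone) & ~bone
    seed(surface, plan.lining_fraction, agents_mod.LINING)

    # osteocytes inside mineralised tissue at the target density
    ocy_frac = plan.ocy_density_per_mm3 * lattice.voxel_volume_mm3
    bone_vox = np.flatnonzero(bone.ravel())
    n_ocy = int(round(ocy_frac * bone_vox.size))
    if n_ocy > 0:
        pop.add(agents_mod.OCY, rng.choice(bone_vox, size=min(n_ocy, bone_vox.size),
                                           replace=False))

    # endothelial tip cells on periosteal+endosteal surfaces at both ends
    tip_region = (periosteum_mask(lattice) | endosteum_mask(lattice)) & ~bone
    nz = lattice.dims[2]
    zgrid = np.arange(nz)[None, None, :]
    frag_z = bone.any(axis=(0, 1))
    gap = _gap_slices(lattice)
    ends = tip_region & ((zgrid < gap[0]) | (zgrid > gap[-1])) & frag_z[None, None, :]
    free = np.flatnonzero(ends.ravel() & (lattice.occupancy.ravel() == EMPTY))
    if free.size < plan.n_tip_cells:
        raise ValueError("not enough free surface voxels for the configured tip cells")
    tips = rng.choice(free, size=plan.n_tip_cells, replace=False)
    pop.add(agents_mod.TIP, tips)

    return pop, state, haem
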