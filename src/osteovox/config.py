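"""Model configuration: every tunable parameter of the simulator.

Parameters are grouped per sub-model and carry explicit units in their names
(``_um`` micrometres, ``_mpa`` megapascal, ``_per_h`` 1/hour, ...).  Anchored
values (density-modulus map, strain thresholds, peak ambulatory force,
fixator stiffness, mineralisation rate, timesteps, oxygen set-point) default
to the murine femoral-osteotomy setting; rate constants that are not
experimentally pinned down are calibration knobs and documented as such in
``docs/methods.md``.  Any field can be overridden from a TOML file.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import MINERAL_MAX, MINERAL_THRESHOLD, VOXEL_SIZE_UM

__all__ = [
    "PhantomSpec",
    "SeedingPlan",
    "MaterialMap",
    "LoadSpec",
    "SignalThresholds",
    "MechanicsConfig",
    "SpeciesConfig",
    "ReceptorConfig",
    "BindingConfig",
    "RDDConfig",
    "CellConfig",
    "ProductionConfig",
    "VesselConfig",
    "MineralConfig",
    "SimConfig",
    "load_config",
]


@dataclass
class PhantomSpec:
    """Synthetic femur-osteotomy phantom: two hollow cortical cylinders
    separated by a transverse gap, wrapped in a periosteal layer."""

    outer_radius_um: float = 84.0
    inner_radius_um: float = 52.5
    fragment_length_um: float = 189.0
    gap_width_um: float = 84.0
    periosteum_um: float = 52.5          # 5 voxels
    haematoma_dilation_um: float = 210.0  # 20 voxels
    margin_xy_um: float = 42.0
    margin_z_um: float = 42.0
    voxel_size_um: float = VOXEL_SIZE_UM
    cortical_density: float = MINERAL_MAX

    def validate(self) -> None:
        if self.gap_width_um <= 0:
            raise ValueError("gap_width_um must be positive")
        if self.inner_radius_um >= self.outer_radius_um:
            raise ValueError("inner radius must be smaller than outer radius")
        n_per = self.periosteum_um / self.voxel_size_um
        if n_per <= 0 or abs(n_per - round(n_per)) > 1e-9:
            raise ValueError("periosteum thickness must be a positive voxel multiple")


@dataclass
class SeedingPlan:
    """Initial cell seeding densities and field multipliers (POD 0)."""

    sspc_periosteum_fraction: float = 0.5    # of free periosteal voxels
    sspc_haematoma_fraction: float = 0.10
    immune_haematoma_fraction: float = 0.10
    hsc_marrow_fraction: float = 0.05
    lining_fraction: float = 0.2             # of bone-surface soft voxels
    ocy_density_per_mm3: float = 44_800.0    # in mineralised tissue
    n_tip_cells: int = 200
    vegf_haematoma_multiplier: float = 5.0
    o2_haematoma_multiplier: float = 5.0
    o2_background: float = 0.065             # mol/m^3
    prerun_iterations: int = 48              # 1 day of RDD before seeding


@dataclass
class MaterialMap:
    """Linear density-to-modulus interpolation with a soft-tissue floor."""

    density_low: float = MINERAL_THRESHOLD   # mg HA/cm^3
    density_high: float = MINERAL_MAX
    e_low_mpa: float = 4000.0
    e_high_mpa: float = 14000.0
    e_soft_mpa: float = 3.0
    poisson: float = 0.3


@dataclass
class LoadSpec:
    """Boundary-condition protocol for the micro-FE solve."""

    protocol: str = "ambulatory"             # or "apparent_stiffness"
    displacement_fraction: float = 0.01      # 1% of length for stiffness protocol
    target_force_n: float = 10.5             # peak ambulatory force F_w
    fixator_stiffness_n_mm: float = 23.8     # k_f
    fixator_offset_um: float = 3000.0        # distance d from axis to fixator plane
    bending_beta: float = 1.0


@dataclass
class SignalThresholds:
    sed_for_mpa: float = 0.008
    eff_for: float = 0.008
    sed_res_mpa: float = 0.015
    eff_res: float = 0.015


@dataclass
class MechanicsConfig:
    material: MaterialMap = field(default_factory=MaterialMap)
    load: LoadSpec = field(default_factory=LoadSpec)
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    gaussian_sigma: float = 1.0
    gaussian_support: float = 0.8            # truncation radius = ceil(support/sigma) voxels
    solver: str = "auto"                     # direct | mgcg | auto
    cg_rtol: float = 1e-6
    direct_max_dof: int = 40_000
    mg_refresh_steps: int = 4                # reuse the MG preconditioner this long


@dataclass
class SpeciesConfig:
    """Diffusion-decay parameters for one chemical species."""

    name: str
    d_soft_um2_s: float
    d_mineral_um2_s: float
    decay_per_s: float
    boundary_value: float                    # Dirichlet value on z faces, mol/m^3
    initial_value: float


def _default_species() -> dict[str, SpeciesConfig]:
    cyt = dict(d_soft_um2_s=100.0, d_mineral_um2_s=1.0, decay_per_s=1e-4)
    return {
        "VEGF": SpeciesConfig("VEGF", boundary_value=1e-9, initial_value=1e-9, **cyt),
        "RANKL": SpeciesConfig("RANKL", boundary_value=1e-10, initial_value=1e-10, **cyt),
        "OPG": SpeciesConfig("OPG", boundary_value=1e-10, initial_value=1e-10, **cyt),
        "Scl": SpeciesConfig("Scl", boundary_value=1e-10, initial_value=1e-10, **cyt),
        "TGFb": SpeciesConfig("TGFb", boundary_value=1e-10, initial_value=1e-10, **cyt),
        "RANKL_OPG": SpeciesConfig("RANKL_OPG", boundary_value=0.0, initial_value=0.0, **cyt),
        "O2": SpeciesConfig(
            "O2", d_soft_um2_s=100.0, d_mineral_um2_s=100.0, decay_per_s=0.0,
            boundary_value=0.065, initial_value=0.065,
        ),
    }


@dataclass
class ReceptorConfig:
    """Receptor-ligand pair with surface binding-site kinetics."""

    receptor: str
    ligand: str
    n_sites: float = 100.0                   # per-cell surface binding sites
    k_on_m3_mol_s: float = 1e4               # K_D = k_off/k_on
    k_off_per_s: float = 1e-4


def _default_receptors() -> dict[str, ReceptorConfig]:
    return {
        "RANK": ReceptorConfig("RANK", "RANKL"),
        "VEGFR": ReceptorConfig("VEGFR", "VEGF"),
        "TGFBR1": ReceptorConfig("TGFBR1", "TGFb", k_on_m3_mol_s=1e5),
        "LRP56": ReceptorConfig("LRP56", "Scl"),
    }


@dataclass
class BindingConfig:
    receptors: dict[str, ReceptorConfig] = field(default_factory=_default_receptors)
    rankl_opg_k_m3_mol_s: float = 1e5        # OPG + RANKL -> RANKL_OPG


@dataclass
class RDDConfig:
    dt_s: float = 1800.0                     # 30 min
    species: dict[str, SpeciesConfig] = field(default_factory=_default_species)
    binding: BindingConfig = field(default_factory=BindingConfig)
    # refactor the BTCS operator after this many voxels flip tissue class
    rebuild_threshold_voxels: int = 512


@dataclass
class CellConfig:
    dt_h: float = 1.0 / 3.0                  # 20 min
    migration_probability: float = 1.0       # SSPC/HSC/Immune: 31.5 um/h at 1.0
    obl_bias_probability: float = 0.5        # directed-migration mixing
    ocl_bias_probability: float = 0.5
    polarisation_beta: float = 5.0           # softmax sharpness
    proliferation_per_h: float = 0.02        # SSPC & HSC
    apoptosis_per_h: dict[str, float] = field(default_factory=lambda: {
        "SSPC": 0.002, "HSC": 0.002, "Immune": 0.004, "OBL": 0.003, "OCL": 0.006,
    })
    embedding_probability: float = 0.2       # OBL -> preOCY per step, density-gated
    ocy_target_per_mm3: float = 44_800.0
    ocy_gate_radius_vox: int = 2
    maturation_h: float = 72.0               # preOCY -> OCY
    lining_probability: float = 0.1
    lrp56_inhibition: float = 0.5            # Scl occupancy blocking Lining -> OBL
    rank_activation: float = 0.5             # RANK occupancy for OCL differentiation
    tgfbr1_activation: float = 0.25          # TGFBR1 occupancy for SSPC -> OBL
    osteoid_increment: float = 4.0           # mg HA/cm^3 per deposition event
    resorption_probability: float = 0.2      # per qualifying cluster per step
    o2_consumption_mol_s: float = 3.9e-20


@dataclass
class ProductionConfig:
    """Per-cell cytokine secretion laws (mol/s per cell).

    Mechanoregulated laws are linear in the local signal and clamped at zero:
    ``rate = max(0, base * (1 + slope * signal / signal_ref))``.
    """

    sed_ref_mpa: float = 0.015
    eff_ref: float = 0.015
    ocy_rankl_base: float = 4e-24
    ocy_scl_base: float = 2e-24
    ocy_opg_base: float = 2e-24              # rises from 0 with SED
    obl_rankl_base: float = 0.5e-24
    obl_opg_base: float = 1e-24
    vegf_max: float = 5e-24                  # scaled by (1 - oxygen fulfilment)
    immune_tgfb: float = 5e-24


@dataclass
class VesselConfig:
    p_grad: float = 0.5
    p_persist: float = 0.3
    p_rand: float = 0.2
    move_probability: float = 0.5            # per cell step
    maintenance_vegf: float = 2e-9           # mol/m^3, growth threshold
    branching_vegf: float = 1e-8
    branching_rate: float = 1e-3             # per stalk voxel per step
    o2_setpoint: float = 0.065               # vessel voxels held at this O2


@dataclass
class MineralConfig:
    rate_per_day: float = 30.0               # mg HA/cm^3/day
    density_cap: float = MINERAL_MAX
    tgfb_banking_mol_per_density: float = 1e-26  # mol stored per mg HA/cm^3 mineralised


@dataclass
class SimConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seeding: SeedingPlan = field(default_factory=SeedingPlan)
    mechanics: MechanicsConfig = field(default_factory=MechanicsConfig)
    rdd: RDDConfig = field(default_factory=RDDConfig)
    cells: CellConfig = field(default_factory=CellConfig)
    production: ProductionConfig = field(default_factory=ProductionConfig)
    vessels: VesselConfig = field(default_factory=VesselConfig)
    mineral: MineralConfig = field(default_factory=MineralConfig)
    seed: int = 0
    duration_days: float = 35.0
    dt_fe_h: float = 8.0
    snapshot_interval_days: float = 7.0
    gap_study_step_mm: float = 0.15

    def validate(self) -> None:
        n_cell = self.dt_fe_h / self.cells.dt_h
        n_rdd = self.dt_fe_h * 3600.0 / self.rdd.dt_s
        for name, n in (("cell", n_cell), ("RDD", n_rdd)):
            if abs(n - round(n)) > 1e-9 or n <= 0:
                raise ValueError(f"dt_fe must be an integer multiple of the {name} step")
        self.phantom.validate()

    @property
    def cell_steps_per_macro(self) -> int:
        return round(self.dt_fe_h / self.cells.dt_h)

    @property
    def rdd_steps_per_macro(self) -> int:
        return round(self.dt_fe_h * 3600.0 / self.rdd.dt_s)


def _update_dataclass(obj, data: dict):
    for key, value in data.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown configuration key: {key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _update_dataclass(current, value)
        elif isinstance(current, dict) and isinstance(value, dict) and current and \
                dataclasses.is_dataclass(next(iter(current.values()))):
            for sub, subdata in value.items():
                if sub in current:
                    _update_dataclass(current[sub], subdata)
                else:
                    raise KeyError(f"unknown entry {sub!r} under {key!r}")
        else:
            setattr(obj, key, type(current)(value) if current is not None else value)
    return obj


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> SimConfig:
    """Build a :class:`SimConfig` from defaults, a TOML file and overrides."""
    cfg = SimConfig()
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        _update_dataclass(cfg, data)
    if overrides:
        _update_dataclass(cfg, overrides)
    cfg.validate()
    return cfg
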