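"""Time-lapsed bone morphometry: multidensity bone volumes, FQR rates,
cortical metrics, ray-traced gap width, and RMSE scoring.

All metrics follow standard micro-CT conventions: bone volume is the voxel
count above a mineral-density threshold times the voxel volume; formation /
quiescence / resorption (FQR) classifies voxels by comparing two registered
thresholded images; cortical thickness uses the distance-transform
sphere-fitting method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import MINERAL_MAX, MINERAL_THRESHOLD, VOXEL_SIZE_UM

__all__ = [
    "MULTIDENSITY_THRESHOLDS",
    "MorphometryReport",
    "bv_multithreshold",
    "fqr",
    "local_thickness",
    "cortical_metrics",
    "gap_width",
    "rmse_score",
]

MULTIDENSITY_THRESHOLDS = np.arange(MINERAL_THRESHOLD, MINERAL_MAX + 1, 25.0)  # 14 values
HIGH_THRESHOLD = 645.0


@dataclass
class MorphometryReport:
    bv_per_threshold: dict[str, dict[float, float]] = field(default_factory=dict)
    bvtv_per_threshold: dict[str, dict[float, float]] = field(default_factory=dict)
    mineralisation_ratio: dict[str, float] = field(default_factory=dict)  # BV645/BV395
    bfr_per_day: dict[str, float] = field(default_factory=dict)
    brr_per_day: dict[str, float] = field(default_factory=dict)
    ct_ar_mm2: float | None = None
    ma_ar_mm2: float | None = None
    ct_th_mm: float | None = None
    ct_po_percent: float | None = None
    gap_median_mm: float | None = None
    vv_tv: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for name, val in self.__dict__.items():
            if isinstance(val, dict):
                out[name] = {str(k): (dict(v) if isinstance(v, dict) else v)
                             for k, v in val.items()}
            else:
                out[name] = val
        return out


def bv_multithreshold(volume: np.ndarray, vois: dict[str, np.ndarray],
                      voxel_size_um: float = VOXEL_SIZE_UM,
                      thresholds: np.ndarray = MULTIDENSITY_THRESHOLDS):
    """Per-VOI bone volume at every multidensity threshold.

    Returns ``(bv, bvtv)`` where BV is in um^3 and BV/TV uses the centre VOI
    of the pair as denominator (DC for DC/DP, FC for FC/FP).
    """
    for need in ("DC", "DP", "FC", "FP"):
        if need not in vois:
            raise KeyError(f"missing VOI {need!r}")
    vv = voxel_size_um ** 3
    bv: dict[str, dict[float, float]] = {}
    counts: dict[str, dict[float, int]] = {}
    for name, mask in vois.items():
        counts[name] = {float(t): int((volume[mask] >= t).sum()) for t in thresholds}
        bv[name] = {t: c * vv for t, c in counts[name].items()}
    denom = {"DC": "DC", "DP": "DC", "FC": "FC", "FP": "FC"}
    bvtv = {}
    for name in vois:
        ref = int(vois[denom.get(name, name)].sum())
        bvtv[name] = {t: counts[name][t] / ref if ref else 0.0
                      for t in counts[name]}
    return bv, bvtv


def mineralisation_ratio(volume: np.ndarray, mask: np.ndarray | None = None,
                         low: float = MINERAL_THRESHOLD,
                         high: float = HIGH_THRESHOLD) -> float:
    """BV645/BV395: highly mineralised fraction of the mineralised volume."""
    region = volume if mask is None else volume[mask]
    n_low = int((region >= low).sum())
    if n_low == 0:
        return 0.0
    return int((region >= high).sum()) / n_low


def fqr(volume_t0: np.ndarray, volume_t1: np.ndarray,
        threshold: float = MINERAL_THRESHOLD, dt_days: float = 7.0,
        mask: np.ndarray | None = None):
    """Formation/quiescence/resorption masks and BFR/BRR in %/day.

    Rates are voxel counts of formation (resp. resorption) relative to the
    baseline bone volume, per day.
    """
    if volume_t0.shape != volume_t1.shape:
        raise ValueError("volume grids do not match")
    b0 = volume_t0 >= threshold
    b1 = volume_t1 >= threshold
    if mask is not None:
        b0 = b0 & mask
        b1 = b1 & mask
    F = b1 & ~b0
    R = b0 & ~b1
    Q = b0 & b1
    n0 = int(b0.sum())
    bfr = 100.0 * int(F.sum()) / n0 / dt_days if n0 else 0.0
    brr = 100.0 * int(R.sum()) / n0 / dt_days if n0 else 0.0
    return F, Q, R, bfr, brr


def local_thickness(mask: np.ndarray, voxel_size_um: float = VOXEL_SIZE_UM) -> np.ndarray:
    """Model-independent local thickness (largest inscribed sphere, um).

    Distance-transform sphere-fitting: a voxel's thickness is twice the
    radius of the largest sphere that contains it and fits in the structure.
    """
    if not mask.any():
        return np.zeros(mask.shape)
    dist = ndimage.distance_transform_edt(mask)
    radii = np.unique(np.round(dist[mask], 6))[::-1]
    thickness = np.zeros(mask.shape)
    for r in radii:
        if r <= 0:
            continue
        centres = dist >= r
        covered = ndimage.distance_transform_edt(~centres) <= r
        update = mask & covered & (thickness == 0)
        thickness[update] = 2.0 * r
    return thickness * voxel_size_um


def cortical_metrics(volume: np.ndarray, region_z: slice | np.ndarray | None = None,
                     cortical_threshold: float = MINERAL_MAX,
                     voxel_size_um: float = VOXEL_SIZE_UM):
    """Ct.Ar, Ma.Ar (mm^2), Ct.Th (mm), Ct.Po (%) over an axial region.

    Slice-wise: the cortical compartment is the filled outer contour of the
    thresholded bone; the medullary area is the largest internal cavity;
    remaining internal voids are intracortical pores.  Returns a dict; values
    are ``None`` (flagged undefined) when the structure is not bridged
    (slices without bone).
    """
    bone3d = volume >= cortical_threshold
    if region_z is None:
        region_z = slice(0, volume.shape[2])
    zs = np.arange(volume.shape[2])[region_z]
    px = (voxel_size_um * 1e-3) ** 2
    ct_list, ma_list, po_pore, po_ct = [], [], 0, 0
    for z in zs:
        b = bone3d[:, :, z]
        if not b.any():
            return {"ct_ar_mm2": None, "ma_ar_mm2": None,
                    "ct_th_mm": None, "ct_po_percent": None}
        solid = ndimage.binary_fill_holes(b)
        cavities, n = ndimage.label(solid & ~b)
        if n:
            sizes = np.bincount(cavities.ravel())[1:]
            medulla = cavities == (1 + int(np.argmax(sizes)))
            pores = solid & ~b & ~medulla
        else:
            medulla = np.zeros_like(b)
            pores = np.zeros_like(b)
        ct_list.append((b.sum() + pores.sum()) * px)
        ma_list.append(medulla.sum() * px)
        po_pore += int(pores.sum())
        po_ct += int(b.sum() + pores.sum())
    th = local_thickness(bone3d[:, :, region_z], voxel_size_um)
    ct_th = float(th[th > 0].mean()) * 1e-3 if (th > 0).any() else 0.0
    return {
        "ct_ar_mm2": float(np.mean(ct_list)),
        "ma_ar_mm2": float(np.mean(ma_list)),
        "ct_th_mm": ct_th,
        "ct_po_percent": 100.0 * po_pore / po_ct if po_ct else 0.0,
    }


def gap_width(volume: np.ndarray, threshold: float = MINERAL_THRESHOLD,
              voxel_size_um: float = VOXEL_SIZE_UM,
              angle_step_deg: float = 2.0):
    """Ray-traced osteotomy gap width distribution and median (mm).

    For each perpendicular direction from the longitudinal axis, the rays at
    consecutive axial rows that pass entirely between the cortices (hitting
    no bone) are counted; count x voxel height is that direction's gap
    width.  The median over directions is reported; a fully bridged
    structure yields median 0.
    """
    bone = volume >= threshold
    nx, ny, nz = volume.shape
    has_bone_z = bone.any(axis=(0, 1))
    if not has_bone_z.any():
        raise ValueError("no bone: cannot identify a longitudinal axis")
    # least-squares longitudinal axis from slice-wise bone centroids
    zs = np.flatnonzero(has_bone_z)
    cx = np.array([ndimage.center_of_mass(bone[:, :, z])[0] for z in zs])
    cy = np.array([ndimage.center_of_mass(bone[:, :, z])[1] for z in zs])
    ax = np.polyfit(zs, cx, 1) if zs.size > 1 else (0.0, cx[0])
    ay = np.polyfit(zs, cy, 1) if zs.size > 1 else (0.0, cy[0])

    r_max = float(np.hypot(nx, ny))
    radii = np.arange(1.0, r_max, 0.5)
    angles = np.deg2rad(np.arange(0.0, 360.0, angle_step_deg))
    zlo, zhi = zs[0], zs[-1]
    widths = []
    for theta in angles:
        free_rows = 0
        for z in range(zlo, zhi + 1):
            x0 = np.polyval(ax, z)
            y0 = np.polyval(ay, z)
            xs = x0 + radii * np.cos(theta)
            ys = y0 + radii * np.sin(theta)
            ok = (xs >= 0) & (xs < nx) & (ys >= 0) & (ys < ny)
            hit = bone[xs[ok].astype(int), ys[ok].astype(int), z].any()
            if not hit:
                free_rows += 1
        widths.append(free_rows * voxel_size_um * 1e-3)
    widths = np.asarray(widths)
    return widths, float(np.median(widths))


def rmse_score(insilico: np.ndarray, reference: np.ndarray) -> float:
    """RMSE between two matched BV/TV time series (any consistent shape)."""
    a = np.asarray(insilico, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series length mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def rmse_table(insilico: dict[str, np.ndarray], reference: dict[str, np.ndarray],
               thresholds=None) -> dict[str, float]:
    """Per-VOI RMSE of BV/TV differences, averaged across timepoints."""
    return {voi: rmse_score(insilico[voi], reference[voi]) for voi in insilico}
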