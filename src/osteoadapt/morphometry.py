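"""Compartment atlas, volumetric second moments and densitometric indices.

The tibia is partitioned into 10 longitudinal sections (distal = section 1,
proximal = section ``n``) and 4 angular sectors (anterior, posterior,
medial, lateral) about the whole-bone centroid axis, giving the 40
compartments used for regional densitometry.  Per-section volumetric
second moments

    Ixx_vol = integral of y^2 dV,   Iyy_vol = integral of x^2 dV

(about each section's own bone centroid, in mm^5) act as bending-stiffness
surrogates and form the data of the remodelling-parameter calibration
objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import BoneMask, VoxelImage

SECTORS = ("anterior", "posterior", "medial", "lateral")


@dataclass(frozen=True)
class CompartmentAtlas:
    """Per-voxel (section, sector) assignment.

    ``section_of_slice`` maps each z-slice to a section in 1..n_sections
    (0 outside the occupied extent); ``sector`` labels every voxel of the
    grid by angular quadrant (1 anterior, 2 posterior, 3 medial, 4 lateral)
    so that non-bone voxels inside the periosteal envelope can be assigned
    to compartments as well.
    """

    n_sections: int
    section_of_slice: np.ndarray  # (nz,) int
    sector: np.ndarray  # (nx, ny) int8, constant along z
    centroid_xy: tuple[float, float]

    def section_volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Broadcast the slice->section map to a full (nx, ny, nz) grid."""
        return np.broadcast_to(self.section_of_slice[None, None, :], shape)

    def sector_volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        return np.broadcast_to(self.sector[:, :, None], shape)


def build_atlas(mask: BoneMask, n_sections: int = 10) -> CompartmentAtlas:
    """Partition the occupied z-extent into equal-length sections and the
    cross-section into angular quadrants.

    Remainder slices from the integer division go to the most proximal
    section.  Sector boundaries are the 45-degree diagonals about the
    whole-bone bone-voxel centroid: anterior is the +y quadrant, posterior
    -y, medial +x, lateral -x, with half-open angular bins so each sector
    owns exactly one diagonal.
    """
    if mask.count() == 0:
        raise ValueError("cannot build an atlas from an empty mask")
    nx, ny, nz = mask.shape
    occupied = np.flatnonzero(mask.data.any(axis=(0, 1)))
    zlo, zhi = int(occupied[0]), int(occupied[-1])
    n_occ = zhi - zlo + 1
    if n_occ < n_sections:
        raise ValueError(f"occupied extent ({n_occ} slices) shorter than {n_sections} sections")
    base = n_occ // n_sections
    lengths = np.full(n_sections, base, dtype=int)
    lengths[-1] += n_occ - base * n_sections
    section_of_slice = np.zeros(nz, dtype=int)
    z = zlo
    for s, length in enumerate(lengths, start=1):
        section_of_slice[z : z + length] = s
        z += length

    cx, cy = (float(c) for c in ndimage.center_of_mass(mask.data)[:2])
    x = np.arange(nx)[:, None] - cx
    y = np.arange(ny)[None, :] - cy
    angle = np.degrees(np.arctan2(y, x))  # 0 deg = +x = medial
    sector = np.empty((nx, ny), dtype=np.int8)
    sector[(angle >= 45) & (angle < 135)] = 1  # anterior (+y)
    sector[(angle >= -135) & (angle < -45)] = 2  # posterior (-y)
    sector[(angle >= -45) & (angle < 45)] = 3  # medial (+x)
    sector[(angle >= 135) | (angle < -135)] = 4  # lateral (-x)
    return CompartmentAtlas(n_sections, section_of_slice, sector, (cx, cy))


@dataclass(frozen=True)
class SecondMomentProfile:
    """Per-section volumetric second moments, mm^5."""

    ixx: np.ndarray
    iyy: np.ndarray

    def residual_to(self, other: "SecondMomentProfile", squared: bool = True) -> float:
        rx = self.ixx - other.ixx
        ry = self.iyy - other.iyy
        if squared:
            return float(np.sum(rx**2) + np.sum(ry**2))
        return float(np.sum(rx) + np.sum(ry))


def volumetric_second_moments(mask: BoneMask, atlas: CompartmentAtlas) -> SecondMomentProfile:
    """Ixx = sum (y - ybar)^2 dV and Iyy = sum (x - xbar)^2 dV per section.

    Voxel-centre sampling times the voxel volume approximates dV; the
    reference axes pass through each section's own bone centroid, which
    makes the profile insensitive to residual in-plane translation.
    """
    s_mm = mask.spacing * 1e-3
    v = s_mm**3
    vox = np.argwhere(mask.data)
    sections = atlas.section_of_slice[vox[:, 2]]
    x = (vox[:, 0] + 0.5) * s_mm
    y = (vox[:, 1] + 0.5) * s_mm
    ixx = np.zeros(atlas.n_sections)
    iyy = np.zeros(atlas.n_sections)
    for s in range(1, atlas.n_sections + 1):
        sel = sections == s
        if not sel.any():
            warnings.warn(f"section {s} contains no bone voxels; moments set to zero")
            continue
        xs, ys = x[sel], y[sel]
        ixx[s - 1] = np.sum((ys - ys.mean()) ** 2) * v
        iyy[s - 1] = np.sum((xs - xs.mean()) ** 2) * v
    return SecondMomentProfile(ixx, iyy)


def exterior_background(mask_data: np.ndarray) -> np.ndarray:
    """Background voxels reachable from the image border, judged slice-wise.

    Uses a 2D face-connected flood fill on every z-slice, matching the
    periosteal-contour convention where an open (C-shaped) cross-section
    drains to the exterior.
    """
    nx, ny, nz = mask_data.shape
    exterior = np.zeros_like(mask_data, dtype=bool)
    structure = ndimage.generate_binary_structure(2, 1)
    border = np.zeros((nx, ny), dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for z in range(nz):
        bg = ~mask_data[:, :, z]
        labels, n = ndimage.label(bg, structure=structure)
        if n == 0:
            continue
        border_labels = np.unique(labels[border & bg])
        border_labels = border_labels[border_labels > 0]
        exterior[:, :, z] = np.isin(labels, border_labels)
    return exterior


def periosteal_mask(mask: BoneMask) -> np.ndarray:
    """Boolean volume of the region enclosed by the periosteal surface:
    bone voxels plus cavities not reachable from the slice border."""
    return mask.data | ~(mask.data | exterior_background(mask.data))


def _region_index(n_sections: int) -> list[str]:
    regions = ["whole"]
    for s in range(1, n_sections + 1):
        for sec in SECTORS:
            regions.append(f"s{s:02d}_{sec}")
    return regions


def periosteal_volume(mask: BoneMask, atlas: CompartmentAtlas) -> pd.Series:
    """Total volume (TV, mm^3) enclosed by the periosteal surface per region."""
    tv_mask = periosteal_mask(mask)
    v = (mask.spacing * 1e-3) ** 3
    section = atlas.section_volume(mask.shape)
    sector = atlas.sector_volume(mask.shape)
    out = {"whole": float(tv_mask.sum()) * v}
    for s in range(1, atlas.n_sections + 1):
        for q, name in enumerate(SECTORS, start=1):
            sel = tv_mask & (section == s) & (sector == q)
            out[f"s{s:02d}_{name}"] = float(sel.sum()) * v
    return pd.Series(out, name="TV")


def densitometrics(
    image: VoxelImage, mask: BoneMask, atlas: CompartmentAtlas
) -> pd.DataFrame:
    """Densitometric report per region (whole bone + 40 compartments).

    ``image`` must hold TMD in mg/cc.  Columns: BV and TV in mm^3, BV/TV,
    BMC in mg (sum of TMD times voxel volume), BMD = BMC/TV in mg/cc, and
    the mean TMD over bone voxels.  BMD is missing (NaN) where TV = 0.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask dimensions differ")
    v_mm3 = mask.voxel_volume_mm3 if hasattr(mask, "voxel_volume_mm3") else (mask.spacing * 1e-3) ** 3
    v_cm3 = v_mm3 * 1e-3
    tv_mask = periosteal_mask(mask)
    section = atlas.section_volume(mask.shape)
    sector = atlas.sector_volume(mask.shape)
    tmd = image.data

    rows = {}
    regions = [("whole", np.ones(mask.shape, dtype=bool))]
    for s in range(1, atlas.n_sections + 1):
        for q, name in enumerate(SECTORS, start=1):
            regions.append((f"s{s:02d}_{name}", (section == s) & (sector == q)))
    for name, sel in regions:
        bone = mask.data & sel
        tv = tv_mask & sel
        n_bone = int(bone.sum())
        n_tv = int(tv.sum())
        bv_mm3 = n_bone * v_mm3
        tv_mm3 = n_tv * v_mm3
        bmc_mg = float(tmd[bone].sum()) * v_cm3
        rows[name] = {
            "BV": bv_mm3,
            "TV": tv_mm3,
            "BVTV": bv_mm3 / tv_mm3 if n_tv else np.nan,
            "BMC": bmc_mg,
            "BMD": bmc_mg / (n_tv * v_cm3) if n_tv else np.nan,
            "TMD_mean": float(tmd[bone].mean()) if n_bone else np.nan,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.reindex(_region_index(atlas.n_sections))


def percent_error(pred: pd.DataFrame, exp: pd.DataFrame) -> pd.DataFrame:
    """100 * (pred - exp) / exp per region per index; positive means
    over-prediction; missing where the experimental value is zero."""
    if not pred.index.equals(exp.index) or not pred.columns.equals(exp.columns):
        raise ValueError("reports have mismatched region structure")
    denom = exp.where(exp != 0)
    return 100.0 * (pred - exp) / denom
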