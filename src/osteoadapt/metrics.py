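"""Validation metrics for predicted versus experimental follow-up images.

Longitudinal pairs are compared on three levels: global geometric overlap
(Jaccard ratio of the bone masks), binary maps of surface remodelling sites
(voxels that change bone/background state between time points, split into
apposition and resorption on the endosteal and periosteal surfaces), and
the two accuracy figures built on those maps:

* spatial match     = 100 * |predicted AND experimental| / |predicted|
* prediction accuracy = 100 * |predicted AND experimental| / |experimental|

computed per direction, per surface and per longitudinal section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import BoneMask, SegmentationModel, VoxelImage, binarise
from .morphometry import CompartmentAtlas, exterior_background


def overlap_ratio(a: BoneMask, b: BoneMask) -> float:
    """Jaccard overlap of two bone masks: |a & b| / |a | b|."""
    if a.shape != b.shape:
        raise ValueError("masks have different dimensions; align them first")
    union = int((a.data | b.data).sum())
    if union == 0:
        raise ValueError("overlap undefined: both masks are empty")
    inter = int((a.data & b.data).sum())
    return inter / union


@dataclass(frozen=True)
class SurfaceClassification:
    """Per-voxel surface labels of a bone mask.

    ``periosteal``/``endosteal`` mark surface *bone* voxels (face-adjacent
    to background); a voxel touching both exterior and enclosed background
    counts as periosteal.  ``exterior`` marks exterior background voxels
    (slice-wise border flood fill), used to label background-side sites.
    """

    periosteal: np.ndarray
    endosteal: np.ndarray
    exterior: np.ndarray


def _face_adjacent(mask: np.ndarray, to: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` with a face neighbour in ``to``."""
    structure = ndimage.generate_binary_structure(3, 1)
    grown = ndimage.binary_dilation(to, structure=structure)
    return mask & grown


def classify_surfaces(mask: BoneMask) -> SurfaceClassification:
    """Label surface bone voxels as periosteal (facing the exterior) or
    endosteal (facing enclosed medullary cavities)."""
    if mask.count() == 0:
        raise ValueError("cannot classify surfaces of an empty mask")
    bone = mask.data
    exterior = exterior_background(bone)
    enclosed = ~bone & ~exterior
    periosteal = _face_adjacent(bone, exterior)
    endosteal = _face_adjacent(bone, enclosed) & ~periosteal
    return SurfaceClassification(periosteal, endosteal, exterior)


@dataclass(frozen=True)
class RemodellingSiteMap:
    """Binary apposition/resorption site volumes with surface labels.

    Sites live on the boundary shell of the earlier mask; ``surface`` holds
    1 for periosteal and 2 for endosteal at site voxels, 0 elsewhere.
    """

    apposition: np.ndarray
    resorption: np.ndarray
    surface: np.ndarray

    def __post_init__(self):
        if (self.apposition & self.resorption).any():
            raise ValueError("apposition and resorption sites must be disjoint")

    def count(self, direction: str) -> int:
        return int(getattr(self, direction).sum())


def remodelling_sites(
    earlier: VoxelImage, later: VoxelImage, seg: SegmentationModel
) -> RemodellingSiteMap:
    """Detect surface voxels whose bone/background state changes.

    Both images must be aligned and equal-dimension.  On the boundary shell
    of the earlier mask (surface bone voxels plus background voxels face-
    adjacent to bone), a voxel is an apposition site when it crosses the
    threshold upward (background -> bone) and a resorption site when it
    crosses downward.  Sites are labelled endosteal or periosteal from the
    earlier mask's surface classification; background-side sites take the
    label of their own background voxel (exterior -> periosteal).
    """
    if earlier.shape != later.shape:
        raise ValueError("misaligned inputs: images must share dimensions")
    m0 = binarise(earlier, seg.threshold)
    m1 = binarise(later, seg.threshold)
    cls = classify_surfaces(m0)
    surf_bone = _face_adjacent(m0.data, ~m0.data) | _edge_of_grid(m0.data)
    surf_bg = _face_adjacent(~m0.data, m0.data)
    shell = surf_bone | surf_bg
    apposition = shell & ~m0.data & m1.data
    resorption = shell & m0.data & ~m1.data
    surface = np.zeros(m0.shape, dtype=np.int8)
    bone_label = np.where(cls.periosteal, 1, np.where(cls.endosteal, 2, 1))
    bg_label = np.where(cls.exterior, 1, 2)
    sites = apposition | resorption
    surface[sites & m0.data] = bone_label[sites & m0.data]
    surface[sites & ~m0.data] = bg_label[sites & ~m0.data]
    return RemodellingSiteMap(apposition, resorption, surface)


def _edge_of_grid(bone: np.ndarray) -> np.ndarray:
    """Bone voxels on the grid border (their outward face is unshared)."""
    edge = np.zeros_like(bone)
    edge[0], edge[-1] = True, True
    edge[:, 0], edge[:, -1] = True, True
    edge[:, :, 0], edge[:, :, -1] = True, True
    return bone & edge


def match_metrics(
    predicted: RemodellingSiteMap,
    experimental: RemodellingSiteMap,
    atlas: CompartmentAtlas | None = None,
) -> pd.DataFrame:
    """Spatial match and prediction accuracy of predicted site maps.

    Rows are (direction, surface, section) combinations -- surfaces ``all``,
    ``periosteal``, ``endosteal`` and sections ``whole`` plus the atlas
    sections when an atlas is supplied (whole-bone figures pool sites
    rather than averaging over sections).  Percentages are missing (NaN)
    where the corresponding denominator is zero.
    """
    if predicted.apposition.shape != experimental.apposition.shape:
        raise ValueError("site maps come from incongruent image pairs")
    shape = predicted.apposition.shape
    surfaces = {
        "all": np.ones(shape, dtype=bool),
        "periosteal": (predicted.surface == 1) | (experimental.surface == 1),
        "endosteal": (predicted.surface == 2) | (experimental.surface == 2),
    }
    sections: dict[str, np.ndarray] = {"whole": np.ones(shape, dtype=bool)}
    if atlas is not None:
        section_vol = atlas.section_volume(shape)
        for s in range(1, atlas.n_sections + 1):
            sections[f"s{s:02d}"] = section_vol == s

    rows = []
    for direction in ("apposition", "resorption"):
        p_all = getattr(predicted, direction)
        e_all = getattr(experimental, direction)
        for surf_name, surf_sel in surfaces.items():
            for sec_name, sec_sel in sections.items():
                sel = surf_sel & sec_sel
                n_pred = int((p_all & sel).sum())
                n_exp = int((e_all & sel).sum())
                n_correct = int((p_all & e_all & sel).sum())
                rows.append({
                    "direction": direction,
                    "surface": surf_name,
                    "section": sec_name,
                    "n_predicted": n_pred,
                    "n_experimental": n_exp,
                    "n_correct": n_correct,
                    "spatial_match": 100.0 * n_correct / n_pred if n_pred else np.nan,
                    "prediction_accuracy": 100.0 * n_correct / n_exp if n_exp else np.nan,
                })
    return pd.DataFrame(rows).set_index(["direction", "surface", "section"])
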