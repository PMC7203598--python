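"""Voxel images, densitometric calibration and histogram-based segmentation.

The in-memory currency of the whole pipeline is :class:`VoxelImage`: a 3D
scalar grid indexed ``data[x, y, z]`` with isotropic voxel spacing in
micrometres.  Axis convention for tibia data: x = medial-lateral,
y = anterior-posterior, z = longitudinal with the proximal end at max z.

Segmentation follows the micro-CT cortical-bone convention: a single
grey-value threshold at the midpoint between the background and bone peaks
of the image histogram, plus a *transition zone* (TZ) of grey values around
the threshold whose voxels may represent either bone or background (they
are the voxels affected by the partial volume effect and are the ones the
remodelling update is allowed to move in both directions).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import SimpleITK as sitk
import tifffile
from scipy import ndimage


class SegmentationError(RuntimeError):
    """Raised when an image histogram does not support bimodal thresholding."""


@dataclass(frozen=True)
class VoxelImage:
    """A 3D scalar grid with isotropic voxel spacing.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz)``.  Grey values (arbitrary scanner
        units) or tissue mineral density (mg/cc) after calibration.
    spacing:
        Voxel edge length in micrometres (isotropic).
    """

    data: np.ndarray
    spacing: float

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError("VoxelImage requires a 3D grid with all dims >= 1")
        if not np.isfinite(data).all():
            raise ValueError("grey values must be finite")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing_mm(self) -> float:
        return self.spacing * 1e-3

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm**3

    def with_data(self, data: np.ndarray) -> "VoxelImage":
        return VoxelImage(data, self.spacing)


@dataclass(frozen=True)
class BoneMask:
    """Binary bone segmentation on the same grid as its source image."""

    data: np.ndarray
    spacing: float

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.dtype != bool:
            data = data.astype(bool)
        if data.ndim != 3:
            raise ValueError("BoneMask requires a 3D grid")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class DensitometricCalibration:
    """Linear grey -> TMD mapping, TMD = slope * grey + intercept (mg/cc)."""

    slope: float
    intercept: float = 0.0

    def __post_init__(self):
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")

    def grey_to_tmd(self, image: VoxelImage) -> VoxelImage:
        return image.with_data(image.data * self.slope + self.intercept)

    def tmd_to_grey(self, image: VoxelImage) -> VoxelImage:
        return image.with_data((image.data - self.intercept) / self.slope)

    def value_to_tmd(self, grey: float) -> float:
        return grey * self.slope + self.intercept

    def value_to_grey(self, tmd: float) -> float:
        return (tmd - self.intercept) / self.slope


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SITK_SUFFIXES = {".mhd", ".mha", ".nii"}


def _format_of(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffixes = path.suffixes
    if suffixes and suffixes[-1] == ".gz" and len(suffixes) > 1 and suffixes[-2] == ".nii":
        return "nifti"
    suffix = path.suffix.lower()
    if suffix in (".mhd", ".mha"):
        return "mhd"
    if suffix == ".nii":
        return "nifti"
    if suffix in (".tif", ".tiff"):
        return "tiff-stack"
    raise IOError(f"cannot infer image format from {path.name!r}")


def read_image(path, fmt: str | None = None, spacing: float | None = None) -> VoxelImage:
    """Read a 3D volume from MHD/RAW, NIfTI-1 or a multi-page TIFF stack.

    Header spacing is interpreted in micrometres (the unit this package
    writes).  TIFF stacks carry no spacing, so ``spacing`` must be supplied;
    for the other formats it overrides the header when given.  Anisotropic
    header spacing is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    kind = _format_of(path, fmt)
    if kind in ("mhd", "nifti"):
        img = sitk.ReadImage(str(path))
        sx, sy, sz = img.GetSpacing()
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        data = np.ascontiguousarray(np.transpose(data, (2, 1, 0))).astype(np.float64)
        if spacing is None:
            if not np.allclose([sx, sy, sz], sx, rtol=1e-6):
                raise IOError(f"anisotropic voxel spacing {img.GetSpacing()} is unsupported")
            spacing = float(sx)
    elif kind == "tiff-stack":
        data = np.asarray(tifffile.imread(str(path)))
        if data.ndim == 2:
            data = data[None]
        data = np.ascontiguousarray(np.transpose(data, (2, 1, 0))).astype(np.float64)
        if spacing is None:
            raise IOError("TIFF stacks carry no voxel spacing; pass spacing explicitly")
    else:
        raise IOError(f"unknown image format {kind!r}")
    return VoxelImage(data, float(spacing))


def write_image(image: VoxelImage, path, fmt: str | None = None) -> None:
    """Write a volume; format chosen by extension unless ``fmt`` is given."""
    path = Path(path)
    kind = _format_of(path, fmt)
    if kind in ("mhd", "nifti"):
        arr = np.transpose(image.data, (2, 1, 0))
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
        img.SetSpacing((image.spacing,) * 3)
        sitk.WriteImage(img, str(path))
    elif kind == "tiff-stack":
        arr = np.transpose(image.data, (2, 1, 0))
        tifffile.imwrite(str(path), np.ascontiguousarray(arr))
    else:
        raise IOError(f"unknown image format {kind!r}")


# ---------------------------------------------------------------------------
# Histogram and segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GreyHistogram:
    """Grey-value frequency plot with uniform bins."""

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=np.float64)
        counts = np.asarray(self.counts, dtype=np.float64)
        if edges.ndim != 1 or counts.ndim != 1 or len(edges) != len(counts) + 1:
            raise ValueError("edges must have len(counts)+1 entries")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @classmethod
    def from_image(cls, image: VoxelImage, bin_width: float | None = None) -> "GreyHistogram":
        """Histogram with bin width 1 for integer grey data, else a
        Freedman-Diaconis-style width (fixed rule for reproducibility)."""
        values = image.data.ravel()
        vmin, vmax = float(values.min()), float(values.max())
        if bin_width is None:
            if np.allclose(values, np.round(values)):
                bin_width = 1.0
            else:
                iqr = np.subtract(*np.percentile(values, [75, 25]))
                bin_width = 2.0 * iqr / max(values.size, 1) ** (1 / 3)
                if bin_width <= 0:
                    bin_width = (vmax - vmin) / 64 or 1.0
        lo = np.floor(vmin / bin_width) * bin_width - 0.5 * bin_width
        n_bins = max(int(np.ceil((vmax - lo) / bin_width)), 1)
        edges = lo + bin_width * np.arange(n_bins + 1)
        counts, _ = np.histogram(values, bins=edges)
        return cls(edges, counts.astype(np.float64))

    def bin_of(self, value: float) -> int:
        idx = int(np.searchsorted(self.edges, value, side="right") - 1)
        return int(np.clip(idx, 0, len(self.counts) - 1))


def _local_maxima(counts: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (plateaus collapse to their first bin)."""
    padded = np.concatenate(([-np.inf], counts, [-np.inf]))
    peaks = []
    i = 1
    n = len(counts)
    while i <= n:
        j = i
        while j < n and padded[j + 1] == padded[j]:
            j += 1
        if padded[i] > padded[i - 1] and padded[j] > padded[j + 1]:
            peaks.append(i - 1)
        i = j + 1
    return np.asarray(peaks, dtype=int)


def compute_threshold(hist: GreyHistogram) -> float:
    """Single-level threshold at the midpoint between the background and
    bone peaks of the histogram.

    Peak detection runs on gently smoothed counts (Gaussian kernel with a
    width of 0.5% of the bin count) so sampling noise in fine bins does not
    masquerade as a mode.  The two dominant modes (largest counts; ties
    broken toward lower grey) must be separated by a valley; the background
    peak is the dominant mode at or below the valley and the bone peak the
    dominant mode above it.  Raises :class:`SegmentationError` for unimodal
    or flat histograms.
    """
    counts = ndimage.gaussian_filter1d(
        hist.counts.astype(np.float64), sigma=max(1.0, len(hist.counts) / 200.0)
    )
    peaks = _local_maxima(counts)
    if len(peaks) < 2:
        raise SegmentationError(
            f"histogram is not bimodal: found {len(peaks)} local maxima; "
            "cannot separate background from bone"
        )
    order = sorted(peaks, key=lambda i: (-counts[i], hist.centers[i]))
    first = order[0]
    # Second peak: the strongest remaining mode separated from the first by
    # a genuine valley (depth below half the smaller peak); this rejects
    # noise maxima riding on the flank of the dominant mode.
    second = None
    for cand in order[1:]:
        p, q = sorted((first, cand))
        between = counts[p + 1 : q]
        if between.size and between.min() < 0.5 * min(counts[p], counts[q]):
            second = cand
            break
    if second is None:
        raise SegmentationError("no valley between the two dominant histogram modes")
    p, q = sorted((first, second))
    between = counts[p + 1 : q]
    split = p + 1 + int(np.argmin(between))
    low = int(np.argmax(counts[: split + 1]))
    high = split + 1 + int(np.argmax(counts[split + 1 :]))
    centers = hist.centers
    return float(0.5 * (centers[low] + centers[high]))


def compute_transition_zone(hist: GreyHistogram, threshold: float) -> tuple[float, float]:
    """Transition-zone bounds around the threshold.

    Scanning outward from the threshold bin, each bound is the nearest bin
    whose count is at least twice the count at the threshold bin.  When no
    bin qualifies on a side, that bound falls back to the histogram extreme
    (with a warning).
    """
    t = hist.bin_of(threshold)
    counts = hist.counts
    centers = hist.centers
    need = 2.0 * counts[t]
    tz_low = None
    for i in range(t - 1, -1, -1):
        if counts[i] >= need:
            tz_low = centers[i]
            break
    if tz_low is None:
        tz_low = centers[0]
        warnings.warn("no bin below threshold reaches twice the threshold count; "
                      "transition zone clipped at the histogram minimum")
    tz_high = None
    for i in range(t + 1, len(counts)):
        if counts[i] >= need:
            tz_high = centers[i]
            break
    if tz_high is None:
        tz_high = centers[-1]
        warnings.warn("no bin above threshold reaches twice the threshold count; "
                      "transition zone clipped at the histogram maximum")
    return float(tz_low), float(tz_high)


@dataclass(frozen=True)
class SegmentationModel:
    """Threshold plus transition-zone bounds, in the units of the image it
    was derived from (grey, or mg/cc after :meth:`to_tmd`)."""

    threshold: float
    tz_low: float
    tz_high: float

    def __post_init__(self):
        if not self.tz_low <= self.threshold <= self.tz_high:
            raise ValueError("require tz_low <= threshold <= tz_high")

    @classmethod
    def from_image(cls, image: VoxelImage, bin_width: float | None = None) -> "SegmentationModel":
        hist = GreyHistogram.from_image(image, bin_width)
        thr = compute_threshold(hist)
        tz_low, tz_high = compute_transition_zone(hist, thr)
        return cls(thr, tz_low, tz_high)

    def to_tmd(self, cal: DensitometricCalibration) -> "SegmentationModel":
        return SegmentationModel(
            cal.value_to_tmd(self.threshold),
            cal.value_to_tmd(self.tz_low),
            cal.value_to_tmd(self.tz_high),
        )

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "tz_low": self.tz_low, "tz_high": self.tz_high}

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationModel":
        return cls(float(d["threshold"]), float(d["tz_low"]), float(d["tz_high"]))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Mask operations
# ---------------------------------------------------------------------------


def binarise(image: VoxelImage, threshold: float) -> BoneMask:
    """Bone mask by strict thresholding: voxel is bone iff grey > threshold."""
    return BoneMask(image.data > threshold, image.spacing)


_CONNECTIVITY = {"face": 1, "edge": 2, "vertex": 3}


def largest_component(mask: BoneMask, connectivity: str = "face") -> BoneMask:
    """Keep only the largest connected component (ties -> lowest label).

    The FE stage requires a single connected element set; stray speckle
    voxels would make the stiffness system singular.
    """
    if mask.count() == 0:
        raise ValueError("cannot extract components of an empty mask")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n = ndimage.label(mask.data, structure=structure)
    if n == 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return BoneMask(labels == keep, mask.spacing)


def crop_longitudinal_fraction(
    image: VoxelImage, fraction: float, from_end: str = "proximal", threshold: float = 0.0
) -> VoxelImage:
    """Retain a fraction of the occupied z-extent, measured from one end.

    Occupancy is judged against ``threshold``; the retained slice count is
    ``floor(fraction * occupied_slices)`` (at least 1).  The proximal end is
    max z by the axis convention.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    occupied = np.flatnonzero((image.data > threshold).any(axis=(0, 1)))
    if occupied.size == 0:
        raise ValueError("no voxels above threshold; occupied extent is empty")
    zlo, zhi = int(occupied[0]), int(occupied[-1])
    n_occ = zhi - zlo + 1
    n_keep = max(int(np.floor(fraction * n_occ)), 1)
    if from_end == "proximal":
        z0, z1 = zhi - n_keep + 1, zhi + 1
    elif from_end == "distal":
        z0, z1 = zlo, zlo + n_keep
    else:
        raise ValueError("from_end must be 'proximal' or 'distal'")
    return image.with_data(image.data[:, :, z0:z1].copy())


class AlignmentResult(NamedTuple):
    reference: VoxelImage
    moving: VoxelImage
    shift: tuple[int, int, int]


def _translate(data: np.ndarray, shift: np.ndarray, fill: float = 0.0) -> np.ndarray:
    out = np.full_like(data, fill)
    src = [slice(max(0, -s), data.shape[a] - max(0, s)) for a, s in enumerate(shift)]
    dst = [slice(max(0, s), data.shape[a] - max(0, -s)) for a, s in enumerate(shift)]
    out[tuple(dst)] = data[tuple(src)]
    return out


def align_for_comparison(
    reference: VoxelImage, moving: VoxelImage, threshold: float
) -> AlignmentResult:
    """Translate ``moving`` so the bone-volume centroids coincide, then crop
    both images to the common bounding box of the union of their masks.

    The translation is the integer voxel shift nearest the centroid offset
    (no rotation and no resampling, which keeps grey values intact); outputs
    share identical dimensions.
    """
    if reference.shape != moving.shape:
        raise ValueError("align_for_comparison expects equal-shape inputs")
    m_ref = reference.data > threshold
    m_mov = moving.data > threshold
    if not m_ref.any() or not m_mov.any():
        raise ValueError("empty bone mask; cannot align")
    c_ref = np.array(ndimage.center_of_mass(m_ref))
    c_mov = np.array(ndimage.center_of_mass(m_mov))
    shift = np.rint(c_ref - c_mov).astype(int)
    moved = _translate(moving.data, shift)
    m_mov2 = moved > threshold
    union = m_ref | m_mov2
    bounds = [(int(idx.min()), int(idx.max()) + 1) for idx in map(np.flatnonzero,
              (union.any(axis=(1, 2)), union.any(axis=(0, 2)), union.any(axis=(0, 1))))]
    box = tuple(slice(lo, hi) for lo, hi in bounds)
    return AlignmentResult(
        reference.with_data(reference.data[box].copy()),
        moving.with_data(moved[box].copy()),
        tuple(int(s) for s in shift),
    )
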