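"""Synthetic tibia-like phantoms and canonical fixtures.

No public repository holds the in vivo scans this kind of pipeline is run
on, so every stage is exercised on synthetic data: a voxelised hollow
tapered tube standing in for the pre-aligned cortical diaphysis (long axis
= z, proximal at max z), with Gaussian-jittered bone and background grey
levels, a Gaussian surface blur emulating the partial volume effect, and a
bimodal histogram by construction.  All generators are pure functions of
(spec, seed); fixed seeds give byte-identical volumes.

Default tissue values emulate murine cortical micro-CT: bone peak around
900 mg/cc, background around 100 mg/cc, 10.4 um voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import BoneMask, DensitometricCalibration, SegmentationModel, VoxelImage
from .remodelling import RemodellingParams, StimulusCache, simulate_step


def default_calibration() -> DensitometricCalibration:
    """Scanner-style linear calibration used by the phantom pipeline
    (0.5 mg/cc per grey unit, zero offset: grey 1800 = 900 mg/cc)."""
    return DensitometricCalibration(slope=0.5, intercept=0.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and grey-value statistics of a cortical-tube phantom.

    Radii and wall thicknesses are in voxels and may taper linearly from
    the distal (z = 0) to the proximal end; ``lumen_offset`` shifts the
    endosteal circle to make the wall eccentric.  TMD statistics are in
    mg/cc; ``blur_sigma`` (voxels) models the partial volume effect.
    """

    shape: tuple[int, int, int] = (40, 40, 120)
    spacing: float = 10.4
    outer_radius: tuple[float, float] = (12.0, 10.0)  # (distal, proximal)
    wall: tuple[float, float] = (4.0, 4.0)
    lumen_offset: tuple[float, float] = (0.0, 0.0)
    bone_tmd: float = 900.0
    bone_sigma: float = 45.0
    bg_tmd: float = 100.0
    bg_sigma: float = 20.0
    blur_sigma: float = 0.7
    seed: int = 0

    def __post_init__(self):
        r0, r1 = self.outer_radius
        w0, w1 = self.wall
        if min(w0, w1) < 1:
            raise ValueError("wall must be at least 1 voxel everywhere")
        if min(r0 - w0, r1 - w1) < 0:
            raise ValueError("wall thicker than the outer radius")
        margin = max(r0, r1) + max(abs(self.lumen_offset[0]), abs(self.lumen_offset[1]))
        if margin >= min(self.shape[0], self.shape[1]) / 2:
            raise ValueError("tube geometry exceeds the grid cross-section")


def geometric_mask(spec: PhantomSpec) -> BoneMask:
    """Exact voxelisation of the tube wall (no noise, no blur).

    A voxel is bone when its centre lies inside the outer circle and
    outside the (possibly offset) inner circle of its slice.
    """
    nx, ny, nz = spec.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    z = np.arange(nz)
    t = z / max(nz - 1, 1)
    r_out = spec.outer_radius[0] + (spec.outer_radius[1] - spec.outer_radius[0]) * t
    wall = spec.wall[0] + (spec.wall[1] - spec.wall[0]) * t
    r_in = r_out - wall
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    d_out = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    d_in = np.sqrt((x - cx - spec.lumen_offset[0]) ** 2 + (y - cy - spec.lumen_offset[1]) ** 2)
    bone = (d_out <= r_out[None, None, :]) & (d_in >= r_in[None, None, :])
    return BoneMask(bone, spec.spacing)


def make_phantom(
    spec: PhantomSpec, cal: DensitometricCalibration | None = None
) -> VoxelImage:
    """Generate a grey-value phantom volume from a spec (deterministic per seed)."""
    if cal is None:
        cal = default_calibration()
    rng = np.random.default_rng(spec.seed)
    bone = geometric_mask(spec).data
    nx, ny, nz = spec.shape
    tmd = rng.normal(spec.bg_tmd, spec.bg_sigma, size=(nx, ny, nz))
    tmd[bone] = rng.normal(spec.bone_tmd, spec.bone_sigma, size=int(bone.sum()))
    if spec.blur_sigma > 0:
        tmd = ndimage.gaussian_filter(tmd, spec.blur_sigma)
    tmd = np.maximum(tmd, 0.0)
    grey = (tmd - cal.intercept) / cal.slope
    return VoxelImage(grey, spec.spacing)


def forward_follow_up(
    baseline: VoxelImage,
    seg: SegmentationModel,
    cal: DensitometricCalibration,
    body_mass: float,
    true_params: RemodellingParams,
    stimulus_kind: str = "sed",
    cache: StimulusCache | None = None,
) -> VoxelImage:
    """One forward remodelling step with known (B*, k*): the ground-truth
    follow-up for parameter-recovery experiments."""
    return simulate_step(baseline, seg, cal, body_mass, true_params,
                         stimulus_kind=stimulus_kind, cache=cache)


def make_fixture(kind: str, spacing: float = 10.4, **dims) -> BoneMask:
    """Canonical masks for closed-form FE and morphometry oracles.

    kinds: ``bar`` (1 x 1 x n), ``plate`` (nx x ny x 1), ``cube`` (n^3),
    ``annulus`` (r_out, r_in, height, centred in a padded grid).
    """
    if kind == "bar":
        n = int(dims.get("n", 10))
        data = np.ones((1, 1, n), dtype=bool)
    elif kind == "plate":
        data = np.ones((int(dims.get("nx", 5)), int(dims.get("ny", 5)), 1), dtype=bool)
    elif kind == "cube":
        n = int(dims.get("n", 3))
        data = np.ones((n, n, n), dtype=bool)
    elif kind == "annulus":
        r_out = float(dims.get("r_out", 8.0))
        r_in = float(dims.get("r_in", 5.0))
        height = int(dims.get("height", 10))
        pad = int(dims.get("pad", 2))
        n = int(np.ceil(2 * r_out)) + 2 * pad + 1
        c = (n - 1) / 2.0
        x = np.arange(n)[:, None]
        y = np.arange(n)[None, :]
        d = np.sqrt((x - c) ** 2 + (y - c) ** 2)
        ring = (d <= r_out) & (d >= r_in)
        data = np.repeat(ring[:, :, None], height, axis=2)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if not (np.array(data.shape) > 0).all():
        raise ValueError("fixture dims must be positive")
    return BoneMask(data, spacing)
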