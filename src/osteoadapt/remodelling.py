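"""Mechanoregulation density update on the bone remodelling unit (BRU) lattice.

The mechanostat rule is linear in the stimulus excess: at each surface node
``N`` the commanded density change per time step (2 weeks by default) is

    dTMD(N) = B * (Theta(N) - k)

with remodelling rate ``B``, apposition limit ``k`` and stimulus ``Theta``
(SED in Pa or maximum principal strain in microstrain).  An optional lazy
zone of half-width ``w`` around ``k`` suppresses the response when
``|Theta - k| <= w``; ``w = 0`` recovers the base model.

Each surface node is the centre of a BRU comprising its (up to) 8 incident
voxels.  The node's commanded change moves the *mean* TMD of the BRU:
apposition scales background and transition-zone voxels by one common
factor, resorption scales bone and transition-zone voxels, so the 8-voxel
mean lands exactly on the target.  Each voxel then receives the average of
the values proposed by all surface nodes whose BRU contains it, and the
image is clamped to physiologically plausible TMD bounds before being
mapped back to grey values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image import (
    BoneMask,
    DensitometricCalibration,
    SegmentationModel,
    VoxelImage,
    binarise,
    largest_component,
)
from . import microfe
from .microfe import StimulusField

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RemodellingParams:
    """Calibrated mechanostat parameters.

    B:        remodelling rate, mg/cc per stimulus unit per time step.
    k:        apposition limit (stimulus threshold), Pa or microstrain.
    lazy_half_width: half-width w of the no-response band about k (same
              units as k); 0 disables the lazy zone.
    tmd_min, tmd_max: clamp bounds for predicted TMD, mg/cc.
    time_step_weeks: duration of one update iteration.
    """

    B: float
    k: float
    lazy_half_width: float = 0.0
    tmd_min: float = 0.0
    tmd_max: float = 1400.0
    time_step_weeks: float = 2.0

    def __post_init__(self):
        if self.B < 0 or self.k < 0 or self.lazy_half_width < 0:
            raise ValueError("require B >= 0, k >= 0, lazy_half_width >= 0")
        if not self.tmd_min < self.tmd_max:
            raise ValueError("require tmd_min < tmd_max")


def delta_tmd(theta, params: RemodellingParams):
    """Commanded TMD change per time step for stimulus ``theta`` (vectorised).

    Inside the lazy zone (``|theta - k| <= w``, band edges inclusive) the
    response is zero; outside it is ``B * (theta - k)``.
    """
    theta = np.asarray(theta, dtype=np.float64)
    if not np.isfinite(theta).all():
        raise ValueError("stimulus must be finite")
    excess = theta - params.k
    out = np.where(np.abs(excess) <= params.lazy_half_width, 0.0, params.B * excess)
    return out if out.ndim else float(out)


def sed_to_uniaxial_strain(sed: float, E: float = microfe.DEFAULT_E) -> float:
    """Microstrain of the uniaxial state with the given strain energy density.

    Uses the uniaxial equivalence SED = E * eps^2 / 2, i.e.
    eps = sqrt(2 * SED / E); handy for expressing SED apposition limits on
    the microstrain scale.
    """
    if sed < 0:
        raise ValueError("SED must be non-negative")
    if not E > 0:
        raise ValueError("E must be positive")
    return float(np.sqrt(2.0 * sed / E) * 1e6)


def apply_clamp(image: VoxelImage, params: RemodellingParams) -> VoxelImage:
    """Limit TMD values to [tmd_min, tmd_max] mg/cc."""
    return image.with_data(np.clip(image.data, params.tmd_min, params.tmd_max))


def bru_update(
    image: VoxelImage,
    seg: SegmentationModel,
    stimulus: StimulusField,
    params: RemodellingParams,
    background_floor: float = 1.0,
) -> VoxelImage:
    """One BRU-lattice density update of a TMD image.

    ``image`` and ``seg`` must both be in TMD units (mg/cc).  ``stimulus``
    carries the surface-node lattice coordinates and stimulus values of the
    current bone mask.  Voxel roles come from the transition-zone bounds:
    bone above ``tz_high``, background below ``tz_low``, TZ in between; TZ
    voxels join the scaled set in both directions.  Background voxels are
    floored at ``background_floor`` mg/cc before apposition scaling so a
    multiplicative factor can raise them from (near) zero; the BRU mean is
    defined on these floored working values.  Voxels not touched by any
    surface node are left unchanged; the result is clamped to the TMD
    bounds.
    """
    nx, ny, nz = image.shape
    coords = stimulus.node_coords
    if coords.size and (
        coords.min() < 0
        or (coords.max(axis=0) > np.array([nx, ny, nz])).any()
    ):
        raise ValueError("stimulus node coordinates fall outside the image lattice")
    n_nodes = len(coords)
    if n_nodes == 0:
        return apply_clamp(image, params)

    # Incident voxels of each node: node - 1 + offset for offset in {0,1}^3.
    vox = coords[:, None, :] - 1 + microfe._CORNER_OFFSETS[None, :, :]  # (N, 8, 3)
    valid = ((vox >= 0) & (vox < np.array([nx, ny, nz]))).all(axis=2)
    vox_clipped = np.clip(vox, 0, np.array([nx, ny, nz]) - 1)
    flat = (vox_clipped[..., 0] * ny + vox_clipped[..., 1]) * nz + vox_clipped[..., 2]
    v = image.data.ravel()[flat]  # (N, 8)

    bone = v > seg.tz_high
    background = v < seg.tz_low
    tz = ~bone & ~background

    delta = np.asarray(delta_tmd(stimulus.values, params))
    pos = delta > 0
    neg = delta < 0
    scaled = valid & np.where(pos[:, None], background | tz, bone | tz)
    scaled &= (pos | neg)[:, None]

    v_work = np.where(scaled & pos[:, None], np.maximum(v, background_floor), v)
    n_valid = valid.sum(axis=1).astype(np.float64)
    total = np.where(valid, v_work, 0.0).sum(axis=1)
    mean = total / n_valid
    target = mean + delta

    sum_scaled = np.where(scaled, v_work, 0.0).sum(axis=1)
    sum_rest = total - sum_scaled
    active = scaled.any(axis=1) & (sum_scaled > 0)
    saturated = (pos | neg) & ~active
    n_sat = int(saturated.sum())
    if n_sat:
        logger.info("bru_update: %d saturated BRUs (no voxels available to scale)", n_sat)

    factor = np.ones(n_nodes)
    factor[active] = (n_valid[active] * target[active] - sum_rest[active]) / sum_scaled[active]
    proposals = np.where(scaled & active[:, None], factor[:, None] * v_work, v_work)

    # Average the proposed *changes* over contributing nodes: identical to
    # averaging the proposals, but exactly a no-op when every change is zero.
    idx = flat[valid]
    changes = (proposals - v)[valid]
    sums = np.bincount(idx, weights=changes, minlength=nx * ny * nz)
    counts = np.bincount(idx, minlength=nx * ny * nz)
    out = image.data.ravel().copy()
    touched = counts > 0
    out[touched] += sums[touched] / counts[touched]
    new = image.with_data(out.reshape(nx, ny, nz))
    return apply_clamp(new, params)


class StimulusCache:
    """Memoises the FE stimulus field by bone-mask content.

    The stimulus of a step depends only on the mask geometry, the material
    constants, the load and the stimulus kind -- not on the remodelling
    parameters -- so repeated simulation of the same baseline (as in
    calibration) needs a single FE solve.
    """

    def __init__(self, maxsize: int = 8):
        self.maxsize = maxsize
        self._store: dict = {}

    def key(self, mask: BoneMask, E, nu, body_mass, kind) -> tuple:
        import hashlib

        digest = hashlib.sha1(np.packbits(mask.data).tobytes()).hexdigest()
        return (digest, mask.shape, mask.spacing, E, nu, body_mass, kind)

    def get_or_compute(self, mask, E, nu, body_mass, kind, tol, maxiter):
        key = self.key(mask, E, nu, body_mass, kind)
        if key not in self._store:
            if len(self._store) >= self.maxsize:
                self._store.pop(next(iter(self._store)))
            self._store[key] = _physiological_stimulus(
                mask, E, nu, body_mass, kind, tol, maxiter
            )
        return self._store[key]


def _physiological_stimulus(mask, E, nu, body_mass, kind, tol, maxiter) -> StimulusField:
    """FE stimulus under the physiological load for a given mask.

    Solves unit loads only along axes with a nonzero load component (the
    medial-lateral component is zero by default, so two solves suffice) and
    superposes the displacement fields before the stimulus is evaluated.
    """
    model = microfe.build_fe_model(mask, E=E, nu=nu)
    microfe.apply_boundary_conditions(model)
    load = microfe.physiological_load(body_mass)
    system = microfe._ReducedSystem(model)
    u = np.zeros((model.n_nodes, 3))
    for axis, weight in enumerate(load):
        if weight == 0.0:
            continue
        force = np.zeros(3)
        force[axis] = 1.0
        u += weight * system.solve(force, tol=tol, maxiter=maxiter).reshape(-1, 3)
    return microfe.compute_stimulus_field(model, microfe.DisplacementField(u), kind=kind)


def simulate_step(
    image: VoxelImage,
    seg: SegmentationModel,
    cal: DensitometricCalibration,
    body_mass: float,
    params: RemodellingParams,
    stimulus_kind: str = "sed",
    E: float = microfe.DEFAULT_E,
    nu: float = microfe.DEFAULT_NU,
    solver_tol: float = 1e-8,
    solver_maxiter: int = 100_000,
    cache: StimulusCache | None = None,
) -> VoxelImage:
    """Advance a grey-value image by one remodelling time step (2 weeks).

    Pipeline: binarise at the subject threshold -> keep the largest
    connected component -> solve the unit-load micro-FE problems and
    superpose the physiological load for the given body mass -> evaluate the
    surface-node stimulus -> apply the BRU update in TMD space -> clamp ->
    convert back to grey values.  Deterministic for fixed inputs.
    """
    mask = largest_component(binarise(image, seg.threshold))
    if cache is not None:
        stim = cache.get_or_compute(mask, E, nu, body_mass, stimulus_kind,
                                    solver_tol, solver_maxiter)
    else:
        stim = _physiological_stimulus(mask, E, nu, body_mass, stimulus_kind,
                                       solver_tol, solver_maxiter)
    tmd = cal.grey_to_tmd(image)
    seg_tmd = seg.to_tmd(cal)
    new_tmd = bru_update(tmd, seg_tmd, stim, params)
    return cal.tmd_to_grey(new_tmd)
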