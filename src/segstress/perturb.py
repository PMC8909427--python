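"""Monte Carlo generation of deformed binary masks within a surface tolerance.

The sampler emulates plausible interobserver re-delineations of a tumour
contour: every accepted realization stays within a hard max-symmetric
surface-distance bound tau of the original mask (1.18 mm by default, the
interobserver scale reported for lung GTVs), is a single 26-connected
component without internal holes, and only ever flips voxels inside the
"uncertainty ring" |d| <= tau around the original surface.

Sampler construction: white noise on the grid is smoothed with a Gaussian
kernel (correlation length ``smoothness_mm``), rescaled to a symmetric
offset band, and the new mask is ``{v : d(v) < o(v) + h}`` where ``d`` is
the signed distance to the original surface voxel centres and ``h`` is half
the smallest voxel spacing.  The ``h`` shift accounts for the geometric
boundary lying half a voxel outside the surface voxel centres: it makes
single-layer additions and removals equally likely (so realized volumes are
unbiased) and, with the offset amplitude capped at ``0.99 tau - h``, no
flip can ever move the surface by more than one voxel layer within the
tolerance.  The offset field acts as a spatially coherent in/out
displacement of the contour front.  Candidates are still validated against
the tolerance contract and redrawn on failure (discrete staircase corners
can create sqrt(2)-voxel gaps), so the bound is a guarantee, not an
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from segstress.errors import DegenerateMaskError, SamplingFailureError, ValidationError
from segstress.surface_metrics import surface_voxels, within_tolerance
from segstress.volumes_io import BinaryMask

#: 26-connectivity structuring element
_FULL_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PerturbationConfig:
    """Knobs of the mask sampler.

    ``smoothness_mm`` defaults to the tolerance itself: deformation patches
    then have roughly the same lateral scale as their amplitude, which is
    what hand-drawn contour differences look like.
    """

    tolerance_mm: float = 1.18
    n_realizations: int = 300
    smoothness_mm: float | None = None
    max_attempts_per_mask: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance_mm <= 0:
            raise ValidationError("tolerance_mm must be > 0")
        if self.smoothness_mm is None:
            self.smoothness_mm = self.tolerance_mm
        if self.smoothness_mm <= 0:
            raise ValidationError("smoothness_mm must be > 0")
        if self.n_realizations < 1:
            raise ValidationError("n_realizations must be >= 1")
        if self.max_attempts_per_mask < 1:
            raise ValidationError("max_attempts_per_mask must be >= 1")


@dataclass
class UncertaintyRing:
    """Shell of voxels within +/- tau (mm) of the original mask surface."""

    ring_voxels: np.ndarray  # boolean grid
    signed_distance: np.ndarray  # mm, negative inside the mask
    tolerance_mm: float


def signed_distance_field(mask: BinaryMask) -> np.ndarray:
    """Euclidean distance (mm) from each voxel centre to the nearest surface
    voxel centre, negative inside the mask."""
    surf = surface_voxels(mask.voxels)
    if not surf.any():
        raise DegenerateMaskError("mask has no surface voxels")
    dist = ndimage.distance_transform_edt(~surf, sampling=mask.spacing)
    sign = np.where(mask.voxels, -1.0, 1.0)
    return sign * dist


def build_ring(mask: BinaryMask, tau: float) -> UncertaintyRing:
    """Voxels whose signed distance to the original surface is within
    +/- ``tau`` mm — the support of any tolerated perturbation."""
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    sdf = signed_distance_field(mask)
    ring = np.abs(sdf) <= tau
    if not ring.any():
        raise DegenerateMaskError("uncertainty ring is empty")
    return UncertaintyRing(ring_voxels=ring, signed_distance=sdf, tolerance_mm=tau)


def _smooth_offset_field(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    smoothness_mm: float,
    amplitude_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean spatially correlated offsets clipped into
    [-amplitude, amplitude].

    The field is standardized to unit variance and scaled so that offsets
    saturate the cap on roughly the outer 13% of the field (|z| > 1.5);
    normalizing by the field's global maximum instead would make the
    realized deformation amplitude shrink as the grid grows.  The 0.99
    shrink applied by callers avoids boundary-equality ties at exactly tau.
    """
    noise = rng.standard_normal(shape)
    sigma_vox = [smoothness_mm / s for s in spacing]
    field = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = field.std()
    if sd == 0:  # pragma: no cover - measure-zero event
        return np.zeros(shape)
    return np.clip(field / sd * (amplitude_mm / 1.5), -amplitude_mm, amplitude_mm)


def _candidate_mask(sdf: np.ndarray, offsets: np.ndarray, half_voxel_mm: float) -> np.ndarray:
    """Threshold the signed distance field at the boundary-displacement
    field, then keep the largest 26-connected component and fill internal
    holes."""
    cand = sdf < offsets + half_voxel_mm
    if not cand.any():
        return cand
    labels, n = ndimage.label(cand, structure=_FULL_STRUCTURE)
    if n > 1:
        sizes = ndimage.sum_labels(cand, labels, index=np.arange(1, n + 1))
        cand = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(cand)


def sample_mask(
    mask: BinaryMask,
    cfg: PerturbationConfig,
    rng: np.random.Generator,
    sdf: np.ndarray | None = None,
) -> BinaryMask:
    """Draw one perturbed mask honouring the tolerance contract.

    Postconditions: within tolerance of the original, single 26-connected
    component, no internal holes, core voxels (d < -tau) all kept and
    exterior voxels (d > tau) all untouched.  Raises
    :class:`SamplingFailureError` after ``max_attempts_per_mask`` rejected
    candidates.
    """
    if sdf is None:
        sdf = signed_distance_field(mask)
    tau = cfg.tolerance_mm
    half_voxel = 0.5 * min(mask.spacing)
    amplitude = tau * 0.99 - half_voxel
    if amplitude <= 0:
        raise SamplingFailureError(
            f"tolerance {tau} mm is below the grid's half-voxel size "
            f"{half_voxel} mm; no perturbation is representable"
        )
    for _ in range(cfg.max_attempts_per_mask):
        offsets = _smooth_offset_field(
            mask.shape, mask.spacing, cfg.smoothness_mm, amplitude, rng
        )
        cand = _candidate_mask(sdf, offsets, half_voxel)
        if not cand.any():
            continue
        candidate = BinaryMask(voxels=cand, spacing=mask.spacing, origin=mask.origin)
        if within_tolerance(mask, candidate, tau):
            return candidate
    raise SamplingFailureError(
        f"no valid perturbation in {cfg.max_attempts_per_mask} attempts "
        f"(tau={tau} mm, smoothness={cfg.smoothness_mm} mm); "
        "the tolerance may be too tight for this grid or the smoothness too small"
    )


def generate_realizations(mask: BinaryMask, cfg: PerturbationConfig) -> list[BinaryMask]:
    """``n_realizations`` independent perturbed masks (original NOT included;
    callers prepend it as realization 0).

    Each realization uses an RNG stream derived from ``(seed, index)``, so
    realization ``i`` is reproducible independently of how many are drawn.
    """
    sdf = signed_distance_field(mask)
    out = []
    for i in range(cfg.n_realizations):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, i)))
        out.append(sample_mask(mask, cfg, rng, sdf=sdf))
    return out
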