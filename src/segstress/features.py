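"""Radiomic feature extraction from an image-mask pair.

Native implementations of a documented ~25-feature subset spanning all the
IBSI families used by the uncertainty-to-effect analysis: first-order
statistics, shape, and the five texture-matrix families (GLCM, GLRLM,
GLSZM, GLDM, NGTDM).  Conventions follow the common pyradiomics defaults
wherever several IBSI-compliant choices exist:

* fixed-bin-size discretization anchored at the ROI minimum
  (``level = floor((I - min)/W) + 1``), default width 25 HU;
* texture matrices at distance 1 over the 13 unique 3D directions,
  symmetric GLCM, features computed per direction then averaged
  (GLSZM/GLDM/NGTDM are direction-free);
* 26-connectivity for GLSZM zones and GLDM/NGTDM neighbourhoods; GLDM with
  dependence criterion |delta level| <= 0.

Degenerate single-level ROIs use fixed, logged conventions (Contrast 0,
MCC and Correlation 1, Coarseness capped at 1e6) so downstream statistics
never see NaNs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from segstress.errors import DegenerateMaskError, ValidationError
from segstress.surface_metrics import surface_voxels
from segstress.volumes_io import BinaryMask, ImageVolume, RunConfig

logger = logging.getLogger(__name__)

#: cap applied to NGTDM Coarseness when its denominator vanishes
COARSENESS_CAP = 1e6

#: 13 unique 3D direction vectors (one per +/- pair), distance 1
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_FULL_STRUCTURE = np.ones((3, 3, 3), dtype=bool)

#: every feature name `extract_all` emits
SUPPORTED_FEATURES: tuple[str, ...] = (
    "firstorder_Maximum",
    "firstorder_Minimum",
    "firstorder_Mean",
    "firstorder_Median",
    "firstorder_Variance",
    "firstorder_Skewness",
    "firstorder_Kurtosis",
    "firstorder_Energy",
    "firstorder_Entropy",
    "firstorder_RootMeanSquared",
    "shape_VoxelVolume",
    "shape_SurfaceAreaApprox",
    "shape_Sphericity",
    "shape_Maximum3DDiameter",
    "glcm_JointEntropy",
    "glcm_Contrast",
    "glcm_Correlation",
    "glcm_MCC",
    "glrlm_GrayLevelNonUniformity",
    "glrlm_RunEntropy",
    "glszm_GrayLevelVariance",
    "glszm_GrayLevelNonUniformityNormalized",
    "gldm_GrayLevelNonUniformity",
    "ngtdm_Coarseness",
)


@dataclass
class DiscretizedROI:
    """Integer gray levels over the ROI; 0 marks voxels outside the mask."""

    levels: np.ndarray
    n_levels: int
    bin_width: float
    roi_voxel_count: int
    spacing: tuple[float, float, float]


@dataclass
class FeatureVector:
    """feature_name -> value map with extraction provenance."""

    values: dict[str, float]
    bin_width: float | None = None
    voxel_size: tuple[float, float, float] | None = None
    mask_id: str | None = None

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def keys(self):
        return self.values.keys()

    def update(self, other: "FeatureVector | dict") -> None:
        self.values.update(other.values if isinstance(other, FeatureVector) else other)


def _roi_values(img: ImageVolume, mask: BinaryMask) -> np.ndarray:
    if img.voxels.shape != mask.voxels.shape:
        raise ValidationError("image and mask grids differ")
    vals = img.voxels[mask.voxels]
    if vals.size == 0:
        raise DegenerateMaskError("empty ROI")
    return vals.astype(float)


def discretize(img: ImageVolume, mask: BinaryMask, bin_width: float) -> DiscretizedROI:
    """Fixed-bin-size discretization anchored at the ROI minimum."""
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    vals = _roi_values(img, mask)
    lo = vals.min()
    levels = np.zeros(img.voxels.shape, dtype=np.int32)
    levels[mask.voxels] = np.floor((vals - lo) / bin_width).astype(np.int32) + 1
    return DiscretizedROI(
        levels=levels,
        n_levels=int(levels.max()),
        bin_width=float(bin_width),
        roi_voxel_count=int(vals.size),
        spacing=mask.spacing,
    )


# ---------------------------------------------------------------------------
# first order & shape


def first_order(img: ImageVolume, mask: BinaryMask, bin_width: float = 25.0) -> FeatureVector:
    """Moments of the raw ROI intensities; Entropy uses the binned histogram.

    Variance/Skewness/Kurtosis are population moments; Kurtosis is the
    Pearson form m4/m2^2 (not excess).  Constant ROIs give Skewness and
    Kurtosis 0 by convention.
    """
    x = _roi_values(img, mask)
    mean = float(x.mean())
    var = float(x.var())
    if var > 0:
        centred = x - mean
        skew = float((centred**3).mean() / var**1.5)
        kurt = float((centred**4).mean() / var**2)
    else:
        skew = kurt = 0.0
    d = discretize(img, mask, bin_width)
    counts = np.bincount(d.levels[mask.voxels])[1:]
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    return FeatureVector(
        values={
            "firstorder_Maximum": float(x.max()),
            "firstorder_Minimum": float(x.min()),
            "firstorder_Mean": mean,
            "firstorder_Median": float(np.median(x)),
            "firstorder_Variance": var,
            "firstorder_Skewness": skew,
            "firstorder_Kurtosis": kurt,
            "firstorder_Energy": float((x**2).sum()),
            "firstorder_Entropy": entropy,
            "firstorder_RootMeanSquared": float(np.sqrt((x**2).mean())),
        },
        bin_width=bin_width,
        voxel_size=mask.spacing,
    )


def shape(mask: BinaryMask) -> FeatureVector:
    """Voxel-count volume, exposed-face surface area, sphericity and the
    maximum 3D diameter over surface voxel centres.

    ``SurfaceAreaApprox`` counts exposed voxel faces; that estimator is
    biased high on curved surfaces (staircase effect), so Sphericity uses a
    marching-cubes mesh area instead, keeping the ordering of shapes
    physically sensible (a digitized ball scores higher than a cube).
    """
    from skimage import measure

    m = mask.voxels
    sx, sy, sz = mask.spacing
    volume = mask.volume_mm3()
    face_areas = (sy * sz, sx * sz, sx * sy)
    area = 0.0
    for axis, fa in enumerate(face_areas):
        padded = np.pad(m, 1)
        exposed = padded & ~np.roll(padded, 1, axis=axis)
        area += fa * exposed.sum()
        exposed = padded & ~np.roll(padded, -1, axis=axis)
        area += fa * exposed.sum()
    verts, faces_, _, _ = measure.marching_cubes(
        np.pad(m, 1).astype(float), level=0.5, spacing=mask.spacing
    )
    mesh_area = float(measure.mesh_surface_area(verts, faces_))
    sphericity = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / mesh_area)
    pts = np.argwhere(surface_voxels(m)).astype(float) * np.asarray(mask.spacing)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # flat/degenerate clouds: brute-force over all surface points
    diameter = float(pdist(pts).max()) if len(pts) > 1 else 0.0
    return FeatureVector(
        values={
            "shape_VoxelVolume": volume,
            "shape_SurfaceAreaApprox": float(area),
            "shape_Sphericity": sphericity,
            "shape_Maximum3DDiameter": diameter,
        },
        voxel_size=mask.spacing,
    )


# ---------------------------------------------------------------------------
# texture matrices


def _shifted_pairs(levels: np.ndarray, d: tuple[int, int, int]):
    """Aligned (source, destination) level views offset by direction ``d``."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for axis, step in enumerate(d):
        if step == 1:
            src[axis] = slice(None, -1)
            dst[axis] = slice(1, None)
        elif step == -1:
            src[axis] = slice(1, None)
            dst[axis] = slice(None, -1)
    return levels[tuple(src)], levels[tuple(dst)]


def glcm_matrix(d: DiscretizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Symmetric gray-level co-occurrence counts for one direction."""
    n = d.n_levels
    a, b = _shifted_pairs(d.levels, direction)
    valid = (a > 0) & (b > 0)
    P = np.zeros((n, n), dtype=float)
    np.add.at(P, (a[valid] - 1, b[valid] - 1), 1.0)
    return P + P.T


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    total = P.sum()
    if total == 0:
        return {}
    p = P / total
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    ii, jj = np.meshgrid(i, i, indexing="ij")
    nz = p > 0
    joint_entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sigma2 > 0:
        correlation = float((((ii - mu) * (jj - mu) * p).sum()) / sigma2)
    else:
        correlation = 1.0
    return {
        "glcm_JointEntropy": joint_entropy,
        "glcm_Contrast": contrast,
        "glcm_Correlation": correlation,
        "glcm_MCC": _mcc(p, px),
    }


def _mcc(p: np.ndarray, px: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the second-largest eigenvalue
    of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))."""
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    ps = p[np.ix_(keep, keep)]
    pxs = px[keep]
    Q = (ps / pxs[:, None]) @ (ps / pxs[None, :]).T
    eig = np.linalg.eigvals(Q)
    eig = np.sort(np.abs(eig))[::-1]
    second = max(float(eig[1]), 0.0)
    return float(np.sqrt(second))


def glcm_features(d: DiscretizedROI) -> FeatureVector:
    """GLCM JointEntropy, Contrast, Correlation and MCC averaged over the 13
    unique directions."""
    if d.n_levels == 1:
        logger.info("single-level ROI: GLCM degenerate conventions applied")
        return FeatureVector(
            values={
                "glcm_JointEntropy": 0.0,
                "glcm_Contrast": 0.0,
                "glcm_Correlation": 1.0,
                "glcm_MCC": 1.0,
            }
        )
    per_dir: list[dict[str, float]] = []
    for direction in DIRECTIONS_13:
        feats = _glcm_features_single(glcm_matrix(d, direction))
        if feats:
            per_dir.append(feats)
    return FeatureVector(values=_average_dicts(per_dir))


def glrlm_matrix(d: DiscretizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts R[level-1, length-1] for one direction."""
    L = d.levels
    shape_ = L.shape
    step = np.asarray(direction)
    idx = np.argwhere(L > 0)
    # run starts: predecessor along the direction is out of grid / out of ROI
    # / different level
    prev = idx - step
    in_grid = np.all((prev >= 0) & (prev < shape_), axis=1)
    same_prev = np.zeros(len(idx), dtype=bool)
    pg = prev[in_grid]
    same_prev[in_grid] = L[pg[:, 0], pg[:, 1], pg[:, 2]] == L[idx[in_grid, 0], idx[in_grid, 1], idx[in_grid, 2]]
    starts = idx[~same_prev]
    levels_at_start = L[starts[:, 0], starts[:, 1], starts[:, 2]]
    lengths = np.ones(len(starts), dtype=int)
    pos = starts.copy()
    alive = np.ones(len(starts), dtype=bool)
    while alive.any():
        nxt = pos[alive] + step
        ok = np.all((nxt >= 0) & (nxt < shape_), axis=1)
        cont = np.zeros(len(nxt), dtype=bool)
        ng = nxt[ok]
        cont[ok] = L[ng[:, 0], ng[:, 1], ng[:, 2]] == levels_at_start[alive][ok]
        alive_idx = np.flatnonzero(alive)
        lengths[alive_idx[cont]] += 1
        pos[alive_idx[cont]] += step
        alive[alive_idx[~cont]] = False
    R = np.zeros((d.n_levels, int(lengths.max(initial=1))), dtype=float)
    np.add.at(R, (levels_at_start - 1, lengths - 1), 1.0)
    return R


def _glrlm_features_single(R: np.ndarray) -> dict[str, float]:
    n_runs = R.sum()
    if n_runs == 0:
        return {}
    level_sums = R.sum(axis=1)
    gln = float((level_sums**2).sum() / n_runs)
    p = R / n_runs
    nz = p > 0
    run_entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    return {"glrlm_GrayLevelNonUniformity": gln, "glrlm_RunEntropy": run_entropy}


def glrlm_features(d: DiscretizedROI) -> FeatureVector:
    """GLRLM GrayLevelNonUniformity and RunEntropy averaged over the 13
    unique directions."""
    per_dir = [_glrlm_features_single(glrlm_matrix(d, dd)) for dd in DIRECTIONS_13]
    return FeatureVector(values=_average_dicts([f for f in per_dir if f]))


def glszm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Size-zone counts Z[level-1, size-1]; zones are 26-connected
    same-level components."""
    zones: list[tuple[int, int]] = []
    for lvl in range(1, d.n_levels + 1):
        labels, n = ndimage.label(d.levels == lvl, structure=_FULL_STRUCTURE)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(d.levels == lvl, labels, index=np.arange(1, n + 1))
        zones.extend((lvl, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    Z = np.zeros((d.n_levels, max_size), dtype=float)
    for lvl, s in zones:
        Z[lvl - 1, s - 1] += 1
    return Z


def glszm_features(d: DiscretizedROI) -> FeatureVector:
    """GLSZM GrayLevelVariance and GrayLevelNonUniformityNormalized."""
    Z = glszm_matrix(d)
    n_zones = Z.sum()
    p = Z / n_zones
    i = np.arange(1, d.n_levels + 1, dtype=float)
    p_level = p.sum(axis=1)
    mu = float((i * p_level).sum())
    glv = float(((i - mu) ** 2 * p_level).sum())
    glnn = float((Z.sum(axis=1) ** 2).sum() / n_zones**2)
    return FeatureVector(
        values={
            "glszm_GrayLevelVariance": glv,
            "glszm_GrayLevelNonUniformityNormalized": glnn,
        }
    )


def gldm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Dependence counts D[level-1, k] where k is the number of 26-neighbours
    sharing the voxel's level (dependence criterion |delta| <= 0)."""
    L = d.levels
    dep = np.zeros(L.shape, dtype=np.int32)
    for direction in DIRECTIONS_13:
        a, b = _shifted_pairs(L, direction)
        match = (a > 0) & (a == b)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for axis, stp in enumerate(direction):
            if stp == 1:
                src[axis] = slice(None, -1)
                dst[axis] = slice(1, None)
            elif stp == -1:
                src[axis] = slice(1, None)
                dst[axis] = slice(None, -1)
        dep[tuple(src)] += match
        dep[tuple(dst)] += match
    roi = L > 0
    levels = L[roi] - 1
    deps = dep[roi]
    D = np.zeros((d.n_levels, int(deps.max(initial=0)) + 1), dtype=float)
    np.add.at(D, (levels, deps), 1.0)
    return D


def gldm_features(d: DiscretizedROI) -> FeatureVector:
    """GLDM GrayLevelNonUniformity."""
    D = gldm_matrix(d)
    n_dep = D.sum()
    gln = float((D.sum(axis=1) ** 2).sum() / n_dep)
    return FeatureVector(values={"gldm_GrayLevelNonUniformity": gln})


def ngtdm_table(d: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence counts n_i and coarseness sums
    s_i = sum over voxels of level i of |i - mean level of valid
    26-neighbours|; voxels with no in-ROI neighbour are excluded."""
    L = d.levels.astype(float)
    roi = d.levels > 0
    nb_sum = np.zeros(L.shape)
    nb_cnt = np.zeros(L.shape)
    for direction in DIRECTIONS_13:
        a, b = _shifted_pairs(d.levels, direction)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for axis, stp in enumerate(direction):
            if stp == 1:
                src[axis] = slice(None, -1)
                dst[axis] = slice(1, None)
            elif stp == -1:
                src[axis] = slice(1, None)
                dst[axis] = slice(None, -1)
        nb_sum[tuple(src)] += np.where(b > 0, b, 0)
        nb_cnt[tuple(src)] += b > 0
        nb_sum[tuple(dst)] += np.where(a > 0, a, 0)
        nb_cnt[tuple(dst)] += a > 0
    valid = roi & (nb_cnt > 0)
    n_i = np.zeros(d.n_levels)
    s_i = np.zeros(d.n_levels)
    if valid.any():
        lv = d.levels[valid]
        diff = np.abs(L[valid] - nb_sum[valid] / nb_cnt[valid])
        np.add.at(n_i, lv - 1, 1.0)
        np.add.at(s_i, lv - 1, diff)
    return n_i, s_i


def ngtdm_features(d: DiscretizedROI) -> FeatureVector:
    """NGTDM Coarseness, capped when the denominator vanishes."""
    n_i, s_i = ngtdm_table(d)
    total = n_i.sum()
    denom = float((n_i / total * s_i).sum()) if total > 0 else 0.0
    if denom <= 0:
        logger.info("NGTDM denominator 0: Coarseness capped at %g", COARSENESS_CAP)
        return FeatureVector(values={"ngtdm_Coarseness": COARSENESS_CAP})
    return FeatureVector(values={"ngtdm_Coarseness": 1.0 / denom})


def _average_dicts(dicts: list[dict[str, float]]) -> dict[str, float]:
    if not dicts:
        return {}
    keys = dicts[0].keys()
    return {k: float(np.mean([d[k] for d in dicts])) for k in keys}


# ---------------------------------------------------------------------------


def extract_all(img: ImageVolume, mask: BinaryMask, cfg: RunConfig | None = None) -> FeatureVector:
    """All supported features from one image-mask pair.  Pure function of
    its inputs."""
    cfg = cfg or RunConfig()
    out = first_order(img, mask, bin_width=cfg.bin_width_hu)
    out.update(shape(mask))
    d = discretize(img, mask, cfg.bin_width_hu)
    out.update(glcm_features(d))
    out.update(glrlm_features(d))
    out.update(glszm_features(d))
    out.update(gldm_features(d))
    out.update(ngtdm_features(d))
    return out


def extract_with_backend(img: ImageVolume, mask: BinaryMask, cfg: RunConfig | None = None):
    """Optional hook delegating extraction to the pyradiomics backend when it
    is installed; raises ImportError otherwise."""
    import radiomics  # noqa: F401  (optional dependency)
    from radiomics.featureextractor import RadiomicsFeatureExtractor

    cfg = cfg or RunConfig()
    import SimpleITK as sitk

    itk_img = sitk.GetImageFromArray(np.ascontiguousarray(img.voxels.transpose(2, 1, 0)))
    itk_img.SetSpacing(img.spacing)
    itk_msk = sitk.GetImageFromArray(
        np.ascontiguousarray(mask.voxels.transpose(2, 1, 0)).astype(np.uint8)
    )
    itk_msk.SetSpacing(mask.spacing)
    extractor = RadiomicsFeatureExtractor(binWidth=cfg.bin_width_hu)
    return extractor.execute(itk_img, itk_msk)
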