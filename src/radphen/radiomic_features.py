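"""Radiomic descriptors of a 3D image + binary tumor mask.

Implements a documented subset of the nine classical descriptor families:
first-order intensity statistics, 3D shape, the five gray-level texture
matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM), and Laplacian-of-Gaussian and
single-level Haar wavelet filtered variants.  Intensities are discretized to
a fixed number of equal-width bins over the in-mask range (scale-free for
synthetic data); directional families are averaged over the 13 unique 3D
directions; zones and dependences use 26-connectivity.  Every texture matrix
is normalized to a probability distribution before statistics; features
whose normalizer vanishes on a degenerate (single-gray-level) input return 0
and the event is logged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeWithMask",
    "QuantizedVolume",
    "FeatureExtractionConfig",
    "discretize",
    "first_order_features",
    "shape_features",
    "texture_features",
    "filter_image",
    "extract_feature_vector",
    "read_nifti_volume",
    "write_nifti_volume",
    "DIRECTIONS_3D",
]

# the 13 unique 3D directions (one representative per +/- pair)
DIRECTIONS_3D = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]
assert len(DIRECTIONS_3D) == 13

_NEIGHBORS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


@dataclass
class VolumeWithMask:
    image: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.image.ndim != 3 or self.image.shape != self.mask.shape:
            raise ValueError("image and mask must be 3-D arrays of the same shape")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def in_mask(self) -> np.ndarray:
        return self.image[self.mask]


@dataclass
class QuantizedVolume:
    levels: np.ndarray       # integer grid, 1..G inside the mask, 0 outside
    mask: np.ndarray
    n_levels: int


def discretize(vol: VolumeWithMask, n_bins: int = 32) -> QuantizedVolume:
    """Equal-width binning of in-mask intensities into 1..n_bins.

    A constant image occupies the single level 1 (effective G = 1).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = vol.in_mask
    lo, hi = float(values.min()), float(values.max())
    levels = np.zeros(vol.image.shape, dtype=np.int64)
    if hi == lo:
        levels[vol.mask] = 1
        return QuantizedVolume(levels=levels, mask=vol.mask, n_levels=1)
    binned = np.floor((vol.image - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    binned = np.clip(binned, 1, n_bins)
    levels[vol.mask] = binned[vol.mask]
    return QuantizedVolume(levels=levels, mask=vol.mask, n_levels=n_bins)


def first_order_features(vol: VolumeWithMask, n_bins: int = 32) -> dict[str, float]:
    """Intensity statistics of the in-mask voxels.

    Skewness and kurtosis use population moments (kurtosis non-excess, so a
    Gaussian gives 3); entropy and uniformity are computed on the
    equal-width-discretized histogram.
    """
    x = vol.in_mask.astype(float)
    n = x.size
    mean = float(x.mean())
    centered = x - mean
    m2 = float((centered**2).mean())
    m3 = float((centered**3).mean())
    m4 = float((centered**4).mean())
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 if m2 > 0 else 0.0
    q = discretize(vol, n_bins=n_bins)
    counts = np.bincount(q.levels[q.mask], minlength=q.n_levels + 1)[1:]
    p = counts / n
    p_nz = p[p > 0]
    p10, p90 = np.percentile(x, [10, 90])
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "variance": m2,
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "energy": float((x**2).sum()),
        "entropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "min": float(x.min()),
        "max": float(x.max()),
        "range": float(x.max() - x.min()),
        "mad": float(np.abs(centered).mean()),
        "rms": float(np.sqrt((x**2).mean())),
        "uniformity": float((p**2).sum()),
        "p10": float(p10),
        "p90": float(p90),
    }


def shape_features(vol: VolumeWithMask) -> dict[str, float]:
    """3D size and shape of the mask.

    Surface area counts exposed voxel faces (not marching cubes); elongation
    and flatness come from the eigenvalues of the physical voxel-coordinate
    covariance, PyRadiomics-style sqrt ratios.
    """
    mask = vol.mask
    sz, sy, sx = vol.spacing
    voxvol = sz * sy * sx
    n_vox = int(mask.sum())
    volume = n_vox * voxvol

    padded = np.pad(mask, 1)
    face_areas = (sy * sx, sz * sx, sz * sy)
    area = 0.0
    for axis, fa in enumerate(face_areas):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        area += float(np.abs(diff).sum()) * fa

    coords = np.argwhere(mask).astype(float) * np.asarray(vol.spacing)
    if n_vox == 1:
        diameter = 0.0
    else:
        pts = coords
        if n_vox > 500:
            from scipy.spatial import ConvexHull, QhullError

            try:
                pts = coords[ConvexHull(coords).vertices]
            except QhullError:  # degenerate (coplanar) masks
                pass
        diff = pts[:, None, :] - pts[None, :, :]
        diameter = float(np.sqrt((diff**2).sum(axis=2)).max())

    if n_vox < 2:
        elongation = flatness = 1.0
    else:
        eig = np.sort(np.linalg.eigvalsh(np.cov(coords, rowvar=False)))[::-1]
        eig = np.clip(eig, 0.0, None)
        elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
        flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    sphericity = float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area)
    return {
        "volume": float(volume),
        "voxel_count": float(n_vox),
        "surface_area": float(area),
        "sphericity": sphericity,
        "max_diameter_3d": diameter,
        "elongation": elongation,
        "flatness": flatness,
    }


# ---------------------------------------------------------------------------
# texture matrices
# ---------------------------------------------------------------------------


def _shift_valid(shape, offset):
    """Slices (src, dst) such that dst = src + offset, both inside the grid."""
    src, dst = [], []
    for s, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(0, s - o))
            dst.append(slice(o, s))
        else:
            src.append(slice(-o, s))
            dst.append(slice(0, s + o))
    return tuple(src), tuple(dst)


def glcm_matrix(q: QuantizedVolume, direction, distance: int = 1, symmetric: bool = True) -> np.ndarray:
    """Gray-level co-occurrence counts for one direction (unnormalized)."""
    G = q.n_levels
    off = tuple(int(d) * distance for d in direction)
    src, dst = _shift_valid(q.levels.shape, off)
    valid = q.mask[src] & q.mask[dst]
    i = q.levels[src][valid] - 1
    j = q.levels[dst][valid] - 1
    mat = np.bincount(i * G + j, minlength=G * G).reshape(G, G).astype(float)
    if symmetric:
        mat = mat + mat.T
    return mat


def _glcm_features(P: np.ndarray) -> dict[str, float]:
    G = P.shape[0]
    total = P.sum()
    if total == 0:
        logger.warning("GLCM has no co-occurring pairs; features set to 0")
        return {k: 0.0 for k in ("contrast", "correlation", "joint_entropy", "energy", "homogeneity")}
    P = P / total
    i = np.arange(1, G + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu_i = float((i * px).sum())
    sig_i = float(np.sqrt(((i - mu_i) ** 2 * px).sum()))
    py = P.sum(axis=0)
    mu_j = float((i * py).sum())
    sig_j = float(np.sqrt(((i - mu_j) ** 2 * py).sum()))
    nz = P[P > 0]
    if sig_i > 0 and sig_j > 0:
        corr = float((((ii - mu_i) * (jj - mu_j)) * P).sum() / (sig_i * sig_j))
    else:
        logger.warning("GLCM marginal sd vanishes (single gray level); correlation set to 0")
        corr = 0.0
    return {
        "contrast": float((((ii - jj) ** 2) * P).sum()),
        "correlation": corr,
        "joint_entropy": float(-(nz * np.log2(nz)).sum()),
        "energy": float((P**2).sum()),
        "homogeneity": float((P / (1.0 + np.abs(ii - jj))).sum()),
    }


def glrlm_matrix(q: QuantizedVolume, direction) -> np.ndarray:
    """Run-length counts R[g, l] for one direction (runs of equal level)."""
    G = q.n_levels
    shape = q.levels.shape
    off = tuple(int(d) for d in direction)
    # a voxel starts a run if its predecessor along -direction is outside the
    # grid, outside the mask, or a different gray level
    src, dst = _shift_valid(shape, off)
    same_next = np.zeros(shape, dtype=bool)  # voxel continues into its successor
    same_next[src] = q.mask[src] & q.mask[dst] & (q.levels[src] == q.levels[dst])
    is_start = q.mask.copy()
    is_start[dst] &= ~same_next[src]

    starts = np.argwhere(is_start)
    levels = q.levels[is_start] - 1
    lengths = np.ones(len(starts), dtype=np.int64)
    cur = starts.copy()
    active = np.arange(len(starts))
    offv = np.asarray(off)
    while active.size:
        cont = same_next[tuple(cur[active].T)]
        active = active[cont]
        if active.size == 0:
            break
        cur[active] += offv
        lengths[active] += 1
    max_len = int(lengths.max()) if len(lengths) else 1
    mat = np.zeros((G, max_len), dtype=float)
    np.add.at(mat, (levels, lengths - 1), 1.0)
    return mat


def _run_zone_features(mat: np.ndarray, n_voxels: int, prefix: str) -> dict[str, float]:
    """Shared run-length / size-zone statistics; columns are lengths/sizes."""
    n_runs = mat.sum()
    if n_runs == 0:
        logger.warning("empty %s matrix; features set to 0", prefix)
        keys = ("short_emphasis", "long_emphasis", "gray_level_non_uniformity", "length_non_uniformity", "percentage")
        return {k: 0.0 for k in keys}
    lengths = np.arange(1, mat.shape[1] + 1, dtype=float)
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    return {
        "short_emphasis": float((col / lengths**2).sum() / n_runs),
        "long_emphasis": float((col * lengths**2).sum() / n_runs),
        "gray_level_non_uniformity": float((row**2).sum() / n_runs),
        "length_non_uniformity": float((col**2).sum() / n_runs),
        "percentage": float(n_runs / n_voxels),
    }


def glszm_matrix(q: QuantizedVolume) -> np.ndarray:
    """Size-zone counts Z[g, s]: 26-connected components of equal gray level."""
    G = q.n_levels
    structure = np.ones((3, 3, 3), dtype=bool)
    counts: list[tuple[int, int]] = []
    for g in range(1, G + 1):
        labeled, n_zones = ndimage.label((q.levels == g) & q.mask, structure=structure)
        if n_zones:
            sizes = np.bincount(labeled.ravel())[1:]
            counts.extend((g - 1, int(s)) for s in sizes)
    if not counts:
        return np.zeros((G, 1))
    max_size = max(s for _, s in counts)
    mat = np.zeros((G, max_size), dtype=float)
    for g, s in counts:
        mat[g, s - 1] += 1.0
    return mat


def _neighbor_stats(q: QuantizedVolume):
    """Per-voxel in-mask 26-neighbor count, level sum, and equal-level count."""
    shape = q.levels.shape
    n_nb = np.zeros(shape, dtype=np.int64)
    sum_nb = np.zeros(shape, dtype=float)
    eq_nb = np.zeros(shape, dtype=np.int64)
    for off in _NEIGHBORS_26:
        src, dst = _shift_valid(shape, off)
        ok = q.mask[dst]
        n_nb[src][...] = n_nb[src] + ok
        sum_nb[src][...] = sum_nb[src] + np.where(ok, q.levels[dst], 0)
        eq_nb[src][...] = eq_nb[src] + (ok & (q.levels[src] == q.levels[dst]))
    return n_nb, sum_nb, eq_nb


def gldm_matrix(q: QuantizedVolume, alpha: int = 0) -> np.ndarray:
    """Dependence counts D[g, k]: k = 1 + #26-neighbors within alpha levels."""
    shape = q.levels.shape
    dep = np.ones(shape, dtype=np.int64)
    for off in _NEIGHBORS_26:
        src, dst = _shift_valid(shape, off)
        close = q.mask[dst] & (np.abs(q.levels[src] - q.levels[dst]) <= alpha)
        dep[src] += close
    g = q.levels[q.mask] - 1
    k = dep[q.mask] - 1
    G = q.n_levels
    kmax = int(k.max()) + 1
    mat = np.zeros((G, kmax), dtype=float)
    np.add.at(mat, (g, k), 1.0)
    return mat


def _gldm_features(mat: np.ndarray) -> dict[str, float]:
    n = mat.sum()
    ks = np.arange(1, mat.shape[1] + 1, dtype=float)
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    p = mat / n
    p_nz = p[p > 0]
    return {
        "small_dependence_emphasis": float((col / ks**2).sum() / n),
        "large_dependence_emphasis": float((col * ks**2).sum() / n),
        "gray_level_non_uniformity": float((row**2).sum() / n),
        "dependence_non_uniformity": float((col**2).sum() / n),
        "dependence_entropy": float(-(p_nz * np.log2(p_nz)).sum()),
    }


def _ngtdm_features(q: QuantizedVolume) -> dict[str, float]:
    n_nb, sum_nb, _ = _neighbor_stats(q)
    mask = q.mask & (n_nb > 0)
    g = q.levels[mask].astype(float)
    abar = sum_nb[mask] / n_nb[mask]
    N = g.size
    G = q.n_levels
    s = np.zeros(G)
    n_g = np.zeros(G)
    np.add.at(s, (g - 1).astype(int), np.abs(g - abar))
    np.add.at(n_g, (g - 1).astype(int), 1.0)
    p = n_g / N
    present = np.flatnonzero(n_g > 0)
    levels = np.arange(1, G + 1, dtype=float)
    n_p = present.size

    def zero(name: str) -> float:
        logger.warning("NGTDM %s normalizer vanishes; set to 0", name)
        return 0.0

    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 0 else zero("coarseness")
    if n_p > 1:
        gi = levels[present]
        pi = p[present]
        si = s[present]
        dif2 = (gi[:, None] - gi[None, :]) ** 2
        contrast = float((pi[:, None] * pi[None, :] * dif2).sum() / (n_p * (n_p - 1)) * s.sum() / N)
        busy_den = float(np.abs(gi[:, None] * pi[:, None] - gi[None, :] * pi[None, :]).sum())
        busyness = ps / busy_den if busy_den > 0 else zero("busyness")
        pair_num = pi[:, None] * si[:, None] + pi[None, :] * si[None, :]
        complexity = float(
            (np.abs(gi[:, None] - gi[None, :]) * pair_num / (pi[:, None] + pi[None, :])).sum() / N
        )
        s_sum = float(s.sum())
        strength = (
            float(((pi[:, None] + pi[None, :]) * dif2).sum()) / s_sum if s_sum > 0 else zero("strength")
        )
    else:
        contrast = 0.0
        busyness = zero("busyness")
        complexity = 0.0
        strength = zero("strength")
    return {
        "coarseness": float(coarseness),
        "contrast": contrast,
        "busyness": float(busyness),
        "complexity": complexity,
        "strength": float(strength),
    }


_FAMILIES = ("glcm", "glrlm", "glszm", "gldm", "ngtdm")


def texture_features(
    q: QuantizedVolume,
    family: str,
    distance: int = 1,
    symmetric: bool = True,
    alpha: int = 0,
) -> dict[str, float]:
    """Standard statistics of one texture-matrix family.

    Directional families (GLCM, GLRLM) average their features over the 13
    unique 3D directions; GLSZM/GLDM/NGTDM are rotation-independent by
    construction.
    """
    family = family.lower()
    if family not in _FAMILIES:
        raise ValueError(f"unknown texture family {family!r}")
    n_voxels = int(q.mask.sum())
    if family == "glcm":
        per_dir = [
            _glcm_features(glcm_matrix(q, d, distance=distance, symmetric=symmetric))
            for d in DIRECTIONS_3D
        ]
        return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}
    if family == "glrlm":
        per_dir = [_run_zone_features(glrlm_matrix(q, d), n_voxels, "GLRLM") for d in DIRECTIONS_3D]
        avg = {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}
        return {
            "short_run_emphasis": avg["short_emphasis"],
            "long_run_emphasis": avg["long_emphasis"],
            "gray_level_non_uniformity": avg["gray_level_non_uniformity"],
            "run_length_non_uniformity": avg["length_non_uniformity"],
            "run_percentage": avg["percentage"],
        }
    if family == "glszm":
        feats = _run_zone_features(glszm_matrix(q), n_voxels, "GLSZM")
        return {
            "small_zone_emphasis": feats["short_emphasis"],
            "large_zone_emphasis": feats["long_emphasis"],
            "gray_level_non_uniformity": feats["gray_level_non_uniformity"],
            "zone_size_non_uniformity": feats["length_non_uniformity"],
            "zone_percentage": feats["percentage"],
        }
    if family == "gldm":
        return _gldm_features(gldm_matrix(q, alpha=alpha))
    return _ngtdm_features(q)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

_WAVELET_CODES = {
    "".join(c): "".join("a" if ch == "L" else "d" for ch in c)
    for c in itertools.product("LH", repeat=3)
}


def filter_image(vol: VolumeWithMask, kind: str, sigma_mm: float | None = None) -> VolumeWithMask:
    """Filtered variant of the image (mask unchanged).

    ``kind='log'`` needs ``sigma_mm``: Gaussian smoothing at a physical scale
    (converted to voxels via the spacing) followed by a spacing-aware discrete
    Laplacian.  ``kind`` may also be a 3-letter wavelet subband code
    (LLL..HHH): one-level separable Haar transform with the requested subband
    upsampled back to the grid shape.
    """
    if kind == "log":
        if sigma_mm is None or sigma_mm <= 0:
            raise ValueError("LoG filter needs sigma_mm > 0")
        sigma_vox = [sigma_mm / s for s in vol.spacing]
        smoothed = ndimage.gaussian_filter(vol.image, sigma=sigma_vox, mode="nearest")
        out = np.zeros_like(smoothed)
        for axis, h in enumerate(vol.spacing):
            out += ndimage.correlate1d(smoothed, [1.0, -2.0, 1.0], axis=axis, mode="nearest") / h**2
        return VolumeWithMask(image=out, mask=vol.mask, spacing=vol.spacing)
    code = kind.upper()
    if code in _WAVELET_CODES:
        import pywt

        coeffs = pywt.dwtn(vol.image, "haar")
        sub = coeffs[_WAVELET_CODES[code]]
        up = sub
        for axis in range(3):
            up = np.repeat(up, 2, axis=axis)
        up = up[tuple(slice(0, s) for s in vol.image.shape)]
        return VolumeWithMask(image=up, mask=vol.mask, spacing=vol.spacing)
    raise ValueError(f"unknown filter kind {kind!r}")


@dataclass(frozen=True)
class FeatureExtractionConfig:
    n_bins: int = 32
    distance: int = 1
    glcm_symmetric: bool = True
    gldm_alpha: int = 0
    families: tuple[str, ...] = _FAMILIES
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0)
    wavelet_subbands: tuple[str, ...] = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def extract_feature_vector(
    vol: VolumeWithMask, config: FeatureExtractionConfig | None = None
) -> dict[str, float]:
    """Full named feature vector: original first-order + shape + textures,
    then first-order + textures on every configured filtered image.

    Names follow ``filter_family_feature`` (e.g. ``original_glcm_contrast``,
    ``log-sigma-2mm_firstorder_mean``); the order is deterministic.
    """
    config = config or FeatureExtractionConfig()
    out: dict[str, float] = {}

    def add_image(tag: str, v: VolumeWithMask, with_shape: bool) -> None:
        for name, val in first_order_features(v, n_bins=config.n_bins).items():
            out[f"{tag}_firstorder_{name}"] = val
        if with_shape:
            for name, val in shape_features(v).items():
                out[f"{tag}_shape_{name}"] = val
        q = discretize(v, n_bins=config.n_bins)
        for family in config.families:
            feats = texture_features(
                q,
                family,
                distance=config.distance,
                symmetric=config.glcm_symmetric,
                alpha=config.gldm_alpha,
            )
            for name, val in feats.items():
                out[f"{tag}_{family}_{name}"] = val

    add_image("original", vol, with_shape=True)
    for sigma in config.log_sigmas_mm:
        tag = f"log-sigma-{sigma:g}mm"
        add_image(tag, filter_image(vol, "log", sigma_mm=sigma), with_shape=False)
    for code in config.wavelet_subbands:
        add_image(f"wavelet-{code}", filter_image(vol, code), with_shape=False)
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise FloatingPointError(f"non-finite features: {bad[:5]}")
    return out


def read_nifti_volume(image_path, mask_path) -> VolumeWithMask:
    """Load an image + mask pair from NIfTI files (spacing from the header)."""
    import nibabel as nib

    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeWithMask(
        image=np.asarray(img.dataobj, dtype=float),
        mask=np.asarray(msk.dataobj) > 0.5,
        spacing=spacing,
    )


def write_nifti_volume(image: np.ndarray, spacing, path) -> None:
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float32), affine), str(path))
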