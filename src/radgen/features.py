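"""Whole-volume radiomic feature extraction.

Each case yields a 53-feature vector: 17 intensity/texture features per
channel (VIBE+C, ADC, b1000) plus two shared shape features (tumor volume
and the volume-decoupled surface/volume ratio ``normsurfvolratio``).

Texture matrices (GLCM, GLRLM) are computed 2D-wise on paraxial slices —
the third array axis indexes slices — restricted to in-mask pixels, and
averaged over the tumor-bearing slices.  Per-field-strength Z-scoring
removes systematic intensity offsets between 1.5T and 3T scanners.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
from scipy import ndimage, signal, stats
from skimage import measure
from skimage.filters import gabor_kernel

from .image import CHANNELS, StudyCase, TumorMask, connected_components

PER_CHANNEL_FEATURES = (
    "meanint",
    "stdint",
    "mean15perc",
    "kurtosis",
    "skewness",
    "entropy",
    "gabor",
    "glcm_contrast",
    "glcm_homogeneity",
    "glcm_energy",
    "glcm_correlation",
    "glrlm_SRE",
    "glrlm_LRE",
    "glrlm_LGRE",
    "glrlm_HGRE",
    "clustersize",
    "clustindex",
)
SHAPE_FEATURES = ("vol", "normsurfvolratio")

#: Canonical order of the 53 features (17 x 3 channels + 2 shape).
FEATURE_NAMES = tuple(
    f"{chan}_{feat}" for chan in CHANNELS for feat in PER_CHANNEL_FEATURES
) + SHAPE_FEATURES

assert len(FEATURE_NAMES) == 53


@dataclasses.dataclass(frozen=True)
class RadiomicsConfig:
    """Fixed extraction parameters.

    Quantization and direction sets are conventional texture-analysis
    defaults; the Gabor bank has 4 frequencies x 4 orientations = 16
    filters.  ``gabor_eps_factor`` scales the division guard by the
    in-mask intensity range so the feature is invariant to global
    intensity scaling.
    """

    glcm_levels: int = 32
    glcm_offsets: tuple[int, ...] = (1, 2, 3, 4)
    glrlm_levels: int = 16
    # in-plane directions as (drow, dcol): 0, 45, 90, 135 degrees
    directions: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
    gabor_frequencies: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4)
    gabor_orientations: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    gabor_eps_factor: float = 1e-6
    entropy_bins: int = 64
    min_cluster_voxels: int = 3

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["directions"] = [list(t) for t in self.directions]
        for k in ("glcm_offsets", "gabor_frequencies", "gabor_orientations"):
            d[k] = list(d[k])
        return d


DEFAULT_CONFIG = RadiomicsConfig()


class DegenerateFeatureWarning(UserWarning):
    """A documented degenerate-input convention was applied."""


# ---------------------------------------------------------------------------
# Shape features
# ---------------------------------------------------------------------------

def compute_volume(mask: TumorMask) -> float:
    """Tumor volume in ml: voxel count x voxel volume (mm^3 -> ml)."""
    n = mask.n_voxels
    if n == 0:
        raise ValueError("empty mask has no volume")
    return n * mask.voxel_volume_mm3 / 1000.0


@dataclasses.dataclass(frozen=True)
class ShapeDescriptor:
    """Volume V (ml), surface area A (mm^2), equal-volume-sphere radius r
    (mm), and normsurfvolratio = (V/r^3)/(A/r^2) = V/(A*r), which is 1/3
    for a sphere and smaller for any other shape."""

    volume_ml: float
    surface_mm2: float
    radius_mm: float
    normsurfvolratio: float


def compute_shape(mask: TumorMask, smoothing_iterations: int = 10) -> ShapeDescriptor:
    """Shape descriptor from a marching-cubes triangulation of the mask.

    The raw triangulation of a binary volume carries staircase facets that
    bias the surface area upward (about +9% for a digital sphere); a few
    Taubin smoothing passes on the mesh remove the staircase without
    shrinking the surface, leaving both spheres and flat-faced shapes
    within a few percent of their analytic areas.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty mask has no shape")
    v_mm3 = mask.n_voxels * mask.voxel_volume_mm3
    padded = np.pad(mask.voxels.astype(float), 1)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - degenerate masks
        raise ValueError(f"surface undefined for this mask: {exc}") from exc
    import trimesh
    from trimesh import smoothing as tsmooth

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if smoothing_iterations > 0:
        tsmooth.filter_taubin(mesh, iterations=smoothing_iterations)
    area_mm2 = float(mesh.area)
    r_mm = (3.0 * v_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    nsvr = v_mm3 / (area_mm2 * r_mm)
    return ShapeDescriptor(v_mm3 / 1000.0, area_mm2, r_mm, nsvr)


# ---------------------------------------------------------------------------
# First-order intensity features
# ---------------------------------------------------------------------------

def first_order_features(values: np.ndarray, bins: int = 64) -> dict[str, float]:
    """Mean, SD, mean of lowest 15% intensities, excess kurtosis, skewness,
    and Shannon entropy (natural log) of the in-mask intensity histogram.

    Constant input: SD and entropy are 0 and skewness/kurtosis are defined
    as 0 (warned).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    mean = float(values.mean())
    sd = float(values.std())
    k15 = int(np.ceil(0.15 * values.size))
    mean15 = float(np.sort(values)[:k15].mean())
    if sd == 0.0:
        warnings.warn("constant in-mask intensities: skewness/kurtosis set to 0",
                      DegenerateFeatureWarning, stacklevel=2)
        skew = kurt = 0.0
        ent = 0.0
    else:
        skew = float(stats.skew(values))
        kurt = float(stats.kurtosis(values))  # excess kurtosis
        hist, _ = np.histogram(values, bins=bins, range=(values.min(), values.max()))
        p = hist[hist > 0] / values.size
        ent = float(-(p * np.log(p)).sum())
    return {
        "meanint": mean,
        "stdint": sd,
        "mean15perc": mean15,
        "kurtosis": kurt,
        "skewness": skew,
        "entropy": ent,
    }


# ---------------------------------------------------------------------------
# Intensity cluster features (clustersize / clustindex)
# ---------------------------------------------------------------------------

def _kmeans_1d_two(values: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Two-group 1-D k-means with deterministic initialization at the
    25th/75th intensity percentiles; returns a boolean high-group flag."""
    c_lo, c_hi = np.percentile(values, [25, 75])
    if c_lo == c_hi:
        c_lo, c_hi = float(values.min()), float(values.max())
    for _ in range(max_iter):
        thresh = 0.5 * (c_lo + c_hi)
        high = values > thresh
        if high.all() or (~high).all():
            break
        new_lo, new_hi = values[~high].mean(), values[high].mean()
        if new_lo == c_lo and new_hi == c_hi:
            break
        c_lo, c_hi = new_lo, new_hi
    return values > 0.5 * (c_lo + c_hi)


def cluster_features(channel: np.ndarray, mask: np.ndarray,
                     min_voxels: int = 3) -> dict[str, float]:
    """Spatial-disorder features from a two-group intensity clustering.

    In-mask intensities are split by 1-D k-means (k=2); within each
    intensity group the 6-connected components are found and components
    smaller than ``min_voxels`` are discarded as noise.  ``clustersize``
    is the mean voxel count of the surviving components and ``clustindex``
    their total number across both groups.
    """
    mask = np.asarray(mask).astype(bool)
    values = np.asarray(channel, dtype=float)[mask]
    if values.size == 0:
        raise ValueError("empty mask")
    if np.unique(values).size < 2:
        warnings.warn("constant in-mask intensities: clustersize=n, clustindex=1",
                      DegenerateFeatureWarning, stacklevel=2)
        return {"clustersize": float(values.size), "clustindex": 1.0}
    high_flag = _kmeans_1d_two(values)
    high = np.zeros(mask.shape, dtype=bool)
    high[mask] = high_flag
    sizes_all: list[int] = []
    for group in (mask & high, mask & ~high):
        _, sizes = connected_components(group, connectivity=6)
        sizes_all.extend(int(s) for s in sizes if s >= min_voxels)
    if not sizes_all:
        return {"clustersize": 0.0, "clustindex": 0.0}
    return {"clustersize": float(np.mean(sizes_all)), "clustindex": float(len(sizes_all))}


# ---------------------------------------------------------------------------
# Gabor filter-bank feature
# ---------------------------------------------------------------------------

_KERNEL_CACHE: dict[tuple, list[np.ndarray]] = {}


def _gabor_bank(config: RadiomicsConfig) -> list[np.ndarray]:
    key = (config.gabor_frequencies, config.gabor_orientations)
    if key not in _KERNEL_CACHE:
        _KERNEL_CACHE[key] = [
            np.real(gabor_kernel(f, theta=t))
            for f in config.gabor_frequencies
            for t in config.gabor_orientations
        ]
    return _KERNEL_CACHE[key]


def gabor_feature(channel: np.ndarray, mask: np.ndarray,
                  config: RadiomicsConfig = DEFAULT_CONFIG) -> float:
    """Variance across a 16-filter Gabor bank of the mean normalized
    in-mask response.

    Each 2D kernel is convolved slice-wise; the response is divided
    voxel-wise by the stabilized image (|I| + eps with eps proportional to
    the in-mask intensity range, making the feature invariant to global
    intensity scaling); the per-filter summary is the in-mask mean divided
    by the bank size.
    """
    mask = np.asarray(mask).astype(bool)
    channel = np.asarray(channel, dtype=float)
    values = channel[mask]
    if values.size == 0:
        raise ValueError("empty mask")
    rng = float(values.max() - values.min())
    eps = config.gabor_eps_factor * rng if rng > 0 else config.gabor_eps_factor
    denom = np.abs(channel) + eps
    bank = _gabor_bank(config)
    # restrict to the mask bounding box (padded) to keep FFT sizes small
    slices = ndimage.find_objects(mask.astype(np.uint8))[0]
    pad = max(max(k.shape) for k in bank) // 2 + 1
    box = tuple(
        slice(max(0, s.start - pad), min(dim, s.stop + pad))
        for s, dim in zip(slices, channel.shape)
    )
    sub_img, sub_mask, sub_den = channel[box], mask[box], denom[box]
    summaries = np.empty(len(bank))
    for i, k in enumerate(bank):
        resp = signal.fftconvolve(sub_img, k[:, :, None], mode="same")
        summaries[i] = (resp[sub_mask] / sub_den[sub_mask]).mean() / len(bank)
    return float(np.var(summaries))


# ---------------------------------------------------------------------------
# Quantization and texture matrices
# ---------------------------------------------------------------------------

def quantize(channel: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Volume-wide min-max quantization of in-mask intensities to
    ``levels`` bins (0..levels-1); out-of-mask voxels get -1."""
    mask = np.asarray(mask).astype(bool)
    channel = np.asarray(channel, dtype=float)
    q = np.full(channel.shape, -1, dtype=np.int64)
    vals = channel[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    mn, mx = vals.min(), vals.max()
    if mx == mn:
        q[mask] = 0
    else:
        q[mask] = np.minimum(((channel[mask] - mn) / (mx - mn) * levels).astype(np.int64),
                             levels - 1)
    return q


def glcm_matrix_slice(q_slice: np.ndarray, levels: int,
                      directions, offsets) -> np.ndarray | None:
    """Symmetric co-occurrence counts on one quantized slice (-1 = out of
    mask), summed over the direction/offset set and normalized to sum 1.
    Returns None when the slice has no valid pair."""
    counts = np.zeros((levels, levels), dtype=np.float64)
    h, w = q_slice.shape
    for dr, dc in directions:
        for d in offsets:
            r, c = dr * d, dc * d
            a = q_slice[max(0, -r):h - max(0, r), max(0, -c):w - max(0, c)]
            b = q_slice[max(0, r):h + min(0, r) or h, max(0, c):w + min(0, c) or w]
            valid = (a >= 0) & (b >= 0)
            if valid.any():
                np.add.at(counts, (a[valid], b[valid]), 1.0)
                np.add.at(counts, (b[valid], a[valid]), 1.0)
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def glcm_props(P: np.ndarray) -> dict[str, float]:
    """Contrast, homogeneity, energy and correlation of a normalized GLCM."""
    L = P.shape[0]
    i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    contrast = float((P * (i - j) ** 2).sum())
    homogeneity = float((P / (1.0 + np.abs(i - j))).sum())
    energy = float((P ** 2).sum())
    pi = P.sum(axis=1)
    mu_i = float((np.arange(L) * pi).sum())
    sig_i = float(np.sqrt(((np.arange(L) - mu_i) ** 2 * pi).sum()))
    pj = P.sum(axis=0)
    mu_j = float((np.arange(L) * pj).sum())
    sig_j = float(np.sqrt(((np.arange(L) - mu_j) ** 2 * pj).sum()))
    if sig_i == 0.0 or sig_j == 0.0:
        corr = 1.0  # degenerate (single occupied level) convention
    else:
        corr = float((P * (i - mu_i) * (j - mu_j)).sum() / (sig_i * sig_j))
    return {"glcm_contrast": contrast, "glcm_homogeneity": homogeneity,
            "glcm_energy": energy, "glcm_correlation": corr}


def glcm_features(channel: np.ndarray, mask: np.ndarray,
                  config: RadiomicsConfig = DEFAULT_CONFIG) -> dict[str, float]:
    """Slice-wise GLCM features, averaged over tumor-bearing slices."""
    q = quantize(channel, mask, config.glcm_levels)
    per_slice: list[dict[str, float]] = []
    for z in range(q.shape[2]):
        qs = q[:, :, z]
        if (qs >= 0).sum() < 2:
            continue
        P = glcm_matrix_slice(qs, config.glcm_levels, config.directions, config.glcm_offsets)
        if P is not None:
            per_slice.append(glcm_props(P))
    if not per_slice:
        raise ValueError("no slice with >= 2 adjacent in-mask pixels")
    return {k: float(np.mean([d[k] for d in per_slice])) for k in per_slice[0]}


def _runs_concat(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized run-length encoding of a 1-D array where -1 entries
    (out-of-mask pixels and line separators) break runs; returns
    (levels, lengths) of the maximal in-mask runs."""
    if arr.size == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    change = np.empty(arr.size, dtype=bool)
    change[0] = True
    np.not_equal(arr[1:], arr[:-1], out=change[1:])
    starts = np.flatnonzero(change)
    lengths = np.diff(np.append(starts, arr.size))
    levels = arr[starts]
    keep = levels >= 0
    return levels[keep], lengths[keep]


def _slice_lines(q_slice: np.ndarray, direction: tuple[int, int]) -> list[np.ndarray]:
    """1-D scan lines of a slice along one of the four in-plane directions."""
    h, w = q_slice.shape
    dr, dc = direction
    if (dr, dc) == (0, 1):  # 0 deg: along rows
        return [q_slice[r] for r in range(h)]
    if (dr, dc) == (-1, 0):  # 90 deg: along columns
        return [q_slice[:, c] for c in range(w)]
    if (dr, dc) == (-1, 1):  # 45 deg: anti-diagonals
        flipped = q_slice[::-1]
        return [flipped.diagonal(o) for o in range(-(h - 1), w)]
    if (dr, dc) == (-1, -1):  # 135 deg: diagonals
        return [q_slice.diagonal(o) for o in range(-(h - 1), w)]
    raise ValueError(f"unsupported direction {direction}")


def glrlm_matrix_slice(q_slice: np.ndarray, levels: int, directions) -> np.ndarray | None:
    """Run-length counts P[i, j-1] = number of runs of length j at level i,
    averaged over directions and normalized to sum 1 (None if no runs)."""
    max_len = max(q_slice.shape)
    counts = np.zeros((levels, max_len), dtype=np.float64)
    sep = np.array([-1], dtype=np.int64)
    for direction in directions:
        lines = _slice_lines(q_slice, direction)
        flat = np.concatenate([np.concatenate((np.asarray(l, dtype=np.int64), sep))
                               for l in lines])
        levs, lens = _runs_concat(flat)
        if levs.size:
            np.add.at(counts, (levs, lens - 1), 1.0)
    counts /= len(directions)
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def glrlm_props(P: np.ndarray) -> dict[str, float]:
    """SRE, LRE, LGRE, HGRE with 1-based gray-level index."""
    levels, max_len = P.shape
    i = np.arange(1, levels + 1)[:, None].astype(float)
    j = np.arange(1, max_len + 1)[None, :].astype(float)
    return {
        "glrlm_SRE": float((P / j ** 2).sum()),
        "glrlm_LRE": float((P * j ** 2).sum()),
        "glrlm_LGRE": float((P / i ** 2).sum()),
        "glrlm_HGRE": float((P * i ** 2).sum()),
    }


def glrlm_features(channel: np.ndarray, mask: np.ndarray,
                   config: RadiomicsConfig = DEFAULT_CONFIG) -> dict[str, float]:
    """Slice-wise run-length features, averaged over tumor-bearing slices."""
    q = quantize(channel, mask, config.glrlm_levels)
    per_slice: list[dict[str, float]] = []
    for z in range(q.shape[2]):
        qs = q[:, :, z]
        if (qs >= 0).sum() < 2:
            continue
        P = glrlm_matrix_slice(qs, config.glrlm_levels, config.directions)
        if P is not None:
            per_slice.append(glrlm_props(P))
    if not per_slice:
        raise ValueError("no slice with >= 2 in-mask pixels")
    return {k: float(np.mean([d[k] for d in per_slice])) for k in per_slice[0]}


# ---------------------------------------------------------------------------
# Full vector
# ---------------------------------------------------------------------------

def extract_radiomics(case: StudyCase,
                      config: RadiomicsConfig = DEFAULT_CONFIG) -> dict[str, float]:
    """Compute the full 53-feature vector for one case, keyed by the
    canonical names in :data:`FEATURE_NAMES`."""
    mask = case.mask.voxels
    if case.mask.n_voxels == 0:
        raise ValueError(f"{case.case_id}: empty mask")
    out: dict[str, float] = {}
    for tag in CHANNELS:
        vol = case.channels[tag].voxels
        values = vol[mask]
        try:
            out.update({f"{tag}_{k}": v
                        for k, v in first_order_features(values, config.entropy_bins).items()})
            out[f"{tag}_gabor"] = gabor_feature(vol, mask, config)
            out.update({f"{tag}_{k}": v for k, v in glcm_features(vol, mask, config).items()})
            out.update({f"{tag}_{k}": v for k, v in glrlm_features(vol, mask, config).items()})
            out.update({f"{tag}_{k}": v
                        for k, v in cluster_features(vol, mask, config.min_cluster_voxels).items()})
        except ValueError as exc:
            raise ValueError(f"{case.case_id}/{tag}: {exc}") from exc
    shape = compute_shape(case.mask)
    out["vol"] = shape.volume_ml
    out["normsurfvolratio"] = shape.normsurfvolratio
    return {name: out[name] for name in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# Per-field-strength Z-transform
# ---------------------------------------------------------------------------

class ZTransform:
    """Per-field-strength, per-feature standardization.

    Location/scale are estimated on a training cohort, separately for the
    1.5T and 3T strata, and re-applied (with the stored training
    parameters) to held-out cohorts so that systematic scanner intensity
    offsets do not drive the clustering.
    """

    def __init__(self) -> None:
        self.params_: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.feature_names_: list[str] = []

    def fit(self, X, field_strengths) -> "ZTransform":
        import pandas as pd

        X = pd.DataFrame(X)
        fs = np.asarray(field_strengths)
        self.feature_names_ = list(X.columns)
        self.params_ = {}
        for stratum in np.unique(fs):
            sub = X.loc[fs == stratum]
            if len(sub) < 2:
                raise ValueError(f"need >= 2 training cases in stratum {stratum}")
            mean = sub.mean(axis=0).to_numpy(dtype=float)
            sd = sub.std(axis=0, ddof=1).to_numpy(dtype=float)
            if np.any(sd == 0):
                warnings.warn(f"zero-SD feature(s) in stratum {stratum}: z set to 0",
                              DegenerateFeatureWarning, stacklevel=2)
            self.params_[str(stratum)] = (mean, sd)
        return self

    def transform(self, X, field_strengths):
        import pandas as pd

        X = pd.DataFrame(X)
        if list(X.columns) != self.feature_names_:
            raise ValueError("feature columns do not match the fitted canonical order")
        fs = np.asarray(field_strengths)
        Z = np.empty(X.shape, dtype=float)
        for stratum, (mean, sd) in self.params_.items():
            rows = fs == stratum
            if not rows.any():
                continue
            safe_sd = np.where(sd > 0, sd, 1.0)
            z = (X.loc[rows].to_numpy(dtype=float) - mean) / safe_sd
            z[:, sd == 0] = 0.0
            Z[rows] = z
        unknown = set(np.unique(fs)) - set(self.params_)
        if unknown:
            raise ValueError(f"no training parameters for field strength(s) {unknown}")
        return pd.DataFrame(Z, index=X.index, columns=X.columns)

    def fit_transform(self, X, field_strengths):
        return self.fit(X, field_strengths).transform(X, field_strengths)

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names_,
            "params": {fs: {"mean": m.tolist(), "sd": s.tolist()}
                       for fs, (m, s) in self.params_.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZTransform":
        zt = cls()
        zt.feature_names_ = list(d["feature_names"])
        zt.params_ = {fs: (np.asarray(v["mean"], dtype=float), np.asarray(v["sd"], dtype=float))
                      for fs, v in d["params"].items()}
        return zt
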