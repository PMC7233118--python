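"""Radiomic feature extraction from a 2D image + ROI mask.

Per sequence, features are computed on the original image and on three
scale-normalized Laplacian-of-Gaussian (LoG) band-pass responses, giving
4 filter channels.  Each channel yields 24 first-order statistics (FOS),
26 gray-level co-occurrence (GLCM) features and 16 gray-level size-zone
(GLSZM) features — 66 per channel, 264 per sequence, 1056 per patient
over the four sequences.  Feature names follow
``"<seq>:<filter>-<class>_<stat>"``, e.g. ``"T2w:LoG3-GLCM_cshade"``.

Texture matrices are built from ROI-relative equal-width discretization
(32 gray levels by default).  GLCMs use distance-1 offsets in 4
directions, symmetrized and averaged; GLSZM zones are 8-connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .synthetic import MRISample, SEQUENCES

FILTERS: Tuple[str, ...] = ("orig", "LoG1", "LoG2", "LoG3")


@dataclass(frozen=True)
class ExtractionConfig:
    n_gray_levels: int = 32
    log_sigmas: Tuple[float, ...] = (1.0, 2.0, 3.0)  # pixels, map to LoG1/2/3
    glcm_offsets: Tuple[Tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
    glszm_connectivity: int = 8

    def __post_init__(self):
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")
        sig = self.log_sigmas
        if any(s <= 0 for s in sig) or list(sig) != sorted(set(sig)):
            raise ValueError("log_sigmas must be strictly positive and increasing")

    @property
    def n_features_per_sequence(self) -> int:
        return (1 + len(self.log_sigmas)) * (len(FOS_NAMES) + len(GLCM_NAMES) + len(GLSZM_NAMES))


@dataclass
class TextureMatrix:
    kind: str  # "GLCM" | "GLSZM"
    matrix: np.ndarray
    normalized: bool


# ---------------------------------------------------------------------------
# discretization and filtering


def discretize(masked_values: np.ndarray, n_gray_levels: int) -> np.ndarray:
    """Equal-width binning of ROI intensities into levels 1..n (top bin right-closed).

    Constant input maps everything to level 1.
    """
    v = np.asarray(masked_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty ROI")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.ones(v.shape, dtype=np.int64)
    frac = (v - lo) / (hi - lo)
    levels = np.ceil(frac * n_gray_levels).astype(np.int64)
    np.clip(levels, 1, n_gray_levels, out=levels)
    return levels


_LOG_DC: Dict[float, float] = {}


def log_filter(image: np.ndarray, sigma: float) -> np.ndarray:
    """Scale-normalized Laplacian-of-Gaussian response (reflect boundary).

    The truncated discrete LoG kernel has a small nonzero sum; it is
    DC-corrected (kernel minus its sum times a Gaussian) so a constant
    image maps to exactly zero response.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    img = np.asarray(image, dtype=float)
    dc = _LOG_DC.get(sigma)
    if dc is None:
        probe = np.ones((int(8 * sigma) + 9, int(8 * sigma) + 9))
        dc = float(ndimage.gaussian_laplace(probe, sigma, mode="reflect")[0, 0])
        _LOG_DC[sigma] = dc
    raw = ndimage.gaussian_laplace(img, sigma, mode="reflect")
    local_mean = ndimage.gaussian_filter(img, sigma, mode="reflect")
    return sigma**2 * (raw - dc * local_mean)


# ---------------------------------------------------------------------------
# first-order statistics

FOS_NAMES: Tuple[str, ...] = (
    "Mean", "Median", "Min", "Max", "Range",
    "P5", "P10", "P25", "P75", "P90", "P95", "IQR",
    "Variance", "SD", "Skewness", "Kurtosis",
    "Energy", "RMS", "MAD", "rMAD", "MedAD", "CV",
    "Entropy", "Uniformity",
)


def first_order_features(masked_values: np.ndarray, n_gray_levels: int = 32) -> Dict[str, float]:
    """Textbook first-order statistics of the ROI intensity distribution.

    Moments are population moments (ddof=0); skewness and excess kurtosis
    of a constant input are defined as 0; entropy (bits) and uniformity
    are computed on the equal-width discretized histogram.
    """
    v = np.asarray(masked_values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty ROI")
    p5, p10, p25, med, p75, p90, p95 = np.percentile(v, [5, 10, 25, 50, 75, 90, 95])
    mean = v.mean()
    dev = v - mean
    var = float(np.mean(dev**2))
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(np.mean(dev**3) / sd**3)
        kurt = float(np.mean(dev**4) / var**2 - 3.0)
    else:
        skew = kurt = 0.0
    levels = discretize(v, n_gray_levels)
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / v.size
    in_core = v[(v >= p10) & (v <= p90)]
    return {
        "Mean": float(mean),
        "Median": float(med),
        "Min": float(v.min()),
        "Max": float(v.max()),
        "Range": float(v.max() - v.min()),
        "P5": float(p5),
        "P10": float(p10),
        "P25": float(p25),
        "P75": float(p75),
        "P90": float(p90),
        "P95": float(p95),
        "IQR": float(p75 - p25),
        "Variance": float(var),
        "SD": float(sd),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float(np.sum(v**2)),
        "RMS": float(np.sqrt(np.mean(v**2))),
        "MAD": float(np.mean(np.abs(v - mean))),
        "rMAD": float(np.mean(np.abs(in_core - in_core.mean()))) if in_core.size else 0.0,
        "MedAD": float(np.median(np.abs(v - med))),
        "CV": float(sd / mean) if mean != 0 else 0.0,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# GLCM

GLCM_NAMES: Tuple[str, ...] = (
    "contrast", "dissimilarity", "homogeneity", "idm", "idn", "idmn",
    "inverse_variance", "asm", "energy", "entropy", "max_prob",
    "correlation", "autocorrelation", "joint_average", "sum_squares",
    "cluster_tendency", "cshade", "cluster_prominence",
    "sum_average", "sum_variance", "sum_entropy",
    "diff_average", "diff_variance", "diff_entropy", "imc1", "imc2",
)


def glcm_matrix(
    levels: np.ndarray,
    mask: np.ndarray,
    offsets: Sequence[Tuple[int, int]] = ((0, 1), (1, 0), (1, 1), (1, -1)),
    n_gray_levels: int | None = None,
) -> TextureMatrix:
    """Symmetric, offset-averaged, normalized gray-level co-occurrence matrix.

    ``levels`` holds integer gray levels (1-based) on the full grid;
    only pairs with both pixels inside ``mask`` are counted.  Each offset
    is symmetrized with its negation before averaging.
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    ng = int(n_gray_levels if n_gray_levels is not None else levels[mask].max())
    acc = np.zeros((ng, ng), dtype=float)
    total = 0
    h, w = levels.shape
    for dy, dx in offsets:
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        a_m = mask[y0:y1, x0:x1]
        b_m = mask[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
        valid = a_m & b_m
        if not valid.any():
            continue
        a = levels[y0:y1, x0:x1][valid] - 1
        b = levels[y0 + dy : y1 + dy, x0 + dx : x1 + dx][valid] - 1
        cnt = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng)
        acc += cnt + cnt.T  # symmetrize: offset and its negation
        total += 2 * a.size
    if total == 0:
        raise ValueError("degenerate ROI for GLCM")
    return TextureMatrix(kind="GLCM", matrix=acc / total, normalized=True)


_GLCM_GRIDS: Dict[int, tuple] = {}


def _glcm_grids(ng: int) -> tuple:
    """Cached index grids for a given gray-level count."""
    cached = _GLCM_GRIDS.get(ng)
    if cached is None:
        i = np.arange(1, ng + 1, dtype=float)[:, None]
        j = np.arange(1, ng + 1, dtype=float)[None, :]
        d = np.abs(i - j)
        ii, jj = np.indices((ng, ng))
        cached = (i, j, d, (ii + jj).ravel(), np.abs(ii - jj).ravel(), d > 0)
        _GLCM_GRIDS[ng] = cached
    return cached


def glcm_features(m: TextureMatrix) -> Dict[str, float]:
    """Standard co-occurrence features of a normalized symmetric GLCM."""
    p = np.asarray(m.matrix, dtype=float)
    ng = p.shape[0]
    i, j, d, sum_idx, diff_idx, inv_var_mask = _glcm_grids(ng)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    sig_i = np.sqrt(((i - mu_i) ** 2 * p).sum())
    sig_j = np.sqrt(((j - mu_j) ** 2 * p).sum())
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.bincount(sum_idx, weights=p.ravel(), minlength=2 * ng - 1)[: 2 * ng - 1]
    k_diff = np.arange(0, ng)
    p_diff = np.bincount(diff_idx, weights=p.ravel(), minlength=ng)

    def _ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    contrast = float(((i - j) ** 2 * p).sum())
    corr = float((((i - mu_i) * (j - mu_j) * p).sum()) / (sig_i * sig_j)) if sig_i > 0 and sig_j > 0 else 1.0
    hxy = _ent(p)
    hx, hy = _ent(px), _ent(py)
    pxy = px[:, None] * py[None, :]
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0
    sum_avg = float((k_sum * p_sum).sum())
    diff_avg = float((k_diff * p_diff).sum())
    return {
        "contrast": contrast,
        "dissimilarity": float((d * p).sum()),
        "homogeneity": float((p / (1.0 + d)).sum()),
        "idm": float((p / (1.0 + d**2)).sum()),
        "idn": float((p / (1.0 + d / ng)).sum()),
        "idmn": float((p / (1.0 + (d / ng) ** 2)).sum()),
        "inverse_variance": float((p[inv_var_mask] / d[inv_var_mask] ** 2).sum()),
        "asm": float((p**2).sum()),
        "energy": float(np.sqrt((p**2).sum())),
        "entropy": hxy,
        "max_prob": float(p.max()),
        "correlation": corr,
        "autocorrelation": float((i * j * p).sum()),
        "joint_average": mu_i,
        "sum_squares": float(((i - mu_i) ** 2 * p).sum()),
        "cluster_tendency": float(((i + j - mu_i - mu_j) ** 2 * p).sum()),
        "cshade": float(((i + j - mu_i - mu_j) ** 3 * p).sum()),
        "cluster_prominence": float(((i + j - mu_i - mu_j) ** 4 * p).sum()),
        "sum_average": sum_avg,
        "sum_variance": float(((k_sum - sum_avg) ** 2 * p_sum).sum()),
        "sum_entropy": _ent(p_sum),
        "diff_average": diff_avg,
        "diff_variance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "diff_entropy": _ent(p_diff),
        "imc1": float(imc1),
        "imc2": imc2,
    }


# ---------------------------------------------------------------------------
# GLSZM

GLSZM_NAMES: Tuple[str, ...] = (
    "SZE", "LZE", "GLN", "GLNN", "ZSN", "ZSNN", "ZP",
    "GLV", "ZV", "ZE", "LGZE", "HGZE",
    "SZLGE", "SZHGE", "LZLGE", "LZHGE",
)

_STRUCT8 = np.ones((3, 3), dtype=bool)


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, connectivity: int = 8) -> TextureMatrix:
    """Gray-level size-zone matrix: entry (i, s) counts 8-connected zones
    of level i with exactly s pixels, restricted to the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    if connectivity != 8:
        raise ValueError("only 8-connectivity supported")
    levels = np.asarray(levels)
    ng = int(levels[mask].max())
    # one union-find pass over all levels: edges join 8-neighbours of equal level
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    idx = -np.ones(mask.shape, dtype=np.int64)
    n_px = int(mask.sum())
    idx[mask] = np.arange(n_px)
    rows, cols = [], []
    h, w = mask.shape
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        a_sl = (slice(y0, y1), slice(x0, x1))
        b_sl = (slice(y0 + dy, y1 + dy), slice(x0 + dx, x1 + dx))
        ok = mask[a_sl] & mask[b_sl] & (levels[a_sl] == levels[b_sl])
        rows.append(idx[a_sl][ok])
        cols.append(idx[b_sl][ok])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    adj = coo_matrix((np.ones(r.size, dtype=np.int8), (r, c)), shape=(n_px, n_px))
    n_zones, comp = connected_components(adj, directed=False)
    sizes = np.bincount(comp)
    zone_level = np.zeros(n_zones, dtype=np.int64)
    zone_level[comp] = levels[mask]
    max_size = int(sizes.max())
    mat = np.zeros((ng, max_size), dtype=np.int64)
    np.add.at(mat, (zone_level - 1, sizes - 1), 1)
    return TextureMatrix(kind="GLSZM", matrix=mat, normalized=False)


def glszm_features(m: TextureMatrix) -> Dict[str, float]:
    """Standard size-zone features, normalized by the total zone count."""
    z = np.asarray(m.matrix, dtype=float)
    nz_total = z.sum()
    if nz_total == 0:
        raise ValueError("GLSZM has no zones")
    ng, ns = z.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    s = np.arange(1, ns + 1)[None, :].astype(float)
    p = z / nz_total
    n_pixels = float((z * s).sum())
    mu_i = float((i * p).sum())
    mu_s = float((s * p).sum())
    pz = p[p > 0]
    zi = p.sum(axis=1)  # by gray level
    zs = p.sum(axis=0)  # by size
    return {
        "SZE": float((p / s**2).sum()),
        "LZE": float((p * s**2).sum()),
        "GLN": float(nz_total * (zi**2).sum()),
        "GLNN": float((zi**2).sum()),
        "ZSN": float(nz_total * (zs**2).sum()),
        "ZSNN": float((zs**2).sum()),
        "ZP": float(nz_total / n_pixels),
        "GLV": float(((i - mu_i) ** 2 * p).sum()),
        "ZV": float(((s - mu_s) ** 2 * p).sum()),
        "ZE": float(-(pz * np.log2(pz)).sum()),
        "LGZE": float((p / i**2).sum()),
        "HGZE": float((p * i**2).sum()),
        "SZLGE": float((p / (i**2 * s**2)).sum()),
        "SZHGE": float((p * i**2 / s**2).sum()),
        "LZLGE": float((p * s**2 / i**2).sum()),
        "LZHGE": float((p * i**2 * s**2).sum()),
    }


# ---------------------------------------------------------------------------
# per-sample extraction


def feature_names(config: ExtractionConfig = ExtractionConfig()) -> List[str]:
    """Deterministic ordered names of the full per-patient feature vector."""
    names = []
    for seq in SEQUENCES:
        for filt in ("orig",) + tuple(f"LoG{k+1}" for k in range(len(config.log_sigmas))):
            names.extend(f"{seq}:{filt}-FOS_{n}" for n in FOS_NAMES)
            names.extend(f"{seq}:{filt}-GLCM_{n}" for n in GLCM_NAMES)
            names.extend(f"{seq}:{filt}-GLSZM_{n}" for n in GLSZM_NAMES)
    return names


def _channel_features(img: np.ndarray, mask: np.ndarray, cfg: ExtractionConfig) -> List[float]:
    vals = img[mask]
    fos = first_order_features(vals, cfg.n_gray_levels)
    lv = np.zeros(img.shape, dtype=np.int64)
    lv[mask] = discretize(vals, cfg.n_gray_levels)
    gl = glcm_features(glcm_matrix(lv, mask, cfg.glcm_offsets, cfg.n_gray_levels))
    # restrict GLSZM to a bounding box for speed
    ys, xs = np.nonzero(mask)
    sl = (slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1))
    sz = glszm_features(glszm_matrix(lv[sl], mask[sl], cfg.glszm_connectivity))
    out = [fos[n] for n in FOS_NAMES]
    out += [gl[n] for n in GLCM_NAMES]
    out += [sz[n] for n in GLSZM_NAMES]
    return out


def extract_features(sample: MRISample, config: ExtractionConfig = ExtractionConfig()) -> Dict[str, float]:
    """Full radiomic vector for one patient (default 264 per sequence, 1056 total).

    LoG filters are applied to the whole image before masking and
    discretization, so boundary responses use true neighbourhoods.
    """
    for seq in SEQUENCES:
        if seq not in sample.images:
            raise ValueError(f"missing sequence {seq}")
    values: List[float] = []
    for seq in SEQUENCES:
        img = np.asarray(sample.images[seq], dtype=float)
        mask = np.asarray(sample.masks[seq], dtype=bool)
        if img.shape != mask.shape or not mask.any():
            raise ValueError(f"invalid mask for sequence {seq}")
        channels = [img] + [log_filter(img, s) for s in config.log_sigmas]
        for ch in channels:
            values.extend(_channel_features(ch, mask, config))
    return dict(zip(feature_names(config), values))


def extract_table(samples: Iterable[MRISample], config: ExtractionConfig = ExtractionConfig()):
    """Feature table: rows = patients, columns = feature names, indexed by patient_id."""
    import pandas as pd

    rows = {s.patient_id: extract_features(s, config) for s in samples}
    return pd.DataFrame.from_dict(rows, orient="index", columns=feature_names(config))


# ---------------------------------------------------------------------------
# inter-rater agreement


def feature_agreement_icc(table_rater1, table_rater2) -> "pd.Series":
    """Two-way random-effects, absolute-agreement, single-measure ICC(2,1) per feature.

    Computed from the two-way ANOVA mean squares across patients (rows)
    and raters (columns); a feature with zero variance across patients
    and raters is undefined and reported as NaN.
    """
    import pandas as pd

    if list(table_rater1.index) != list(table_rater2.index) or list(
        table_rater1.columns
    ) != list(table_rater2.columns):
        raise ValueError("tables must share patients and feature names")
    x1 = table_rater1.to_numpy(dtype=float)
    x2 = table_rater2.to_numpy(dtype=float)
    n = x1.shape[0]
    k = 2
    grand = (x1 + x2) / 2
    mean_subj = grand  # per-subject mean over raters
    mean_rater1 = x1.mean(axis=0)
    mean_rater2 = x2.mean(axis=0)
    mean_all = (mean_rater1 + mean_rater2) / 2
    ss_subj = k * ((mean_subj - mean_all) ** 2).sum(axis=0)
    ss_rater = n * ((mean_rater1 - mean_all) ** 2 + (mean_rater2 - mean_all) ** 2)
    ss_tot = ((x1 - mean_all) ** 2 + (x2 - mean_all) ** 2).sum(axis=0)
    ss_err = ss_tot - ss_subj - ss_rater
    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    icc = np.where(ss_tot > 0, icc, np.nan)
    return pd.Series(icc, index=table_rater1.columns, name="ICC")
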