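"""Whole-frame 2D radiomics: intensity, texture and wavelet feature banks.

Per frame the bank yields exactly 350 named values:

* 16 first-order intensity statistics of the gray-value distribution;
* 54 texture statistics of the 32-level quantized image — 22 gray-level
  co-occurrence (GLCM, distance 1, four directions averaged, symmetric),
  16 gray-level run-length (GLRLM, direction-averaged) and 16 gray-level
  size-zone (GLSZM, 8-connectivity) features;
* 280 wavelet features — a two-level Haar decomposition retaining both
  approximation images gives 8 subbands {LL1, LH1, HL1, HH1, LL2, LH2,
  HL2, HH2}, and on each subband the 16 intensity features plus the first
  19 co-occurrence features of the canonical order are computed (35 per
  subband).

A case vector concatenates the 350-value bank over the five key frames,
frame-major, for 1,750 named values.  Features are computed on the whole
frame (no lesion mask) and are bit-deterministic.

Degenerate inputs are defined, not errors: on a constant image the
variance, entropy and all difference/shade statistics are 0, the
homogeneity-type statistics (joint energy, IDM, ID, IDMN, IDN, maximum
probability, uniformity) are 1, and correlation and the information
measures of correlation are set to 0 (their normalizers vanish).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from skimage.feature import graycomatrix

INTENSITY_FEATURE_NAMES = (
    "mean", "median", "minimum", "maximum", "range", "variance", "std",
    "skewness", "kurtosis", "energy", "rms", "entropy", "uniformity",
    "mad", "p10", "p90",
)

GLCM_FEATURE_NAMES = (
    "autocorrelation", "joint_average", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "joint_energy",
    "joint_entropy", "imc1", "imc2", "idm", "id", "idmn", "idn",
    "inverse_variance", "maximum_probability", "sum_entropy",
    "sum_of_squares",
)
#: co-occurrence subset used in the wavelet domain: first 19 of the canon
GLCM_WAVELET_SUBSET = GLCM_FEATURE_NAMES[:19]

GLRLM_FEATURE_NAMES = (
    "sre", "lre", "gln", "glnn", "rln", "rlnn", "rp", "glv", "rv", "re",
    "lglre", "hglre", "srlgle", "srhgle", "lrlgle", "lrhgle",
)

GLSZM_FEATURE_NAMES = (
    "sae", "lae", "gln", "glnn", "szn", "sznn", "zp", "glv", "zv", "ze",
    "lglze", "hglze", "salgle", "sahgle", "lalgle", "lahgle",
)

WAVELET_SUBBANDS = ("LL1", "LH1", "HL1", "HH1", "LL2", "LH2", "HL2", "HH2")

N_INTENSITY = 16
N_TEXTURE = 54
N_WAVELET = 280
N_PER_FRAME = 350
N_KEY_FRAMES = 5
N_PER_CASE = 1750

_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def quantize_gray(frame: np.ndarray, n_levels: int = 32) -> np.ndarray:
    """Equal-width quantization of a frame into integer levels 1..n_levels.

    Bin edges span the frame's own min..max; a constant frame maps to all
    ones.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    x = np.asarray(frame, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.ones(x.shape, dtype=np.int64)
    q = np.floor((x - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
    return np.clip(q, 1, n_levels)


# --------------------------------------------------------------------------
# first-order intensity statistics
# --------------------------------------------------------------------------

def _histogram_probs(x: np.ndarray, bins: int = 256) -> np.ndarray:
    counts, _ = np.histogram(x, bins=bins)
    return counts[counts > 0] / x.size


def intensity_features(frame: np.ndarray) -> dict[str, float]:
    """The 16 first-order statistics, in canonical order."""
    x = np.asarray(frame, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty frame")
    mean = float(x.mean())
    var = float(x.var())
    std = float(np.sqrt(var))
    if var > 0:
        z = (x - mean) / std
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))  # Pearson (non-excess) kurtosis
    else:
        skew = kurt = 0.0
    p = _histogram_probs(x)
    entropy = float(-(p * np.log2(p)).sum() + 0.0)
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "variance": var,
        "std": std,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float(np.sum(x**2)),
        "rms": float(np.sqrt(np.mean(x**2))),
        "entropy": entropy,
        "uniformity": float(np.sum(p**2)),
        "mad": float(np.mean(np.abs(x - mean))),
        "p10": float(np.percentile(x, 10)),
        "p90": float(np.percentile(x, 90)),
    }


# --------------------------------------------------------------------------
# gray-level co-occurrence features
# --------------------------------------------------------------------------

def glcm_matrix(
    quantized: np.ndarray,
    n_levels: int = 32,
    angles: tuple[float, ...] = _GLCM_ANGLES,
    distance: int = 1,
) -> np.ndarray:
    """Direction-averaged, symmetric, normalized co-occurrence matrix."""
    counts = graycomatrix(
        (quantized - 1).astype(np.uint8),
        distances=[distance],
        angles=list(angles),
        levels=n_levels,
        symmetric=True,
        normed=False,
    )[:, :, 0, :].astype(float)
    sums = counts.sum(axis=(0, 1))
    sums[sums == 0] = 1.0
    return (counts / sums).mean(axis=2)


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 22 co-occurrence statistics of a normalized symmetric matrix."""
    ng = P.shape[0]
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, ng + 1)[None, :].astype(float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i[:, 0] * px).sum())
    mu_y = float((j[0, :] * py).sum())
    sig_x = float(np.sqrt(((i[:, 0] - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((j[0, :] - mu_y) ** 2 * py).sum()))

    k_diff = np.arange(0, ng)
    p_diff = np.array([P[np.abs(i - j) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([P[(i + j) == k].sum() for k in k_sum])

    def ent(v: np.ndarray) -> float:
        v = v[v > 0]
        return float(-(v * np.log2(v)).sum() + 0.0)

    da = float((k_diff * p_diff).sum())
    hxy = ent(P)
    hx, hy = ent(px), ent(py)
    outer = px[:, None] * py[None, :]
    with np.errstate(divide="ignore"):
        log_outer = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
    hxy1 = float(-(P * log_outer).sum())
    hxy2 = ent(outer.ravel())

    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sig_x > 0 and sig_y > 0:
        corr = float((((i - mu_x) * (j - mu_y) * P).sum()) / (sig_x * sig_y))
    else:
        corr = 0.0

    off = np.abs(i - j) > 0
    inv_var = float((P[off] / (i - j)[off] ** 2).sum())

    return {
        "autocorrelation": float((i * j * P).sum()),
        "joint_average": mu_x,
        "cluster_prominence": float(((i + j - mu_x - mu_y) ** 4 * P).sum()),
        "cluster_shade": float(((i + j - mu_x - mu_y) ** 3 * P).sum()),
        "cluster_tendency": float(((i + j - mu_x - mu_y) ** 2 * P).sum()),
        "contrast": float(((i - j) ** 2 * P).sum()),
        "correlation": corr,
        "difference_average": da,
        "difference_entropy": ent(p_diff),
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "joint_energy": float((P**2).sum()),
        "joint_entropy": hxy,
        "imc1": float(imc1),
        "imc2": imc2,
        "idm": float((P / (1.0 + (i - j) ** 2)).sum()),
        "id": float((P / (1.0 + np.abs(i - j))).sum()),
        "idmn": float((P / (1.0 + ((i - j) / ng) ** 2)).sum()),
        "idn": float((P / (1.0 + np.abs(i - j) / ng)).sum()),
        "inverse_variance": inv_var,
        "maximum_probability": float(P.max()),
        "sum_entropy": ent(p_sum),
        "sum_of_squares": float(((i - mu_x) ** 2 * P).sum()),
    }


# --------------------------------------------------------------------------
# gray-level run-length features
# --------------------------------------------------------------------------

def _rle_lines(lines, n_levels: int, max_len: int) -> np.ndarray:
    R = np.zeros((n_levels, max_len), dtype=float)
    for line in lines:
        if line.size == 0:
            continue
        change = np.flatnonzero(np.diff(line)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [line.size]))
        for s, e in zip(starts, ends):
            R[line[s] - 1, e - s - 1] += 1
    return R


def glrlm_matrices(quantized: np.ndarray, n_levels: int = 32) -> list[np.ndarray]:
    """Run-length matrices for the four directions 0/45/90/135 degrees."""
    q = np.asarray(quantized)
    h, w = q.shape
    max_len = max(h, w)
    flipped = np.fliplr(q)
    dirs = [
        [q[r, :] for r in range(h)],                                   # 0
        [np.diagonal(flipped, o) for o in range(-(h - 1), w)],          # 45
        [q[:, c] for c in range(w)],                                   # 90
        [np.diagonal(q, o) for o in range(-(h - 1), w)],                # 135
    ]
    return [_rle_lines(lines, n_levels, max_len) for lines in dirs]


def _rl_stats(R: np.ndarray, n_pixels: int, names) -> dict[str, float]:
    Nr = R.sum()
    if Nr == 0:  # cannot occur for a nonempty image
        return {n: 0.0 for n in names}
    ng, nr = R.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    r = np.arange(1, nr + 1)[None, :].astype(float)
    p = R / Nr
    mu_i = float((p * i).sum())
    mu_r = float((p * r).sum())
    pz = p[p > 0]
    vals = (
        float((R / r**2).sum() / Nr),
        float((R * r**2).sum() / Nr),
        float((R.sum(axis=1) ** 2).sum() / Nr),
        float((R.sum(axis=1) ** 2).sum() / Nr**2),
        float((R.sum(axis=0) ** 2).sum() / Nr),
        float((R.sum(axis=0) ** 2).sum() / Nr**2),
        float(Nr / n_pixels),
        float((p * (i - mu_i) ** 2).sum()),
        float((p * (r - mu_r) ** 2).sum()),
        float(-(pz * np.log2(pz)).sum()),
        float((R / i**2).sum() / Nr),
        float((R * i**2).sum() / Nr),
        float((R / (i**2 * r**2)).sum() / Nr),
        float((R * i**2 / r**2).sum() / Nr),
        float((R * r**2 / i**2).sum() / Nr),
        float((R * i**2 * r**2).sum() / Nr),
    )
    return dict(zip(names, vals))


def glrlm_features(quantized: np.ndarray, n_levels: int = 32) -> dict[str, float]:
    """16 run-length statistics, averaged over the four directions."""
    mats = glrlm_matrices(quantized, n_levels)
    n_pixels = quantized.size
    per_dir = [_rl_stats(R, n_pixels, GLRLM_FEATURE_NAMES) for R in mats]
    return {
        n: float(np.mean([d[n] for d in per_dir])) for n in GLRLM_FEATURE_NAMES
    }


# --------------------------------------------------------------------------
# gray-level size-zone features
# --------------------------------------------------------------------------

def glszm_matrix(quantized: np.ndarray, n_levels: int = 32) -> np.ndarray:
    """Size-zone matrix: 8-connected zones of equal gray level."""
    q = np.asarray(quantized)
    max_size = q.size
    structure = np.ones((3, 3), bool)
    counts: dict[tuple[int, int], float] = {}
    for level in range(1, n_levels + 1):
        mask = q == level
        if not mask.any():
            continue
        labels, n_zones = ndimage.label(mask, structure=structure)
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            counts[(level, int(s))] = counts.get((level, int(s)), 0.0) + 1.0
    max_s = max((s for (_, s) in counts), default=1)
    S = np.zeros((n_levels, max_s), dtype=float)
    for (level, s), c in counts.items():
        S[level - 1, s - 1] = c
    return S


def glszm_features(quantized: np.ndarray, n_levels: int = 32) -> dict[str, float]:
    """16 size-zone statistics (same functional forms as GLRLM, over zone size)."""
    S = glszm_matrix(quantized, n_levels)
    return _rl_stats(S, quantized.size, GLSZM_FEATURE_NAMES)


# --------------------------------------------------------------------------
# texture bank and wavelet bank
# --------------------------------------------------------------------------

def texture_features(frame: np.ndarray, n_levels: int = 32) -> dict[str, float]:
    """The 54 texture statistics (22 GLCM + 16 GLRLM + 16 GLSZM)."""
    q = quantize_gray(frame, n_levels)
    out: dict[str, float] = {}
    for k, v in glcm_features(glcm_matrix(q, n_levels)).items():
        out[f"glcm_{k}"] = v
    for k, v in glrlm_features(q, n_levels).items():
        out[f"glrlm_{k}"] = v
    for k, v in glszm_features(q, n_levels).items():
        out[f"glszm_{k}"] = v
    return out


def wavelet_subbands(frame: np.ndarray, wavelet: str = "haar") -> dict[str, np.ndarray]:
    """Two-level 2D DWT keeping both approximation images: 8 subbands."""
    x = np.asarray(frame, dtype=float)
    if min(x.shape) < 16:
        raise ValueError(
            f"frame {x.shape} too small for a two-level wavelet decomposition "
            "(need at least 16x16)"
        )
    ll1, (lh1, hl1, hh1) = pywt.dwt2(x, wavelet, mode="symmetric")
    ll2, (lh2, hl2, hh2) = pywt.dwt2(ll1, wavelet, mode="symmetric")
    return {
        "LL1": ll1, "LH1": lh1, "HL1": hl1, "HH1": hh1,
        "LL2": ll2, "LH2": lh2, "HL2": hl2, "HH2": hh2,
    }


def wavelet_features(
    frame: np.ndarray, wavelet: str = "haar", n_levels: int = 32
) -> dict[str, float]:
    """280 wavelet-domain features: 35 per subband over 8 subbands.

    Per subband: the 16 intensity features plus the 19-feature
    co-occurrence subset (the first 19 of the canonical 22-feature order).
    """
    out: dict[str, float] = {}
    for band, img in wavelet_subbands(frame, wavelet).items():
        for k, v in intensity_features(img).items():
            out[f"wav_{band}_intensity_{k}"] = v
        q = quantize_gray(img, n_levels)
        g = glcm_features(glcm_matrix(q, n_levels))
        for k in GLCM_WAVELET_SUBSET:
            out[f"wav_{band}_glcm_{k}"] = g[k]
    return out


def frame_features(frame: np.ndarray, n_levels: int = 32) -> dict[str, float]:
    """Full 350-feature bank of a single frame."""
    out = {f"intensity_{k}": v for k, v in intensity_features(frame).items()}
    out.update(texture_features(frame, n_levels))
    out.update(wavelet_features(frame, n_levels=n_levels))
    assert len(out) == N_PER_FRAME
    return out


def case_radiomics_vector(stack, key_frames, n_levels: int = 32) -> pd.Series:
    """1,750 named radiomics values: 350 per key frame, frame-major."""
    if len(key_frames) != N_KEY_FRAMES:
        raise ValueError(f"expected {N_KEY_FRAMES} key frames, got {len(key_frames)}")
    values: dict[str, float] = {}
    for slot, idx in enumerate(key_frames):
        if not (0 <= idx < stack.n_frames):
            raise IndexError(
                f"key frame {idx} out of range for a stack of {stack.n_frames} frames"
            )
        for k, v in frame_features(stack[idx], n_levels).items():
            values[f"f{slot}_{k}"] = v
    s = pd.Series(values, dtype=float)
    assert len(s) == N_PER_CASE
    return s
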