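"""Engineered texture-feature comparator arm.

Per ROI, a deterministic bank of ~290 named features in the WND-CHARM
spirit — pixel statistics, Haralick co-occurrence statistics, local binary
patterns, Gabor filter-bank energies, Chebyshev and Zernike decompositions,
edge statistics and Fourier-domain statistics — followed by mRMR selection
of the 20 most relevant/least redundant features and a 1000-tree random
forest emitting image-level failing probabilities.

The bank deliberately trades the full 4059-feature set for a documented,
unit-testable subset; each family is computed on the grayscale image, the
cheap families also on each RGB channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.signal import fftconvolve
from skimage.feature import graycomatrix, local_binary_pattern
from skimage.filters import gabor_kernel, sobel
from skimage.transform import resize
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import mutual_info_score
from sklearn.preprocessing import StandardScaler

from .errors import InvalidArgumentError, InvalidDataError
from .slide_prep import RegionOfInterest
from .synthetic_data import is_failing_label

__all__ = [
    "FeatureVector",
    "SelectedFeatureSet",
    "extract_features",
    "extract_feature_table",
    "mrmr_select",
    "train_rf",
    "rf_predict",
    "FeatureScaler",
]

GABOR_FREQUENCIES = (0.06, 0.125, 0.25, 0.4)  # cycles/px; 0.125 ~ myocyte banding at 2 um/px
GABOR_ORIENTATIONS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)


@dataclass
class FeatureVector:
    values: np.ndarray
    feature_names: list[str]
    roi_id: str = ""
    patient_id: str = ""


@dataclass
class SelectedFeatureSet:
    indices: list[int]
    scores: list[float]
    k: int


# ---------------------------------------------------------------------------
# feature families


def _moments(v: np.ndarray, prefix: str) -> list[tuple[str, float]]:
    v = v.ravel()
    sd = float(v.std())
    if sd > 0:
        skew, kurt = float(sstats.skew(v)), float(sstats.kurtosis(v))
    else:
        skew = kurt = 0.0  # degenerate (constant) input: no shape information
    q = np.percentile(v, [5, 25, 50, 75, 95])
    out = [("mean", float(v.mean())), ("sd", sd), ("skew", skew), ("kurtosis", kurt)]
    out += [(f"q{p:02d}", float(x)) for p, x in zip((5, 25, 50, 75, 95), q)]
    return [(f"{prefix}_{n}", x) for n, x in out]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _haralick(chan: np.ndarray, prefix: str, levels: int = 32) -> list[tuple[str, float]]:
    lv = np.minimum((chan / (256 / levels)).astype(np.uint8), levels - 1)
    glcm = graycomatrix(
        lv, distances=[1], angles=list(GABOR_ORIENTATIONS), levels=levels, symmetric=True, normed=True
    )
    idx = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    acc = np.zeros(13)
    for a in range(glcm.shape[3]):
        p = glcm[:, :, 0, a]
        px = p.sum(axis=1)
        mu_x = (idx * px).sum()
        var_x = ((idx - mu_x) ** 2 * px).sum()
        sd_x = np.sqrt(var_x)
        # symmetric GLCM: x and y marginals coincide
        asm = (p * p).sum()
        contrast = (((ii - jj) ** 2) * p).sum()
        corr = (((ii - mu_x) * (jj - mu_x) * p).sum() / var_x) if var_x > 0 else 0.0
        idm = (p / (1.0 + (ii - jj) ** 2)).sum()
        ks = np.arange(2 * levels - 1)
        p_sum = np.array([p[ii + jj == k].sum() for k in ks])
        sum_avg = (ks * p_sum).sum()
        sum_var = (((ks - sum_avg) ** 2) * p_sum).sum()
        kd = np.arange(levels)
        p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in kd])
        diff_avg = (kd * p_diff).sum()
        diff_var = (((kd - diff_avg) ** 2) * p_diff).sum()
        hxy = _entropy(p)
        hx = _entropy(px)
        outer = np.outer(px, px)
        nz = (p > 0) & (outer > 0)
        hxy1 = float(-(p[nz] * np.log(outer[nz])).sum())
        pos = outer > 0
        hxy2 = float(-(outer[pos] * np.log(outer[pos])).sum())
        imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
        imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))
        acc += np.array(
            [asm, contrast, corr, var_x, idm, sum_avg, sum_var, _entropy(p_sum), hxy, diff_var,
             _entropy(p_diff), imc1, imc2]
        )
    acc /= glcm.shape[3]
    return [(f"{prefix}_haralick_{n}", float(v)) for n, v in zip(HARALICK_NAMES, acc)]


def _lbp(chan: np.ndarray, prefix: str, radius: int) -> list[tuple[str, float]]:
    codes = local_binary_pattern(chan.astype(np.uint8), P=8, R=radius, method="uniform")
    codes = codes[radius:-radius, radius:-radius]  # border neighborhoods are undefined
    hist = np.bincount(codes.astype(np.int64).ravel(), minlength=10).astype(np.float64)
    hist /= hist.sum()
    return [(f"{prefix}_lbp_r{radius}_b{i}", float(h)) for i, h in enumerate(hist)]


def _edge_stats(chan: np.ndarray, prefix: str) -> list[tuple[str, float]]:
    mag = sobel(chan / 255.0)
    m = float(mag.mean())
    density = float((mag > 2.0 * m).mean()) if m > 0 else 0.0
    return [
        (f"{prefix}_edge_mean", m),
        (f"{prefix}_edge_sd", float(mag.std())),
        (f"{prefix}_edge_density", density),
    ]


def _spectral(chan: np.ndarray, prefix: str) -> list[tuple[str, float]]:
    mag = np.log1p(np.abs(np.fft.rfft2(chan / 255.0)))
    return _moments(mag, f"{prefix}_spectral")


def _gabor(gray: np.ndarray) -> list[tuple[str, float]]:
    out = []
    g = gray / 255.0
    for f in GABOR_FREQUENCIES:
        for theta in GABOR_ORIENTATIONS:
            kern = gabor_kernel(frequency=f, theta=theta)
            resp = fftconvolve(g, np.real(kern), mode="same") ** 2
            resp += fftconvolve(g, np.imag(kern), mode="same") ** 2
            out.append((f"gray_gabor_f{f:g}_t{int(np.degrees(theta))}", float(resp.mean())))
    return out


@lru_cache(maxsize=4)
def _zernike_basis(size: int, max_order: int) -> tuple:
    ax = (np.arange(size) + 0.5) / size * 2.0 - 1.0
    xx, yy = np.meshgrid(ax, ax)
    rho = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)
    disk = rho <= 1.0
    basis, names = [], []
    for n in range(max_order + 1):
        for m in range(n % 2, n + 1, 2):
            r = np.zeros_like(rho)
            for s in range((n - m) // 2 + 1):
                coef = (
                    (-1) ** s
                    * factorial(n - s)
                    / (factorial(s) * factorial((n + m) // 2 - s) * factorial((n - m) // 2 - s))
                )
                r += coef * rho ** (n - 2 * s)
            z = r * np.exp(-1j * m * theta) * disk
            basis.append(z * (n + 1) / np.pi)
            names.append(f"zernike_n{n}_m{m}")
    return tuple(basis), tuple(names), disk


def _zernike(gray: np.ndarray, max_order: int = 8, size: int = 64) -> list[tuple[str, float]]:
    small = resize(gray / 255.0, (size, size), order=1, anti_aliasing=True, preserve_range=True)
    basis, names, disk = _zernike_basis(size, max_order)
    norm = disk.sum()
    return [(f"gray_{n}", float(np.abs((small * b).sum()) / norm)) for b, n in zip(basis, names)]


def _chebyshev(gray: np.ndarray, degree: int = 20, size: int = 32) -> list[tuple[str, float]]:
    small = resize(gray / 255.0, (size, size), order=1, anti_aliasing=True, preserve_range=True)
    xs = np.linspace(-1.0, 1.0, size)
    v = np.polynomial.chebyshev.chebvander(xs, degree)  # (size, degree+1)
    g, *_ = np.linalg.lstsq(v, small, rcond=None)  # fit columns
    coeffs, *_ = np.linalg.lstsq(v, g.T, rcond=None)
    coeffs = coeffs.T  # (degree+1, degree+1)
    mag = np.abs(coeffs)
    feats = []
    for order in range(degree + 1):
        ii, jj = np.meshgrid(np.arange(degree + 1), np.arange(degree + 1), indexing="ij")
        feats.append((f"gray_cheb_order{order:02d}", float(mag[(ii + jj) == order].sum())))
    feats += _moments(mag, "gray_cheb_coeff")
    return feats


# ---------------------------------------------------------------------------


def extract_features(roi: RegionOfInterest | np.ndarray) -> FeatureVector:
    """Compute the deterministic feature bank for one RGB ROI.

    All values are finite; degenerate (constant) images yield zero for
    spread/shape features and a single occupied histogram bin.
    """
    if isinstance(roi, RegionOfInterest):
        pixels, roi_id, patient_id = roi.pixels, roi.roi_id, roi.patient_id
    else:
        pixels, roi_id, patient_id = np.asarray(roi), "", ""
    if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.size == 0:
        raise InvalidArgumentError("extract_features requires a non-empty RGB raster")
    p = pixels.astype(np.float64)
    gray = 0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2]
    channels = [("gray", gray), ("r", p[..., 0]), ("g", p[..., 1]), ("b", p[..., 2])]

    feats: list[tuple[str, float]] = []
    for name, chan in channels:
        feats += _moments(chan, name)
        feats += _haralick(chan, name)
        feats += _lbp(chan, name, radius=1)
        feats += _lbp(chan, name, radius=2)
        feats += _edge_stats(chan, name)
        feats += _spectral(chan, name)
    feats += _gabor(gray)
    feats += _zernike(gray)
    feats += _chebyshev(gray)

    names = [n for n, _ in feats]
    values = np.array([v for _, v in feats], dtype=np.float64)
    values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
    return FeatureVector(values=values, feature_names=names, roi_id=roi_id, patient_id=patient_id)


def extract_feature_table(rois) -> pd.DataFrame:
    """Feature matrix for a sequence of ROIs, indexed by roi_id, with a
    patient_id column first."""
    rows, ids, pids = [], [], []
    names = None
    for roi in rois:
        fv = extract_features(roi)
        if names is None:
            names = fv.feature_names
        rows.append(fv.values)
        ids.append(fv.roi_id)
        pids.append(fv.patient_id)
    df = pd.DataFrame(np.vstack(rows), columns=names, index=pd.Index(ids, name="roi_id"))
    df.insert(0, "patient_id", pids)
    return df


# ---------------------------------------------------------------------------
# mRMR selection


def _discretize_terciles(x: np.ndarray) -> np.ndarray:
    """Code each feature into 3 levels split at mean +/- sd/2."""
    mu, sd = x.mean(), x.std()
    return np.digitize(x, [mu - 0.5 * sd, mu + 0.5 * sd])


def mrmr_select(features: np.ndarray, labels, k: int = 20, method: str = "mid") -> SelectedFeatureSet:
    """Greedy forward mRMR (MID criterion): at each step pick the feature
    maximizing I(f; y) - mean_{s in S} I(f; s) on tercile-discretized values;
    the first pick is the max-relevance feature; ties break to the lowest
    feature index.

    ``method`` may also be "wilcoxon" (rank-sum p-value ascending) or
    "fisher" (Fisher score descending); these alternatives are provided for
    comparison and are not the default.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise InvalidArgumentError("features must be a 2-D matrix")
    n, p = X.shape
    if k > p:
        raise InvalidArgumentError(f"k={k} exceeds {p} features")
    if np.unique(y).size < 2:
        raise InvalidDataError("labels are constant; selection is undefined")

    if method == "wilcoxon":
        classes = np.unique(y)
        pvals = np.array(
            [sstats.ranksums(X[y == classes[0], j], X[y == classes[1], j]).pvalue for j in range(p)]
        )
        order = np.argsort(pvals, kind="stable")[:k]
        return SelectedFeatureSet(list(map(int, order)), [float(pvals[j]) for j in order], k)
    if method == "fisher":
        classes = np.unique(y)
        num = np.zeros(p)
        den = np.zeros(p)
        for c in classes:
            Xc = X[y == c]
            num += Xc.shape[0] * (Xc.mean(axis=0) - X.mean(axis=0)) ** 2
            den += Xc.shape[0] * Xc.var(axis=0)
        score = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        order = np.argsort(-score, kind="stable")[:k]
        return SelectedFeatureSet(list(map(int, order)), [float(score[j]) for j in order], k)
    if method != "mid":
        raise InvalidArgumentError("method must be one of 'mid', 'wilcoxon', 'fisher'")

    codes = np.column_stack([_discretize_terciles(X[:, j]) for j in range(p)])
    relevance = np.array([mutual_info_score(codes[:, j], y) for j in range(p)])
    selected: list[int] = []
    scores: list[float] = []
    redundancy_cache: dict[tuple[int, int], float] = {}

    def mi_ff(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in redundancy_cache:
            redundancy_cache[key] = mutual_info_score(codes[:, a], codes[:, b])
        return redundancy_cache[key]

    for _ in range(k):
        best_j, best_score = -1, -np.inf
        for j in range(p):
            if j in selected:
                continue
            red = np.mean([mi_ff(j, s) for s in selected]) if selected else 0.0
            score = relevance[j] - red
            if score > best_score:  # strict improvement: ties keep the lowest index
                best_j, best_score = j, score
        selected.append(best_j)
        scores.append(float(best_score))
    return SelectedFeatureSet(selected, scores, k)


class FeatureScaler:
    """Z-scoring with training-set statistics, reused exactly at test time."""

    def __init__(self):
        self._scaler = StandardScaler()

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        self._scaler.fit(np.asarray(X, dtype=np.float64))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self._scaler.transform(np.asarray(X, dtype=np.float64))

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# random forest


def _binary_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "iub":
        return y.astype(int)
    return np.array([1 if is_failing_label(str(v)) else 0 for v in y], dtype=int)


def train_rf(features: np.ndarray, labels, n_trees: int = 1000, rng_seed: int = 0):
    """Breiman-style random forest: bootstrap bagging, sqrt(p) features per
    split, trees grown to purity.  Failing class is encoded 1."""
    X = np.asarray(features, dtype=np.float64)
    y = _binary_labels(labels)
    if np.unique(y).size < 2:
        raise InvalidDataError("training labels contain a single class")
    counts = np.bincount(y)
    if counts.min() < 2:
        raise InvalidDataError("need at least 2 samples per class")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=int(rng_seed) & 0x7FFFFFFF,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf


def rf_predict(model, features: np.ndarray) -> np.ndarray:
    """Image-level failing probability: the fraction of trees voting failing
    (trees are grown to purity, so the averaged leaf probabilities are the
    vote fractions)."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[1] != model.n_features_in_:
        raise InvalidArgumentError(
            f"feature dimension {X.shape[1]} does not match training ({model.n_features_in_})"
        )
    proba = model.predict_proba(X)
    col = int(np.where(model.classes_ == 1)[0][0])
    return proba[:, col]
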