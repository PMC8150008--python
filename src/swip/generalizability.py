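"""Propensity-score generalizability index between study samples.

For each (focal, previous) pair of samples a logistic membership model
produces sampling propensity scores s(X) = Pr(Z = 1 | X); the
generalizability index B is the Bhattacharyya overlap of the two score
densities, estimated by Gaussian-kernel density estimation on [0, 1].
B = 1 for identical samples, B = 0 for disjoint ones; B-bar averages
B over the K previous studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .simgen import RegressionDataset, StudyDatabase

__all__ = [
    "PropensityScores",
    "GeneralizabilityResult",
    "fit_propensity",
    "estimate_overlap",
    "generalizability_index",
    "sheather_jones_bandwidth",
    "silverman_bandwidth",
]

_CLIP = 1e-6
_GRID_SIZE = 512


@dataclass
class PropensityScores:
    """Fitted membership probabilities split by group, clipped to (0, 1)."""

    s_focal: np.ndarray
    s_prev: np.ndarray
    coef: np.ndarray = None
    intercept: float = 0.0
    penalized: bool = False


@dataclass
class GeneralizabilityResult:
    B_k: np.ndarray
    B_bar: float


# ---------------------------------------------------------------------------
# Bandwidth selection

def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a Gaussian kernel."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        return 0.0
    return 0.9 * scale * n ** (-0.2)


def _phi4(u: np.ndarray) -> np.ndarray:
    return (u**4 - 6.0 * u**2 + 3.0) * np.exp(-0.5 * u**2) / np.sqrt(2 * np.pi)


def _phi6(u: np.ndarray) -> np.ndarray:
    return (
        (u**6 - 15.0 * u**4 + 45.0 * u**2 - 15.0)
        * np.exp(-0.5 * u**2)
        / np.sqrt(2 * np.pi)
    )


def sheather_jones_bandwidth(x: np.ndarray, nbins: int = 512) -> float:
    """Sheather–Jones solve-the-equation plug-in bandwidth.

    Pairwise sums are computed on a linear binning of the data (counts
    autocorrelation over lags), so cost is O(nbins^2) regardless of n.
    Falls back to Silverman's rule when the plug-in equation has no
    bracketed root (tiny or degenerate samples).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    h0 = silverman_bandwidth(x)
    if n < 10 or h0 <= 0:
        return h0
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        return 0.0
    counts, edges = np.histogram(x, bins=nbins, range=(lo, hi))
    delta = edges[1] - edges[0]
    # kappa[l] = sum_i c_i * c_{i+l}; pair sums become 1-D lag sums
    kappa = np.correlate(counts.astype(float), counts.astype(float), mode="full")[
        nbins - 1 :
    ]
    kappa[0] = (kappa[0] - n) / 2.0  # remove self-pairs, halve
    kappa[1:] /= 2.0
    lags = np.arange(nbins) * delta
    npairs = n * (n - 1) / 2.0

    def pair_sum(fun, s: float) -> float:
        return 2.0 * float(np.sum(kappa * fun(lags / s))) / (n * n)

    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    lam = min(sd, iqr / 1.349) if iqr > 0 else sd
    a = 0.920 * lam * n ** (-1.0 / 7.0)
    b = 0.912 * lam * n ** (-1.0 / 9.0)
    TD = -pair_sum(_phi6, b) / (b**7)
    if TD <= 0 or npairs <= 0:
        return h0

    RK = 1.0 / (2.0 * np.sqrt(np.pi))

    def sd_functional(alpha: float) -> float:
        return pair_sum(_phi4, alpha) / (alpha**5) + _phi4(np.array(0.0)) / (
            n * alpha**5
        )

    def objective(h: float) -> float:
        alpha = 1.357 * (abs(sd_functional(a)) / TD) ** (1.0 / 7.0) * h ** (5.0 / 7.0)
        sdval = sd_functional(alpha)
        if sdval <= 0:
            return np.inf
        return (RK / (n * sdval)) ** 0.2 - h

    try:
        f_lo, f_hi = objective(h0 / 8), objective(8 * h0)
        if not (np.isfinite(f_lo) and np.isfinite(f_hi)) or f_lo * f_hi > 0:
            return h0
        return float(brentq(objective, h0 / 8, 8 * h0, xtol=1e-6 * h0))
    except (ValueError, FloatingPointError):
        return h0


_SELECTORS = {"sj": sheather_jones_bandwidth, "silverman": silverman_bandwidth}


# ---------------------------------------------------------------------------
# Propensity model

def fit_propensity(
    X_focal: np.ndarray, X_prev: np.ndarray, ridge_C: float = 10.0
) -> PropensityScores:
    """Logistic regression of sample membership (1 = focal) on covariates.

    Near-perfect separation — a legitimate signature of dissimilar
    samples — triggers a fallback to a lightly L2-penalized fit rather
    than an error; rank-deficient covariate blocks are reduced by
    dropping collinear columns.
    """
    X_focal = np.atleast_2d(np.asarray(X_focal, dtype=float))
    X_prev = np.atleast_2d(np.asarray(X_prev, dtype=float))
    if X_focal.shape[0] == 0 or X_prev.shape[0] == 0:
        raise ValueError("both samples must be non-empty")
    if X_focal.shape[1] != X_prev.shape[1]:
        raise ValueError("covariate dimension mismatch between samples")
    X = np.vstack([X_focal, X_prev])
    n_f = X_focal.shape[0]
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError("too few rows to fit the membership model")
    z = np.zeros(X.shape[0])
    z[:n_f] = 1.0

    # drop collinear columns via pivoted QR on the centered design
    Xc = X - X.mean(axis=0)
    keep = np.arange(X.shape[1])
    r = np.linalg.matrix_rank(Xc)
    if r < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(Xc, pivoting=True, mode="economic")
        keep = np.sort(piv[:r])
        warnings.warn(
            f"collinear covariates: keeping {len(keep)} of {X.shape[1]} columns",
            stacklevel=2,
        )
    Xu = X[:, keep]

    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = LogisticRegression(C=np.inf, max_iter=500).fit(Xu, z)
            if np.max(np.abs(model.coef_)) > 30.0:
                raise ConvergenceWarning("separation")
        except (ConvergenceWarning, Exception):
            model = LogisticRegression(C=ridge_C, max_iter=2000).fit(Xu, z)
            penalized = True
            warnings.warn(
                "membership model separated; used L2-penalized fit",
                stacklevel=2,
            )
    s = model.predict_proba(Xu)[:, 1]
    s = np.clip(s, _CLIP, 1.0 - _CLIP)
    return PropensityScores(
        s_focal=s[:n_f],
        s_prev=s[n_f:],
        coef=model.coef_.ravel(),
        intercept=float(model.intercept_[0]),
        penalized=penalized,
    )


# ---------------------------------------------------------------------------
# Density overlap

_BIN_THRESHOLD = 4096


def _kde_on_grid(x: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    if bandwidth <= 0:
        span = grid[-1] - grid[0]
        bandwidth = max(1e-3 * span, 1e-9)
        warnings.warn("degenerate sample: using minimal bandwidth", stacklevel=3)
    if x.size <= _BIN_THRESHOLD:
        u = (grid[:, None] - x[None, :]) / bandwidth
        dens = np.exp(-0.5 * u**2).sum(axis=1) / (
            x.size * bandwidth * np.sqrt(2 * np.pi)
        )
    else:
        # linear binning onto the evaluation grid: O(grid^2) regardless of n
        step = grid[1] - grid[0]
        pos = np.clip((x - grid[0]) / step, 0.0, grid.size - 1.0)
        lo = np.floor(pos).astype(int)
        frac = pos - lo
        wts = np.bincount(lo, weights=1.0 - frac, minlength=grid.size)
        wts += np.bincount(
            np.minimum(lo + 1, grid.size - 1), weights=frac, minlength=grid.size
        )
        u = (grid[:, None] - grid[None, :]) / bandwidth
        dens = (np.exp(-0.5 * u**2) @ wts) / (
            x.size * bandwidth * np.sqrt(2 * np.pi)
        )
    area = np.trapezoid(dens, grid)
    if area > 0:
        dens /= area
    return dens


def estimate_overlap(
    s_a: np.ndarray,
    s_b: np.ndarray,
    support: tuple = (0.0, 1.0),
    grid_size: int = _GRID_SIZE,
    bw_method: str = "sj",
    product_form: bool = False,
) -> float:
    """Overlap of two score densities on a fixed grid over ``support``.

    Default is the Bhattacharyya coefficient ∫ sqrt(f_a f_b), which is 1
    iff the densities coincide and 0 iff they are disjoint;
    ``product_form=True`` instead integrates the plain product f_a f_b
    (not bounded by 1 in general).  Densities are renormalized on the
    grid before integration and the result is clamped to [0, 1].
    """
    s_a = np.asarray(s_a, dtype=float).ravel()
    s_b = np.asarray(s_b, dtype=float).ravel()
    if s_a.size == 0 or s_b.size == 0:
        raise ValueError("score samples must be non-empty")
    lo, hi = support
    if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
        raise ValueError("support must be a finite, increasing interval")
    select = _SELECTORS[bw_method]
    grid = np.linspace(lo, hi, grid_size)
    f_a = _kde_on_grid(s_a, grid, select(s_a))
    f_b = _kde_on_grid(s_b, grid, select(s_b))
    integrand = f_a * f_b if product_form else np.sqrt(f_a * f_b)
    B = float(np.trapezoid(integrand, grid))
    return min(max(B, 0.0), 1.0)


def generalizability_index(
    focal: RegressionDataset,
    db: StudyDatabase,
    bw_method: str = "sj",
    grid_size: int = _GRID_SIZE,
) -> GeneralizabilityResult:
    """Average generalizability index over the K previous studies.

    B_k is the overlap of focal vs study-k propensity-score densities on
    [0, 1]; B-bar is their unweighted mean.
    """
    if any(s.p != focal.p for s in db.studies):
        raise ValueError("all studies must share the predictor dimension")
    B = np.empty(db.K)
    for k, study in enumerate(db.studies):
        ps = fit_propensity(focal.X, study.X)
        B[k] = estimate_overlap(
            ps.s_focal, ps.s_prev, support=(0.0, 1.0),
            grid_size=grid_size, bw_method=bw_method,
        )
    return GeneralizabilityResult(B_k=B, B_bar=float(B.mean()))
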