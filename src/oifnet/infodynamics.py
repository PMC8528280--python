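"""Shannon entropy, (lagged) mutual information and transfer entropy.

All quantities are in bits.  Three estimators are provided:

``gaussian``
    Covariance-based, parameter-free.  For jointly Gaussian variables MI is
    ``-1/2 log2(1 - r^2)`` and transfer entropy reduces to half the Granger
    log-variance ratio, which gives cheap, deterministic estimates and a
    closed-form oracle for testing.  This is the default.
``kernel``
    Box-kernel (Theiler-style) plug-in estimator with Chebyshev-norm radius
    ``bandwidth`` times the pooled standard deviation (default 0.5).
``binned``
    Equal-width histogram plug-in (default 8 bins per dimension).

Transfer entropy follows the first-order Markov convention: the information the
source at lag ``u`` provides about the next state of the target beyond the
target's own present, TE = I(y(t+1); x(t+1-u) | y(t)).  Negative raw estimates
are numerical artifacts and are clamped to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "InfoEstimate",
    "DelayScan",
    "shannon_entropy",
    "mutual_information",
    "select_delay",
    "transfer_entropy",
    "te_from_temperature",
    "permutation_pvalue",
]

ESTIMATORS = ("gaussian", "kernel", "binned")
LOG2 = np.log(2.0)


@dataclass
class InfoEstimate:
    """A nonnegative information estimate (bits) with its provenance."""

    value: float
    estimator: str
    delay: int = 0
    markov_orders: tuple[int, int] = (1, 1)
    params: dict = field(default_factory=dict)
    clamped: bool = False


@dataclass
class DelayScan:
    """Lagged-MI profile over candidate delays and the selected optimum."""

    mi: np.ndarray          # MI(u) for u = 0..u_max, bits
    u_star: int             # argmax, smallest u on ties
    statistical_distance: float  # d = exp(-I(u*))

    @property
    def i_star(self) -> float:
        return float(self.mi[self.u_star])


def _check_series(*arrs, min_len: int = 2):
    out = []
    L = None
    for a in arrs:
        a = np.asarray(a, dtype=float).ravel()
        if L is None:
            L = a.size
        elif a.size != L:
            raise ValueError(f"series length mismatch: {a.size} != {L}")
        out.append(a)
    if L < min_len:
        raise ValueError(f"series too short ({L} < {min_len})")
    return out


def shannon_entropy(x, bins: int | None = None) -> float:
    """Entropy (bits) of the empirical distribution of ``x``.

    By default each unique value is one event (appropriate for count data,
    where the abundance values themselves are the events); pass ``bins`` for a
    fixed-width discretization of continuous data.
    """
    (x,) = _check_series(x, min_len=1)
    if bins is None:
        _, counts = np.unique(x, return_counts=True)
    else:
        counts, _ = np.histogram(x, bins=bins)
        counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# estimator internals


def _gaussian_mi(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    r2 = min(r * r, 1 - 1e-15)
    return -0.5 * np.log2(1.0 - r2)


def _binned_joint(cols: list[np.ndarray], bins: int) -> np.ndarray:
    H, _ = np.histogramdd(np.column_stack(cols), bins=bins)
    return H


def _entropy_from_counts(H: np.ndarray) -> float:
    p = H[H > 0] / H.sum()
    return float(-(p * np.log2(p)).sum())


def _binned_mi(x, y, bins: int) -> float:
    Hxy = _binned_joint([x, y], bins)
    hx = _entropy_from_counts(Hxy.sum(axis=1))
    hy = _entropy_from_counts(Hxy.sum(axis=0))
    hxy = _entropy_from_counts(Hxy)
    return hx + hy - hxy


def _kernel_entropy(cols: list[np.ndarray], radius: float) -> float:
    """Box-kernel plug-in entropy: H = -<log2 p̂>, with p̂ the fraction of
    points within Chebyshev radius ``radius`` (including the point itself, so
    p̂ > 0)."""
    pts = np.column_stack(cols)
    tree = cKDTree(pts)
    counts = np.array(tree.query_ball_point(pts, r=radius, p=np.inf,
                                            return_length=True))
    p = counts / pts.shape[0]
    return float(-np.mean(np.log2(p)))


def _kernel_radius(cols: list[np.ndarray], bandwidth: float) -> float:
    sd = np.mean([c.std() for c in cols])
    return bandwidth * sd if sd > 0 else bandwidth


def _kernel_mi(x, y, bandwidth: float) -> float:
    r = _kernel_radius([x, y], bandwidth)
    hx = _kernel_entropy([x], r)
    hy = _kernel_entropy([y], r)
    hxy = _kernel_entropy([x, y], r)
    return hx + hy - hxy


def mutual_information(x, y, estimator: str = "gaussian", bins: int = 8,
                       bandwidth: float = 0.5) -> InfoEstimate:
    """Mutual information I(X;Y) in bits (symmetric, clamped at zero)."""
    x, y = _check_series(x, y, min_len=8)
    if estimator == "gaussian":
        v = _gaussian_mi(x, y)
        params = {}
    elif estimator == "binned":
        v = _binned_mi(x, y, bins)
        params = {"bins": bins}
    elif estimator == "kernel":
        v = _kernel_mi(x, y, bandwidth)
        params = {"bandwidth": bandwidth}
    else:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    clamped = v < 0
    return InfoEstimate(value=max(v, 0.0), estimator=estimator, params=params,
                        clamped=clamped)


def lagged_mi(x_source, y_target, u: int, estimator: str = "gaussian",
              **kw) -> float:
    """I(x(t-u); y(t)) on the aligned overlap."""
    x, y = _check_series(x_source, y_target)
    if u == 0:
        return mutual_information(x, y, estimator, **kw).value
    return mutual_information(x[:-u], y[u:], estimator, **kw).value


def select_delay(x_source, y_target, u_max: int = 10,
                 estimator: str = "gaussian", **kw) -> DelayScan:
    """Scan delays u = 0..u_max, pick the u maximizing lagged MI (ties break
    toward the smallest u); report the statistical distance d = exp(-I)."""
    x, y = _check_series(x_source, y_target)
    if x.size - u_max < 8:
        raise ValueError(
            f"series of length {x.size} too short for delay scan to u_max={u_max}"
        )
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant input to delay scan; returning u*=0, I=0")
        return DelayScan(mi=np.zeros(u_max + 1), u_star=0, statistical_distance=1.0)
    mi = np.array([lagged_mi(x, y, u, estimator, **kw) for u in range(u_max + 1)])
    u_star = int(np.argmax(mi))  # argmax returns the first (smallest) maximizer
    return DelayScan(mi=mi, u_star=u_star,
                     statistical_distance=float(np.exp(-mi[u_star])))


def _gaussian_te(yp: np.ndarray, y: np.ndarray, xl: np.ndarray) -> float:
    """TE = 1/2 log2( var(y+|y) / var(y+|y,x) ) from the 3x3 correlation
    matrix of (y(t+1), y(t), x(t+1-u))."""
    cols = np.vstack([yp, y, xl])
    sd = cols.std(axis=1)
    if np.any(sd == 0):
        return 0.0
    R = np.corrcoef(cols)
    if not np.all(np.isfinite(R)):
        return 0.0
    det_full = np.linalg.det(R)
    det_yx = np.linalg.det(R[1:, 1:])
    r_ypy = R[0, 1]
    num = 1.0 - r_ypy ** 2              # var(y+|y) / var(y+)
    if det_yx <= 1e-12 or num <= 0:     # collinear regressors: no usable signal
        return 0.0
    den = det_full / det_yx              # var(y+|y,x) / var(y+)
    # a (near-)deterministic source->target map drives the conditional
    # variance to zero; floor it so the TE stays finite
    den = max(den, 1e-12)
    return 0.5 * np.log2(num / den)


def _plugin_te(yp, y, xl, joint_fn) -> float:
    """TE from four (joint) entropies: H(y+,y) + H(y,x) - H(y+,y,x) - H(y)."""
    h_ypy = joint_fn([yp, y])
    h_yx = joint_fn([y, xl])
    h_ypyx = joint_fn([yp, y, xl])
    h_y = joint_fn([y])
    return h_ypy + h_yx - h_ypyx - h_y


def transfer_entropy(x_source, y_target, u: int = 1, estimator: str = "gaussian",
                     bins: int = 8, bandwidth: float = 0.5) -> InfoEstimate:
    """Transfer entropy TE_{x->y}(q=1, s=1, u) in bits, clamped at zero.

    Built from the aligned triplets (y(t+1), y(t), x(t+1-u)); requires at
    least 8 such triplets.
    """
    x, y = _check_series(x_source, y_target)
    if u < 0:
        raise ValueError("delay u must be >= 0")
    L = x.size
    t0 = max(u - 1, 0)          # first t with t+1-u >= 0
    t = np.arange(t0, L - 1)
    if t.size < 8:
        raise ValueError(
            f"insufficient effective sample: {t.size} triplets (< 8) for "
            f"series of length {L} at delay u={u}"
        )
    yp, yc, xl = y[t + 1], y[t], x[t + 1 - u]
    if estimator == "gaussian":
        v = _gaussian_te(yp, yc, xl)
        params = {}
    elif estimator == "binned":
        v = _plugin_te(yp, yc, xl, lambda cols: _entropy_from_counts(
            _binned_joint(cols, bins)))
        params = {"bins": bins}
    elif estimator == "kernel":
        r = _kernel_radius([yp, yc, xl], bandwidth)
        v = _plugin_te(yp, yc, xl, lambda cols: _kernel_entropy(cols, r))
        params = {"bandwidth": bandwidth}
    else:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    clamped = v < 0
    return InfoEstimate(value=max(v, 0.0), estimator=estimator, delay=u,
                        params=params, clamped=clamped)


def te_with_optimal_delay(x_source, y_target, u_max: int = 10,
                          estimator: str = "gaussian", **kw
                          ) -> tuple[InfoEstimate, DelayScan]:
    """The full source->target step: MI-based delay selection then TE."""
    scan = select_delay(x_source, y_target, u_max=u_max, estimator=estimator, **kw)
    te = transfer_entropy(x_source, y_target, u=scan.u_star,
                          estimator=estimator, **kw)
    return te, scan


def te_from_temperature(temp, target, u_max: int = 10,
                        estimator: str = "gaussian", **kw
                        ) -> dict[str, InfoEstimate]:
    """TE(temperature -> target) at the MI-selected delay, with the reverse
    direction for asymmetry reporting.  The temperature series is z-scored
    first so both inputs live on comparable scales."""
    temp, target = _check_series(temp, target)
    if temp.std() == 0:
        raise ValueError("temperature series is constant")
    tz = (temp - temp.mean()) / temp.std(ddof=1)
    fwd, _ = te_with_optimal_delay(tz, target, u_max=u_max, estimator=estimator, **kw)
    rev, _ = te_with_optimal_delay(target, tz, u_max=u_max, estimator=estimator, **kw)
    return {"forward": fwd, "reverse": rev}


def permutation_pvalue(x_source, y_target, u: int = 1, estimator: str = "gaussian",
                       n_perm: int = 200, seed: int | None = None, **kw) -> float:
    """Optional circular-shift permutation null for a TE value (off by default
    in the pipeline; clamping plus thresholding is the standard noise
    control)."""
    rng = np.random.default_rng(seed)
    x, y = _check_series(x_source, y_target)
    obs = transfer_entropy(x, y, u=u, estimator=estimator, **kw).value
    L = x.size
    null = np.empty(n_perm)
    for k in range(n_perm):
        shift = rng.integers(1, L)
        null[k] = transfer_entropy(np.roll(x, shift), y, u=u,
                                   estimator=estimator, **kw).value
    return float((1 + np.sum(null >= obs)) / (1 + n_perm))
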