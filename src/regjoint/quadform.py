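"""Distribution of quadratic forms in normal variables.

The variance-component score statistic Q = y' Gamma y is, under Gaussian y,
a weighted sum of independent chi-square(1) variables with weights equal to
the eigenvalues of Gamma (times the variance along each eigenvector).  The
survival function is evaluated exactly, with the method chosen
deterministically from the weight configuration:

* all weights equal  -> scaled (noncentral) chi-square closed form;
* two positive central weights -> smooth one-dimensional conditioning
  integral (the oscillatory inversion converges too slowly there);
* otherwise -> characteristic-function inversion (the Imhof/Davies
  integral), with a Kuonen saddlepoint fallback when the integration error
  estimate is unacceptable or the probability is below the inversion's
  absolute accuracy.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, optimize, stats

__all__ = ["weighted_chi2_sf", "weighted_chi2_quantile"]

_EPS = 1e-14
_IMHOF_LIMIT = 800
_IMHOF_ERR_TOL = 1e-5
_IMHOF_ABS_FLOOR = 1e-8  # below this, tail accuracy comes from the saddlepoint


def _imhof_sf(q: float, lam: np.ndarray, delta2: np.ndarray) -> tuple[float, float]:
    """P(sum_j lam_j chi2_1(delta2_j) > q) by characteristic-function inversion."""

    def integrand(u):
        lu = lam * u
        th = 0.5 * np.sum(np.arctan(lu) + delta2 * lu / (1.0 + lu**2)) - 0.5 * q * u
        rho = np.exp(
            0.25 * np.sum(np.log1p(lu**2))
            + 0.5 * np.sum(delta2 * lu**2 / (1.0 + lu**2))
        )
        return np.sin(th) / (u * rho)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(
            integrand, 0.0, np.inf, limit=_IMHOF_LIMIT, epsabs=1e-11, epsrel=1e-9
        )
    return 0.5 + val / np.pi, err


def _two_weight_sf(q: float, l1: float, l2: float) -> float:
    """Exact P(l1 X + l2 Y > q) for X, Y ~ chi2(1), by conditioning on Y."""
    if q <= 0:
        return 1.0

    def f(y):
        return stats.chi2.sf((q - l2 * y) / l1, 1) * stats.chi2.pdf(y, 1)

    cut = q / l2  # beyond this Y alone exceeds q
    tail = stats.chi2.sf(cut, 1)
    val, _ = integrate.quad(f, 0.0, cut, limit=200, epsabs=1e-12, epsrel=1e-10)
    return val + tail


def _saddlepoint_sf(q: float, lam: np.ndarray, delta2: np.ndarray) -> float:
    """Kuonen saddlepoint approximation to the upper tail."""

    def K(z):
        return -0.5 * np.sum(np.log1p(-2 * z * lam)) + np.sum(
            delta2 * lam * z / (1 - 2 * z * lam)
        )

    def K1(z):
        return np.sum(lam / (1 - 2 * z * lam)) + np.sum(
            delta2 * lam / (1 - 2 * z * lam) ** 2
        )

    def K2(z):
        return 2 * np.sum(lam**2 / (1 - 2 * z * lam) ** 2) + 4 * np.sum(
            delta2 * lam**2 / (1 - 2 * z * lam) ** 3
        )

    lam_max, lam_min = lam.max(), lam.min()
    upper = (1.0 / (2 * lam_max)) * (1 - 1e-10) if lam_max > 0 else 1e6
    lower = (1.0 / (2 * lam_min)) * (1 - 1e-10) if lam_min < 0 else -1e6
    mean = K1(0.0)
    if abs(q - mean) < 1e-12 * max(1.0, abs(mean)):
        return 0.5
    try:
        zhat = optimize.brentq(lambda z: K1(z) - q, lower + 1e-12, upper - 1e-12)
    except ValueError:
        return float(q < mean)
    w = np.sign(zhat) * np.sqrt(max(2 * (zhat * q - K(zhat)), 0.0))
    v = zhat * np.sqrt(K2(zhat))
    if abs(w) < 1e-8 or abs(v) < 1e-12:
        return 0.5
    z = w + np.log(v / w) / w
    return float(stats.norm.sf(z))


def weighted_chi2_sf(
    q: float,
    weights: np.ndarray,
    ncp: np.ndarray | None = None,
    return_flag: bool = False,
):
    """Survival probability of Q = sum_j w_j chi2_1(ncp_j) at q.

    Parameters
    ----------
    q : float
        Observed value of the quadratic form.
    weights : array
        Eigenvalue weights; (numerically) zero entries are dropped.
    ncp : array, optional
        Per-term noncentrality parameters (delta_j^2); default all central.
    return_flag : bool
        If True, also return the method used ("closed_form", "conditioning",
        "imhof" or "saddlepoint").
    """
    lam = np.asarray(weights, dtype=float).ravel()
    delta2 = (
        np.zeros_like(lam) if ncp is None else np.asarray(ncp, dtype=float).ravel()
    )
    if delta2.shape != lam.shape:
        raise ValueError("ncp must match weights in length")
    keep = np.abs(lam) > _EPS * max(1.0, np.abs(lam).max(initial=0.0))
    lam, delta2 = lam[keep], delta2[keep]
    if lam.size == 0:
        raise ValueError("all weights are (numerically) zero")
    central = not delta2.any()

    if np.allclose(lam, lam[0], rtol=1e-12, atol=0) and lam[0] > 0:
        p = float(stats.ncx2.sf(q / lam[0], df=lam.size, nc=delta2.sum())
                  if not central else stats.chi2.sf(q / lam[0], df=lam.size))
        return (p, "closed_form") if return_flag else p

    if lam.size == 2 and central and (lam > 0).all():
        p = float(min(max(_two_weight_sf(q, lam[0], lam[1]), 0.0), 1.0))
        return (p, "conditioning") if return_flag else p

    p, err = _imhof_sf(q, lam, delta2)
    flag = "imhof"
    if (
        not np.isfinite(p)
        or err > _IMHOF_ERR_TOL
        or p < _IMHOF_ABS_FLOOR
        or p > 1 + 1e-7
    ):
        p = _saddlepoint_sf(q, lam, delta2)
        flag = "saddlepoint"
    p = float(min(max(p, 5e-324), 1.0))
    return (p, flag) if return_flag else p


def weighted_chi2_quantile(
    alpha: float, weights: np.ndarray, ncp: np.ndarray | None = None
) -> float:
    """Upper-alpha quantile: the q with P(Q > q) = alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    lam = np.asarray(weights, dtype=float).ravel()
    delta2 = np.zeros_like(lam) if ncp is None else np.asarray(ncp, float).ravel()
    mean = float(np.sum(lam * (1 + delta2)))
    sd = float(np.sqrt(2 * np.sum(lam**2 * (1 + 2 * delta2)))) + 1e-12
    hi = mean + 3 * sd
    while weighted_chi2_sf(hi, lam, delta2) > alpha:
        hi = mean + 2 * (hi - mean)
    lo = mean - 3 * sd if lam.min() < 0 else max(mean - 3 * sd, 1e-12)
    while weighted_chi2_sf(lo, lam, delta2) < alpha:
        lo = mean - 2 * (mean - lo) if lam.min() < 0 else lo / 4
        if 0 < lo < 1e-300:
            break
    return float(
        optimize.brentq(lambda t: weighted_chi2_sf(t, lam, delta2) - alpha, lo, hi)
    )
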