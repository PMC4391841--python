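"""Non-additivity of haplotype effects and analytic power.

The additive design captures a fraction of the variance explained by the
underlying haplotypes.  The missed fraction

    tau = (sigma2_H - sigma2_G) / sigma2_H

(where sigma2_G is the variance captured by the additive projection) is
normalized by its maximum attainable value at the system's haplotype
frequencies, giving tau_prime = tau / tau_max in [0, 1]: 0 means the signal
is strictly additive, 1 means deviation from additivity is maximal.

Both sigma2_H and sigma2_G are exact quadratic forms in the haplotype effect
vector beta, so tau_max is the solution of a generalized eigenvalue problem
and is computed in closed form (no stochastic optimization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

from .hapcore import HaplotypeSystem, design_moments, haplotype_variance, \
    population_captured_variance
from .quadform import weighted_chi2_quantile, weighted_chi2_sf

__all__ = [
    "NonAdditivityProfile",
    "PowerSpec",
    "tau",
    "tau_max",
    "effect_path",
    "analytic_power_f",
    "analytic_power_vc",
]


@dataclass
class NonAdditivityProfile:
    tau: float
    tau_max: float
    tau_prime: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.tau <= self.tau_max + 1e-9):
            raise ValueError("need 0 <= tau <= tau_max")


@dataclass
class PowerSpec:
    """Inputs of the fixed-effects analytic power computation.

    ``r2`` is the population proportion of phenotypic variance explained,
    sigma2_X / (sigma2_H + 1) for the haplotype generative model.
    """

    n: int
    alpha: float
    r2: float
    df1: int
    df2: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 <= self.r2 < 1:
            raise ValueError("r2 must be in [0,1)")
        if self.df2 is None:
            self.df2 = self.n - self.df1 - 1


def _quadratic_forms(system: HaplotypeSystem):
    """(A, P): sigma2_H = b'Ab and sigma2_G(additive) = b'Pb."""
    pi = system.pi
    A = 2.0 * (np.diag(pi) - np.outer(pi, pi))
    C_ff, C_fD = design_moments(system, "additive")
    P = C_fD.T @ np.linalg.pinv(C_ff, rcond=1e-12) @ C_fD
    return A, P


def tau(system: HaplotypeSystem) -> NonAdditivityProfile:
    """Non-additivity of the system's effect vector (requires sigma2_H > 0)."""
    s2h = haplotype_variance(system)
    if s2h <= 0:
        raise ValueError("tau is undefined when sigma2_H = 0")
    s2g = population_captured_variance(system, "additive")
    t = max((s2h - s2g) / s2h, 0.0)
    tmax, _ = tau_max(system, sigma2_H=s2h)
    tp = 0.0 if tmax == 0 else min(t / tmax, 1.0)
    return NonAdditivityProfile(tau=t, tau_max=tmax, tau_prime=tp)


def tau_max(system: HaplotypeSystem, sigma2_H: float = 1.0) -> tuple[float, np.ndarray]:
    """Maximum non-additivity attainable at the system's frequencies.

    tau(beta) = 1 - (beta'P beta)/(beta'A beta) is a generalized Rayleigh
    quotient, so its maximum is 1 minus the smallest generalized eigenvalue
    of (P, A) on the complement of A's null space (constant effect vectors).
    Returns (tau_max, beta_star) with beta_star scaled so that
    haplotype_variance(beta_star) = sigma2_H.  The value itself is invariant
    to the scale of beta.
    """
    k = system.k
    if (system.pi <= 0).any():
        raise ValueError("tau_max requires strictly positive haplotype frequencies "
                         "(drop zero-frequency haplotypes)")
    A, P = _quadratic_forms(system)
    if k < 3:
        # with k <= 2 haplotypes the additive span exhausts all k-1 free
        # directions: no non-additive direction exists
        return 0.0, _rescale(system, _additive_vector(system), sigma2_H)
    V = linalg.null_space(np.ones((1, k)))  # basis orthogonal to constants
    At = V.T @ A @ V
    Pt = V.T @ P @ V
    Pt = (Pt + Pt.T) / 2
    At = (At + At.T) / 2
    vals, vecs = linalg.eigh(Pt, At)
    lam_min = max(float(vals[0]), 0.0)
    beta_star = V @ vecs[:, 0]
    return min(1.0 - lam_min, 1.0), _rescale(system, beta_star, sigma2_H)


def _rescale(system: HaplotypeSystem, beta: np.ndarray, sigma2_H: float) -> np.ndarray:
    s2 = haplotype_variance(system.with_beta(beta))
    if s2 <= 0:
        raise ValueError("cannot rescale a zero-variance effect vector")
    return beta * np.sqrt(sigma2_H / s2)


def _additive_vector(system: HaplotypeSystem) -> np.ndarray:
    """Some strictly additive effect vector (beta = H alpha) with variance > 0."""
    H = system.H.astype(float)
    candidates = [H @ np.ones(system.m)]
    candidates += [H[:, j] for j in range(system.m)]
    for b in candidates:
        if haplotype_variance(system.with_beta(b)) > 1e-12:
            return b
    raise ValueError("no additive direction carries variance at these frequencies")


def effect_path(
    system: HaplotypeSystem,
    sigma2_H: float,
    tau_prime_target: float,
    tol: float = 1e-8,
) -> np.ndarray:
    """Haplotype effects with fixed variance and requested non-additivity.

    Interpolates between a strictly additive vector (tau' = 0) and the
    maximizing vector beta_star (tau' = 1), rescaling to keep
    haplotype_variance = sigma2_H, and solves the interpolation weight by
    root bracketing so that tau_prime hits the target to ~1e-8.
    """
    if not 0 <= tau_prime_target <= 1:
        raise ValueError("tau_prime_target must be in [0, 1]")
    if sigma2_H <= 0:
        raise ValueError("sigma2_H must be positive")
    tmax, beta_star = tau_max(system, sigma2_H)
    if tmax == 0.0:
        if tau_prime_target > 0:
            raise ValueError("tau_max = 0 at these frequencies; only tau'=0 attainable")
        return _rescale(system, _additive_vector(system), sigma2_H)
    beta_add = _rescale(system, _additive_vector(system), sigma2_H)
    # align signs so the path does not pass through zero variance
    if haplotype_variance(system.with_beta(beta_add + beta_star)) < sigma2_H / 4:
        beta_star = -beta_star

    def tp(t: float) -> float:
        b = (1 - t) * beta_add + t * beta_star
        sys_b = system.with_beta(b)
        s2h = haplotype_variance(sys_b)
        if s2h <= 1e-14:
            return 1.0  # degenerate interior point; brentq will move away
        s2g = population_captured_variance(sys_b, "additive")
        return max(s2h - s2g, 0.0) / s2h / tmax

    if tau_prime_target <= 0:
        beta = beta_add
    elif tau_prime_target >= 1:
        beta = beta_star
    else:
        t_hat = optimize.brentq(
            lambda t: tp(t) - tau_prime_target, 0.0, 1.0, xtol=1e-13, rtol=1e-15
        )
        beta = (1 - t_hat) * beta_add + t_hat * beta_star
    return _rescale(system, beta, sigma2_H)


# ---------------------------------------------------------------------------
# analytic power
# ---------------------------------------------------------------------------


def analytic_power_f(spec: PowerSpec) -> float:
    """Power of the joint F-test from the non-central F distribution.

    The non-centrality parameter is ncp = n R^2 / (1 - R^2) (fixed-score
    form), with R^2 the population proportion of variance explained.
    """
    if spec.df2 is None or spec.df2 <= 0:
        raise ValueError("df2 must be positive")
    fcrit = stats.f.isf(spec.alpha, spec.df1, spec.df2)
    if spec.r2 == 0:
        return spec.alpha
    ncp = spec.n * spec.r2 / (1.0 - spec.r2)
    return float(stats.ncf.sf(fcrit, spec.df1, spec.df2, ncp))


def analytic_power_vc(
    gamma_eigenvalues: np.ndarray, sigma2_g: float, alpha: float
) -> float:
    """Power of the Davies-based quadratic-form test Q = y' Gamma y.

    Under the alternative the standardized trait has covariance
    sigma2_g * Gamma + (1 - sigma2_g) I, so Q remains a weighted sum of
    chi-square(1) variables with weights lam_j (sigma2_g lam_j + 1 - sigma2_g);
    power is the survival of that distribution at the null critical value.
    """
    lam = np.asarray(gamma_eigenvalues, dtype=float).ravel()
    if lam.size == 0 or not np.isfinite(lam).all():
        raise ValueError("invalid eigenvalue spectrum")
    if not 0 <= sigma2_g < 1:
        raise ValueError("sigma2_g must be in [0, 1) on the standardized scale")
    qcrit = weighted_chi2_quantile(alpha, lam)
    if sigma2_g == 0:
        return alpha
    lam_alt = lam * (sigma2_g * lam + (1.0 - sigma2_g))
    return weighted_chi2_sf(qcrit, lam_alt)
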