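"""Haplotype-system domain types and exact population-level genetics.

The generative model throughout the package is the haplotype model

    Y = D beta + eps,    eps ~ N(0, 1),

where ``D`` (n x k) counts the copies of each of ``k`` haplotypes carried by
each individual, haplotypes are rows of a binary matrix ``H`` (k x m) over m
biallelic SNPs, and ``beta`` is a vector of per-copy haplotype effects.  Under
Hardy-Weinberg equilibrium the two haplotypes of an individual are independent
draws from the population frequency vector ``pi``.

Everything in this module is computed by *exact* enumeration over the
diplotype distribution (no sampling), so these quantities can serve as
oracles for the sampling-based machinery elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeSystem",
    "DiplotypeSample",
    "GenotypeDataset",
    "PhenotypeVector",
    "genotypes_from_diplotypes",
    "allele_frequencies",
    "pairwise_ld",
    "haplotype_variance",
    "population_captured_variance",
    "design_moments",
    "system_with_r2",
]

_FREQ_TOL = 1e-12

DESIGN_KINDS = ("additive", "interaction", "genotypic", "haplotype_prob")


class MonomorphicSNPError(ValueError):
    """LD is undefined for a SNP fixed at frequency 0 or 1."""


@dataclass
class HaplotypeSystem:
    """A set of haplotypes with population frequencies and optional effects.

    Parameters
    ----------
    H : (k, m) array of 0/1
        Haplotype allele codes, one row per distinct haplotype
        (0 = reference allele, 1 = alternate allele).
    pi : (k,) array
        Population haplotype frequencies; non-negative, summing to 1.
    beta : (k,) array, optional
        Per-copy haplotype effects in trait units.

    Haplotypes are conventionally listed in lexicographic order of their
    allele codes (00 < 01 < 10 < 11); zero-frequency haplotypes may be
    omitted, so k <= 2**m.
    """

    H: np.ndarray
    pi: np.ndarray
    beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.int8)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.H.ndim != 2:
            raise ValueError("H must be a 2-d (k x m) matrix")
        k, m = self.H.shape
        if not np.isin(self.H, (0, 1)).all():
            raise ValueError("H entries must be 0 or 1")
        if len({tuple(row) for row in self.H}) != k:
            raise ValueError("haplotype rows must be distinct")
        if k > 2**m:
            raise ValueError(f"k={k} exceeds 2^m={2 ** m}")
        if self.pi.shape != (k,):
            raise ValueError("pi must have one entry per haplotype")
        if (self.pi < -_FREQ_TOL).any():
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        self.pi = np.clip(self.pi, 0.0, None)
        self.pi = self.pi / self.pi.sum()
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
            if self.beta.shape != (k,):
                raise ValueError("beta must have length k")

    @property
    def k(self) -> int:
        return self.H.shape[0]

    @property
    def m(self) -> int:
        return self.H.shape[1]

    def with_beta(self, beta: np.ndarray) -> "HaplotypeSystem":
        return HaplotypeSystem(self.H.copy(), self.pi.copy(), np.asarray(beta, float))

    def require_beta(self) -> np.ndarray:
        if self.beta is None:
            raise ValueError("this operation requires haplotype effects (beta)")
        return self.beta

    # -- plain-text round trip (used by CLI scenario configs) ---------------

    def to_tsv(self, path: str | Path) -> None:
        """Write haplotype string / frequency / effect columns as TSV."""
        hap = ["".join(str(a) for a in row) for row in self.H]
        df = pd.DataFrame({"haplotype": hap, "frequency": self.pi})
        df["effect"] = self.beta if self.beta is not None else np.nan
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplotypeSystem":
        df = pd.read_csv(path, sep="\t", dtype={"haplotype": str})
        H = np.array([[int(c) for c in s] for s in df["haplotype"]], dtype=np.int8)
        beta = None
        if "effect" in df.columns and not df["effect"].isna().all():
            beta = df["effect"].to_numpy(float)
        return cls(H, df["frequency"].to_numpy(float), beta)


@dataclass
class DiplotypeSample:
    """Haplotype copy-counts for n individuals drawn from a HaplotypeSystem."""

    D: np.ndarray
    panel: HaplotypeSystem

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=np.int16)
        if self.D.ndim != 2 or self.D.shape[1] != self.panel.k:
            raise ValueError("D must be n x k for the panel's k haplotypes")
        if not np.isin(self.D, (0, 1, 2)).all():
            raise ValueError("D entries must be in {0,1,2}")
        if not (self.D.sum(axis=1) == 2).all():
            raise ValueError("each D row must sum to 2 (two haplotype copies)")

    @property
    def n(self) -> int:
        return self.D.shape[0]


MISSING = -9  # sentinel for missing genotype calls


@dataclass
class GenotypeDataset:
    """Unphased alternate-allele counts with per-SNP metadata.

    ``snp_meta`` is a DataFrame with columns chrom, pos (1-based bp), snp_id,
    ref, alt; ``G`` entries are in {0,1,2} or MISSING (-9).
    """

    G: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G)
        if self.G.ndim != 2:
            raise ValueError("G must be 2-d (n x m)")
        ok = np.isin(self.G, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("G entries must be 0/1/2 or the missing sentinel")
        if len(self.snp_meta) != self.G.shape[1]:
            raise ValueError("snp_meta must have one row per SNP column")
        if self.sample_ids is None:
            self.sample_ids = [f"S{i + 1}" for i in range(self.G.shape[0])]

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def m(self) -> int:
        return self.G.shape[1]

    def imputed(self) -> np.ndarray:
        """Genotypes as float with missing entries replaced per-SNP by the mean."""
        X = self.G.astype(float)
        miss = self.G == MISSING
        if miss.any():
            X[miss] = np.nan
            col_mean = np.nanmean(X, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(miss)
            X[idx] = col_mean[idx[1]]
        return X

    def subset_snps(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            self.G[:, index],
            self.snp_meta.iloc[index].reset_index(drop=True),
            self.sample_ids,
        )


def default_snp_meta(m: int, chrom: str = "1", spacing_bp: int = 1000) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": np.arange(1, m + 1) * spacing_bp,
            "snp_id": [f"snp{i + 1}" for i in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )


@dataclass
class PhenotypeVector:
    """A quantitative trait vector, optionally standardized to mean 0, var 1."""

    y: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.standardized:
            if abs(self.y.mean()) > 1e-8 or abs(self.y.var() - 1.0) > 1e-8:
                raise ValueError("standardized phenotype must have mean 0, var 1")

    @property
    def n(self) -> int:
        return self.y.size

    def standardize(self) -> "PhenotypeVector":
        s = self.y.std()
        if s == 0:
            raise ValueError("phenotype has zero variance")
        return PhenotypeVector((self.y - self.y.mean()) / s, standardized=True)


# ---------------------------------------------------------------------------
# population-level operations
# ---------------------------------------------------------------------------


def genotypes_from_diplotypes(sample: DiplotypeSample) -> GenotypeDataset:
    """Collapse phased haplotype counts to unphased genotypes, G = D H."""
    G = sample.D @ sample.panel.H.astype(np.int16)
    return GenotypeDataset(G.astype(np.int16), default_snp_meta(sample.panel.m))


def allele_frequencies(system: HaplotypeSystem) -> np.ndarray:
    """Per-SNP alternate-allele frequencies xi_l = sum_i pi_i H_il."""
    return system.pi @ system.H


def pairwise_ld(
    system: HaplotypeSystem, snp_a: int, snp_b: int
) -> tuple[float, float, float]:
    """Two-SNP linkage disequilibrium (D, D', r^2) implied by the system.

    D = P(1,1) - xi_a xi_b;  r^2 = D^2 / (xi_a(1-xi_a) xi_b(1-xi_b));
    D' = D normalized by its frequency-constrained bound (sign-dependent).
    """
    if snp_a == snp_b:
        raise ValueError("snp_a and snp_b must differ")
    xi = allele_frequencies(system)
    xa, xb = xi[snp_a], xi[snp_b]
    for name, x in (("snp_a", xa), ("snp_b", xb)):
        if x <= 0.0 or x >= 1.0:
            raise MonomorphicSNPError(f"{name} is monomorphic (xi={x}); LD undefined")
    p11 = float(system.pi[(system.H[:, snp_a] == 1) & (system.H[:, snp_b] == 1)].sum())
    d = p11 - xa * xb
    r2 = d * d / (xa * (1 - xa) * xb * (1 - xb))
    if d >= 0:
        dmax = min(xa * (1 - xb), xb * (1 - xa))
    else:
        dmax = min(xa * xb, (1 - xa) * (1 - xb))
    d_prime = 0.0 if dmax == 0 else d / dmax
    return d, d_prime, r2


def haplotype_variance(system: HaplotypeSystem) -> float:
    """Variance of the haplotype-model signal D beta under HWE.

    sigma^2_H = sum_i beta_i^2 2 pi_i (1 - pi_i) - 4 sum_{i<j} beta_i beta_j pi_i pi_j,
    equivalently twice the variance of the effect of a single haplotype draw.
    The total trait variance is sigma^2_H + 1.
    """
    beta = system.require_beta()
    pi = system.pi
    mu = pi @ beta
    return float(2.0 * (pi @ (beta**2) - mu * mu))


def _hwe_enumeration(system: HaplotypeSystem):
    """All ordered diplotype pairs (u, v) with HWE weights pi_u pi_v.

    Returns (weights w, genotype rows per pair, u index, v index).
    """
    k = system.k
    u, v = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    u, v = u.ravel(), v.ravel()
    w = system.pi[u] * system.pi[v]
    g = system.H[u].astype(int) + system.H[v].astype(int)
    return w, g, u, v


def _design_features(system: HaplotypeSystem, design_kind: str, g: np.ndarray,
                     u: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Population design features per ordered diplotype pair."""
    if design_kind == "additive":
        return g.astype(float)
    if design_kind == "interaction":
        m = g.shape[1]
        cols = [g.astype(float)]
        for a in range(m):
            for b in range(a + 1, m):
                cols.append((g[:, a] * g[:, b]).astype(float)[:, None])
        return np.hstack(cols)
    if design_kind == "genotypic":
        classes, inv = np.unique(g, axis=0, return_inverse=True)
        F = np.zeros((g.shape[0], classes.shape[0]))
        F[np.arange(g.shape[0]), inv] = 1.0
        return F
    if design_kind == "haplotype_prob":
        # expected haplotype counts given the unphased genotype, E[D | G]
        k = system.k
        classes, inv = np.unique(g, axis=0, return_inverse=True)
        F = np.zeros((g.shape[0], k))
        for c in range(classes.shape[0]):
            rows = inv == c
            ww = w[rows]
            counts = np.zeros(k)
            np.add.at(counts, u[rows], ww)
            np.add.at(counts, v[rows], ww)
            tot = ww.sum()
            F[rows] = counts / tot if tot > 0 else 0.0
        return F
    raise ValueError(f"unsupported design_kind: {design_kind!r}")


def design_moments(system: HaplotypeSystem, design_kind: str):
    """Exact HWE second moments linking a design to the haplotype signal.

    Returns ``(C_ff, C_fD)`` where ``C_ff`` is the covariance of the design
    features and ``C_fD`` the covariance between features and the haplotype
    copy-count vector, so the variance captured by the (centered) design for
    effects beta is ``beta' C_fD' pinv(C_ff) C_fD beta``.
    """
    w, g, u, v = _hwe_enumeration(system)
    F = _design_features(system, design_kind, g, u, v, w)
    mu_f = w @ F
    Fc = F - mu_f
    C_ff = Fc.T @ (Fc * w[:, None])
    k = system.k
    D = np.zeros((len(u), k))
    D[np.arange(len(u)), u] += 1.0
    D[np.arange(len(v)), v] += 1.0
    Dc = D - w @ D
    C_fD = Fc.T @ (Dc * w[:, None])
    return C_ff, C_fD


def population_captured_variance(system: HaplotypeSystem, design_kind: str) -> float:
    """Population variance captured by projecting the signal onto a design.

    Exact HWE expectation of the explained variance B'X'X B / n when the
    chosen design is fitted (with intercept) to the noiseless signal D beta;
    no sampling is involved.  Satisfies
    0 <= sigma^2_X <= sigma^2_H for every linear sub-design.
    """
    beta = system.require_beta()
    if design_kind not in DESIGN_KINDS:
        raise ValueError(f"unsupported design_kind: {design_kind!r}")
    C_ff, C_fD = design_moments(system, design_kind)
    c = C_fD @ beta
    sol = np.linalg.pinv(C_ff, rcond=1e-12) @ c
    return float(c @ sol)


def system_with_r2(
    xi_a: float, xi_b: float, r2: float, sign: int = 1
) -> HaplotypeSystem:
    """Two-SNP haplotype system with given allele frequencies and exact r^2.

    Frequencies are returned in lexicographic haplotype order (00,01,10,11).
    """
    if not (0 < xi_a < 1 and 0 < xi_b < 1):
        raise ValueError("allele frequencies must be strictly inside (0,1)")
    if not 0 <= r2 < 1 or abs(sign) != 1:
        raise ValueError("need 0 <= r2 < 1 and sign in {-1, +1}")
    d = sign * np.sqrt(r2 * xi_a * (1 - xi_a) * xi_b * (1 - xi_b))
    p11 = xi_a * xi_b + d
    p10 = xi_a - p11
    p01 = xi_b - p11
    p00 = 1.0 - p11 - p10 - p01
    pi = np.array([p00, p01, p10, p11])
    if (pi < -1e-12).any():
        raise ValueError("r2 target infeasible at these allele frequencies")
    H = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
    return HaplotypeSystem(H, np.clip(pi, 0, None))
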