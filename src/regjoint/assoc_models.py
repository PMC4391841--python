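"""The five regional association model families.

Design construction (additive, additive + pairwise interactions, genotypic
class indicators, EM haplotype dosages), least-squares fitting with a joint
F-test of all genetic coefficients, and the Haseman-Elston variance-component
estimator with a Davies-type quadratic-form p-value.

All linear models are fitted on column-centered data with an implicit
intercept; rank deficiency is resolved by rank-revealing (pivoted) QR so the
numerator degrees of freedom equal the retained rank.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .hapcore import MISSING, GenotypeDataset, PhenotypeVector
from .quadform import weighted_chi2_sf

__all__ = [
    "DesignMatrix",
    "ModelFit",
    "KinshipMatrix",
    "HaplotypeDosage",
    "design_additive",
    "design_interaction",
    "design_genotypic",
    "em_haplotype_dosages",
    "design_haplotype",
    "fit_linear",
    "grm",
    "fit_vc_he",
    "vc_pvalue_davies",
    "fit_model",
    "MODEL_NAMES",
]

GENOTYPIC_MAX_SNPS = 8
EM_MAX_SNPS = 12
MODEL_NAMES = ("additive", "interaction", "genotypic", "haplotype", "vc")

_RANK_TOL = 1e-8


@dataclass
class DesignMatrix:
    """A numeric design with column labels and the model family it encodes."""

    X: np.ndarray
    labels: list[str]
    design_kind: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise ValueError("design must be n x q with q >= 1")
        if len(self.labels) != self.X.shape[1]:
            raise ValueError("one label per design column required")

    @property
    def q(self) -> int:
        return self.X.shape[1]


@dataclass
class ModelFit:
    """Least-squares fit of one association model on one region.

    ``sigma2_raw`` is the explained variance B'X'XB/n on centered data;
    ``sigma2_adj`` subtracts the finite-sample bias, (ESS - df1 * RSS/df2)/n,
    and is unbiased for the population captured variance (it may be
    negative).  ``r2_raw``/``r2_adj`` are the corresponding proportions of
    total variance.
    """

    design_kind: str
    beta_hat: np.ndarray
    labels: list[str]
    sigma2_raw: float
    sigma2_adj: float
    r2_raw: float
    r2_adj: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n: int
    dropped_columns: list[str] = field(default_factory=list)
    coef_table: pd.DataFrame | None = None

    def to_row(self) -> dict:
        return {
            "model": self.design_kind,
            "F": self.f_stat,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p_value,
            "r2_raw": self.r2_raw,
            "r2_adj": self.r2_adj,
            "sigma2_raw": self.sigma2_raw,
            "sigma2_adj": self.sigma2_adj,
        }


@dataclass
class KinshipMatrix:
    """Genetic-similarity matrix Gamma = Z Z' / m from normalized genotypes.

    The dense n x n matrix is never formed unless asked for: ``Z`` (n x m)
    is kept as a low-rank factor, which is what the Haseman-Elston and
    quadratic-form computations need.
    """

    Z: np.ndarray
    m_snps: int
    scaling: str = "zz_over_m"  # or "zz_raw"

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def _denom(self) -> float:
        return float(self.m_snps) if self.scaling == "zz_over_m" else 1.0

    def dense(self) -> np.ndarray:
        return (self.Z @ self.Z.T) / self._denom

    def eigenvalues(self) -> np.ndarray:
        """Non-zero eigenvalues of Gamma (eigenvalues of Z'Z / denom)."""
        w = np.linalg.eigvalsh(self.Z.T @ self.Z) / self._denom
        return w[w > 1e-10 * max(1.0, w.max())]

    def quad_form(self, y: np.ndarray) -> float:
        s = self.Z.T @ y
        return float(s @ s) / self._denom


@dataclass
class HaplotypeDosage:
    """EM posterior-expected haplotype counts from unphased genotypes."""

    M: np.ndarray
    haplotypes: np.ndarray  # h x m binary codes, row order matches M columns
    em_frequencies: np.ndarray
    loglik_trace: np.ndarray
    converged: bool

    def __post_init__(self) -> None:
        rs = self.M.sum(axis=1)
        if np.abs(rs - 2.0).max() > 1e-8:
            raise ValueError("dosage rows must sum to 2")

    def labels(self) -> list[str]:
        return ["hap_" + "".join(str(a) for a in row) for row in self.haplotypes]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def _check_complete(G: GenotypeDataset) -> np.ndarray:
    X = np.asarray(G.G, dtype=float)
    if (G.G == MISSING).any():
        raise ValueError("missing genotypes present; impute before building designs")
    return X


def design_additive(G: GenotypeDataset) -> DesignMatrix:
    """One allele-count column per SNP (the multivariate additive model)."""
    if G.m == 0:
        raise ValueError("empty SNP set")
    X = _check_complete(G)
    return DesignMatrix(X, list(G.snp_meta["snp_id"]), "additive")


def design_interaction(G: GenotypeDataset) -> DesignMatrix:
    """Allele counts plus all C(m,2) pairwise genotype products."""
    if G.m < 2:
        raise ValueError("interaction design needs at least 2 SNPs")
    X = _check_complete(G)
    ids = list(G.snp_meta["snp_id"])
    cols, labels = [X], list(ids)
    for a, b in itertools.combinations(range(G.m), 2):
        cols.append((X[:, a] * X[:, b])[:, None])
        labels.append(f"{ids[a]}x{ids[b]}")
    return DesignMatrix(np.hstack(cols), labels, "interaction")


def design_genotypic(G: GenotypeDataset, genotypic_max: int = GENOTYPIC_MAX_SNPS) -> DesignMatrix:
    """Indicators over the multilocus genotype classes (up to 3^m).

    Columns are built for the classes observed in the sample; one redundant
    column (the most frequent class) is dropped against the intercept so the
    model degrees of freedom are explicit.
    """
    if G.m > genotypic_max:
        raise ValueError(
            f"genotypic design with m={G.m} SNPs implies 3^{G.m} columns; "
            f"raise genotypic_max (currently {genotypic_max}) to force it"
        )
    X = _check_complete(G).astype(int)
    classes, inv, counts = np.unique(
        X, axis=0, return_inverse=True, return_counts=True
    )
    F = np.zeros((G.n, classes.shape[0]))
    F[np.arange(G.n), inv] = 1.0
    labels = ["g_" + " ".join(str(a) for a in row) for row in classes]
    ref = int(np.argmax(counts))  # dropped reference class
    keep = [j for j in range(classes.shape[0]) if j != ref]
    return DesignMatrix(F[:, keep], [labels[j] for j in keep], "genotypic")


# ---------------------------------------------------------------------------
# EM haplotype dosages
# ---------------------------------------------------------------------------


def _compatible_pairs(g: np.ndarray) -> list[tuple[tuple, tuple]]:
    """All ordered haplotype pairs consistent with one unphased genotype row."""
    het = np.where(g == 1)[0]
    base = np.where(g == 2, 1, 0)
    pairs = []
    for bits in itertools.product((0, 1), repeat=len(het)):
        h1 = base.copy()
        h1[het] = bits
        h2 = g - h1
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def em_haplotype_dosages(
    G: GenotypeDataset,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeDosage:
    """EM haplotype-frequency estimation and posterior dosages under HWE.

    The E-step weights each compatible ordered haplotype pair (u, v) of an
    individual proportionally to pi_u * pi_v; the M-step re-estimates the
    frequencies from the posterior-expected counts.  Individuals are grouped
    by genotype class, so the complexity is driven by the number of distinct
    multilocus genotypes rather than by n.
    """
    if G.m > EM_MAX_SNPS:
        raise ValueError(f"EM phase enumeration limited to m <= {EM_MAX_SNPS} SNPs")
    X = _check_complete(G).astype(int)
    classes, inv, counts = np.unique(X, axis=0, return_inverse=True, return_counts=True)

    class_pairs = [_compatible_pairs(g) for g in classes]
    hap_index: dict[tuple, int] = {}
    for pairs in class_pairs:
        for h1, h2 in pairs:
            for h in (h1, h2):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
    haps = sorted(hap_index, key=lambda h: hap_index[h])
    # re-sort lexicographically for a stable, documented column order
    order = sorted(range(len(haps)), key=lambda i: haps[i])
    haps = [haps[i] for i in order]
    hap_index = {h: i for i, h in enumerate(haps)}
    k = len(haps)

    pair_u = [np.array([hap_index[a] for a, _ in pairs]) for pairs in class_pairs]
    pair_v = [np.array([hap_index[b] for _, b in pairs]) for pairs in class_pairs]

    n = G.n
    pi = np.full(k, 1.0 / k)
    loglik = []
    converged = False
    for _ in range(max_iter):
        new_pi = np.zeros(k)
        ll = 0.0
        for c, cnt in enumerate(counts):
            w = pi[pair_u[c]] * pi[pair_v[c]]
            tot = w.sum()
            ll += cnt * np.log(max(tot, 1e-300))
            w = w / max(tot, 1e-300)
            np.add.at(new_pi, pair_u[c], cnt * w)
            np.add.at(new_pi, pair_v[c], cnt * w)
        new_pi /= 2.0 * n
        loglik.append(ll)
        if np.abs(new_pi - pi).max() < tol:
            pi = new_pi
            converged = True
            break
        pi = new_pi

    M_class = np.zeros((len(classes), k))
    for c in range(len(classes)):
        w = pi[pair_u[c]] * pi[pair_v[c]]
        w = w / max(w.sum(), 1e-300)
        np.add.at(M_class[c], pair_u[c], w)
        np.add.at(M_class[c], pair_v[c], w)
    M = M_class[inv]
    return HaplotypeDosage(
        M, np.array(haps, dtype=np.int8), pi, np.asarray(loglik), converged
    )


def design_haplotype(G: GenotypeDataset) -> DesignMatrix:
    """Haplotype-probability design: EM dosage columns (one dropped).

    Rows of the dosage matrix sum to 2, so the most frequent haplotype's
    column is dropped against the intercept.
    """
    dos = em_haplotype_dosages(G)
    ref = int(np.argmax(dos.em_frequencies))
    keep = [j for j in range(dos.M.shape[1]) if j != ref]
    labels = [dos.labels()[j] for j in keep]
    if not keep:  # single haplotype: no genetic variation
        raise ValueError("haplotype design is degenerate (one haplotype)")
    return DesignMatrix(dos.M[:, keep], labels, "haplotype")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_linear(X: DesignMatrix, y: PhenotypeVector | np.ndarray) -> ModelFit:
    """Centered least squares with a joint F-test of all genetic columns.

    Rank-revealing pivoted QR (relative tolerance 1e-8) drops collinear
    columns; df1 equals the retained rank and dropped columns are reported.
    """
    yv = y.y if isinstance(y, PhenotypeVector) else np.asarray(y, float).ravel()
    n, q = X.X.shape
    if n != yv.size:
        raise ValueError("design and phenotype lengths differ")
    yc = yv - yv.mean()
    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("phenotype has zero variance")
    Xc = X.X - X.X.mean(axis=0)

    Q, R, piv = linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > _RANK_TOL * (diag[0] if diag.size and diag[0] > 0 else 1.0)))
    if rank == 0:
        raise ValueError("design has rank 0 after centering")
    if n <= rank + 1:
        raise ValueError("need n > rank(X) + 1 observations")

    kept = piv[:rank]
    Q1 = Q[:, :rank]
    R1 = R[:rank, :rank]
    qty = Q1.T @ yc
    b_kept = linalg.solve_triangular(R1, qty)
    beta_hat = np.zeros(q)
    beta_hat[kept] = b_kept

    ess = float(qty @ qty)
    rss = max(tss - ess, 0.0)
    df1, df2 = rank, n - rank - 1
    sigma2_resid = rss / df2
    f_stat = (ess / df1) / sigma2_resid if sigma2_resid > 0 else np.inf
    p_value = float(stats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 5e-324
    p_value = max(p_value, 5e-324)

    r2_raw = ess / tss
    r2_adj = 1.0 - (1.0 - r2_raw) * (n - 1) / df2
    sigma2_raw = ess / n
    sigma2_adj = (ess - df1 * sigma2_resid) / n

    # per-column multivariate coefficient stats on the retained columns
    Rinv = linalg.solve_triangular(R1, np.eye(rank))
    var_b = sigma2_resid * np.sum(Rinv**2, axis=1)
    se = np.sqrt(var_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, b_kept / se, np.nan)
    pvals = 2 * stats.t.sf(np.abs(tvals), df2)
    coef = pd.DataFrame(
        {
            "term": [X.labels[j] for j in kept],
            "beta": b_kept,
            "se": se,
            "t": tvals,
            "p": pvals,
        }
    )
    dropped = [X.labels[j] for j in piv[rank:]]

    return ModelFit(
        design_kind=X.design_kind,
        beta_hat=beta_hat,
        labels=list(X.labels),
        sigma2_raw=sigma2_raw,
        sigma2_adj=sigma2_adj,
        r2_raw=r2_raw,
        r2_adj=r2_adj,
        f_stat=float(f_stat),
        df1=df1,
        df2=df2,
        p_value=p_value,
        n=n,
        dropped_columns=dropped,
        coef_table=coef,
    )


# ---------------------------------------------------------------------------
# variance component model
# ---------------------------------------------------------------------------


def grm(G: GenotypeDataset, scaling: str = "zz_over_m") -> KinshipMatrix:
    """Genomic relationship matrix from standardized allele counts.

    z_il = (g_il - 2 xi_l) / sqrt(2 xi_l (1 - xi_l)) with xi_l the sample
    allele frequency, so each column has (in-sample) mean 0 and variance ~1.
    Gamma = Z Z' / m by default ("zz_raw" keeps the unscaled cross-product).
    """
    if scaling not in ("zz_over_m", "zz_raw"):
        raise ValueError("scaling must be 'zz_over_m' or 'zz_raw'")
    X = G.imputed()
    xi = X.mean(axis=0) / 2.0
    mono = (xi <= 0.0) | (xi >= 1.0)
    if mono.any():
        bad = list(G.snp_meta["snp_id"][mono])
        raise ValueError(f"monomorphic SNPs must be dropped before grm: {bad}")
    Z = (X - 2 * xi) / np.sqrt(2 * xi * (1 - xi))
    return KinshipMatrix(Z, m_snps=G.m, scaling=scaling)


def fit_vc_he(
    Gamma: KinshipMatrix, y: PhenotypeVector
) -> tuple[float, float, float]:
    """Haseman-Elston regression of squared trait differences on kinship.

    Regresses (y_i - y_j)^2 on Gamma_ij over all i < j pairs.  With the
    Gamma = ZZ'/m scaling the genetic variance on the trait scale is
    sigma2_g = -v1 / 2.  Returns (sigma2_g_hat, v0_hat, v1_hat).

    The pair-level regression is evaluated from O(n m) sufficient statistics
    of the factor Z; the n(n-1)/2 pairs are never materialized.
    """
    if not y.standardized:
        raise ValueError("fit_vc_he expects a standardized phenotype")
    yv = y.y
    n = yv.size
    if n < 3:
        raise ValueError("need at least 3 individuals")
    Z = Gamma.Z
    denom = Gamma._denom

    r = (Z @ (Z.T @ np.ones(n))) / denom          # row sums of Gamma
    diag = np.einsum("ij,ij->i", Z, Z) / denom    # diagonal of Gamma
    ZtZ = Z.T @ Z
    frob2 = float(np.sum(ZtZ**2)) / denom**2      # ||Gamma||_F^2
    s = Z.T @ yv
    yGy = float(s @ s) / denom

    N = n * (n - 1) / 2.0
    Sx = (float(r.sum()) - float(diag.sum())) / 2.0
    Sxx = (frob2 - float(np.sum(diag**2))) / 2.0
    sum_y2 = float(yv @ yv)
    Sd = n * sum_y2 - float(yv.sum()) ** 2
    # sum_{i<j} Gamma_ij (y_i^2 + y_j^2) and cross term
    Sxy2 = float(np.sum(yv**2 * (r - diag)))
    cross = yGy - float(np.sum(diag * yv**2))
    Sxd = Sxy2 - cross

    var_x = Sxx - Sx * Sx / N
    if var_x <= 0:
        raise ValueError("kinship entries are constant; HE slope undefined")
    v1 = (Sxd - Sx * Sd / N) / var_x
    v0 = Sd / N - v1 * Sx / N
    sigma2_g = -v1 / 2.0
    if Gamma.scaling == "zz_raw":
        sigma2_g *= Gamma.m_snps  # -v1/2 on the raw scale is sigma2_g / m
    return sigma2_g, v0, v1


def vc_pvalue_davies(
    Gamma: KinshipMatrix, y: PhenotypeVector, return_flag: bool = False
):
    """P-value for the quadratic form Q = y' Gamma y.

    Under the null, y ~ N(0, I) (standardized trait) and Q is a weighted sum
    of chi-square(1) variables with weights equal to the eigenvalues of
    Gamma; the survival function is evaluated by exact numerical inversion
    (saddlepoint fallback flagged when the inversion fails to converge).
    """
    if not y.standardized:
        raise ValueError("vc_pvalue_davies expects a standardized phenotype")
    q = Gamma.quad_form(y.y)
    lam = Gamma.eigenvalues()
    p, flag = weighted_chi2_sf(q, lam, return_flag=True)
    return (p, flag) if return_flag else p


# ---------------------------------------------------------------------------
# one-call dispatch used by the simulation engine and CLI
# ---------------------------------------------------------------------------


def fit_model(name: str, G: GenotypeDataset, y: PhenotypeVector | np.ndarray):
    """Fit one named model; returns a ModelFit, or a dict for the VC model."""
    if name == "additive":
        return fit_linear(design_additive(G), y)
    if name == "interaction":
        return fit_linear(design_interaction(G), y)
    if name == "genotypic":
        return fit_linear(design_genotypic(G), y)
    if name == "haplotype":
        return fit_linear(design_haplotype(G), y)
    if name == "vc":
        yv = y.y if isinstance(y, PhenotypeVector) else np.asarray(y, float)
        ystd = PhenotypeVector(yv).standardize()
        Gamma = grm(G)
        sigma2_g, v0, v1 = fit_vc_he(Gamma, ystd)
        scale = float(np.var(yv))  # back to trait units
        p = vc_pvalue_davies(Gamma, ystd)
        return {
            "model": "vc",
            "sigma2_raw": sigma2_g * scale,
            "sigma2_adj": sigma2_g * scale,
            "v0": v0,
            "v1": v1,
            "p": p,
        }
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
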