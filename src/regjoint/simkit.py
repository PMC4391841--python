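"""Simulation engine for regional association scenarios.

Covers three families of experiments:

* common-variant scenarios — a small causal haplotype system (optionally
  extended with "nuisance" SNPs at fixed pairwise LD) with haplotype effects
  set by the non-additivity path;
* rare-variant tagging scenarios — an untyped rare causal allele riding on
  the 1-1 haplotype of two common SNPs in mutual linkage equilibrium;
* panel-window scenarios — windows of SNPs drawn from a phased haplotype
  panel with two designated causal SNPs, the rest acting as nuisance.

Plus the synthetic phased-panel generator (a founder-mosaic copying process
with tunable LD decay and allele-frequency spectrum) that stands in for a
real reference panel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .assoc_models import MODEL_NAMES, fit_model
from .hapcore import (
    DiplotypeSample,
    GenotypeDataset,
    HaplotypeSystem,
    PhenotypeVector,
    allele_frequencies,
    default_snp_meta,
    haplotype_variance,
    pairwise_ld,
)
from .nonadd_power import effect_path

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "PhasedPanel",
    "sample_diplotypes",
    "simulate_phenotype",
    "extend_with_nuisance",
    "rare_tagging_scenario",
    "panel_window_scenario",
    "run_scenario",
    "generate_fixture_panel",
]


@dataclass
class ScenarioConfig:
    """One simulation scenario: generative system, sample sizes, models.

    ``mask`` lists SNP columns hidden from fitting (e.g. an untyped causal
    variant); ``models`` are names from assoc_models.MODEL_NAMES.
    """

    system: HaplotypeSystem
    n: int = 5000
    n_replicates: int = 10000
    models: tuple[str, ...] = ("additive",)
    alpha: float = 5e-5
    seed: int = 0
    mask: tuple[int, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if any(j < 0 or j >= self.system.m for j in self.mask):
            raise ValueError("mask indices out of range")

    @property
    def visible_snps(self) -> np.ndarray:
        return np.array([j for j in range(self.system.m) if j not in set(self.mask)])


@dataclass
class ScenarioResult:
    """Replicate-aggregated estimates for each fitted model."""

    table: pd.DataFrame  # one row per model
    config: ScenarioConfig
    n_replicates_done: int
    failures: dict = field(default_factory=dict)

    def row(self, model: str) -> pd.Series:
        return self.table.set_index("model").loc[model]


# ---------------------------------------------------------------------------
# sampling under the haplotype model
# ---------------------------------------------------------------------------


def _draw_hap_indices(system: HaplotypeSystem, n: int, rng: np.random.Generator):
    return rng.choice(system.k, size=(n, 2), p=system.pi)


def sample_diplotypes(
    system: HaplotypeSystem, n: int, rng: np.random.Generator
) -> DiplotypeSample:
    """n individuals as two independent haplotype draws from pi (HWE)."""
    idx = _draw_hap_indices(system, n, rng)
    D = np.zeros((n, system.k), dtype=np.int16)
    rows = np.arange(n)
    np.add.at(D, (rows, idx[:, 0]), 1)
    np.add.at(D, (rows, idx[:, 1]), 1)
    return DiplotypeSample(D, system)


def simulate_phenotype(
    sample: DiplotypeSample, system: HaplotypeSystem, rng: np.random.Generator
) -> PhenotypeVector:
    """y = D beta + eps with standard normal errors."""
    beta = system.require_beta()
    y = sample.D @ beta + rng.standard_normal(sample.n)
    return PhenotypeVector(y)


# ---------------------------------------------------------------------------
# nuisance-SNP construction at fixed pairwise LD
# ---------------------------------------------------------------------------


class InfeasibleLDError(ValueError):
    pass


def extend_with_nuisance(
    system: HaplotypeSystem,
    n_nuisance: int,
    target_r2: float,
    nuisance_freq: float | None = None,
    tol: float = 1e-6,
) -> HaplotypeSystem:
    """Add non-associated SNPs whose pairwise r2 with every other SNP hits a target.

    The joint haplotype frequencies over causal + nuisance SNPs are solved by
    constrained least squares on the r2 targets over the enlarged frequency
    simplex, holding the causal sub-distribution fixed.  Effects are extended
    by zeros, so sigma2_H is unchanged.  Pairs internal to the causal system
    are left as supplied (they must already meet the target if uniform LD is
    wanted).  Raises InfeasibleLDError naming the worst pair if the targets
    cannot be met to ``tol``.
    """
    if n_nuisance < 1:
        raise ValueError("n_nuisance must be >= 1")
    if not 0 <= target_r2 < 1:
        raise ValueError("target r2 must be in [0, 1)")
    m0, k0 = system.m, system.k
    if nuisance_freq is None:
        nuisance_freq = float(np.mean(allele_frequencies(system)))
    m = m0 + n_nuisance

    # enlarged haplotype table: causal haplotypes x nuisance allele combos
    combos = np.array(list(itertools.product((0, 1), repeat=n_nuisance)), dtype=np.int8)
    H = np.hstack(
        [
            np.repeat(system.H, len(combos), axis=0),
            np.tile(combos, (k0, 1)),
        ]
    )
    causal_of_row = np.repeat(np.arange(k0), len(combos))

    q = nuisance_freq
    combo_p = np.prod(np.where(combos == 1, q, 1 - q), axis=1)
    p0 = system.pi[causal_of_row] * np.tile(combo_p, k0)  # product start

    if target_r2 == 0.0:
        out = HaplotypeSystem(H, p0)
    else:
        pairs = [
            (a, b)
            for a, b in itertools.combinations(range(m), 2)
            if a >= m0 or b >= m0
        ]

        def r2_vec(p):
            xi = p @ H
            out = np.empty(len(pairs))
            for i, (a, b) in enumerate(pairs):
                p11 = p[(H[:, a] == 1) & (H[:, b] == 1)].sum()
                d = p11 - xi[a] * xi[b]
                denom = xi[a] * (1 - xi[a]) * xi[b] * (1 - xi[b])
                out[i] = d * d / denom if denom > 0 else np.inf
            return out

        def objective(p):
            return float(np.sum((r2_vec(p) - target_r2) ** 2))

        # the causal-marginal equalities imply sum(p) = 1, so the simplex
        # constraint is omitted (it makes the SLSQP constraint matrix singular)
        A_marg = np.zeros((k0, H.shape[0]))
        A_marg[causal_of_row, np.arange(H.shape[0])] = 1.0
        constraints = [{"type": "eq", "fun": lambda p, A=A_marg: A @ p - system.pi}]
        best = None
        rng = np.random.default_rng(12345)
        for attempt in range(12):
            start = p0 if attempt == 0 else np.clip(
                p0 + rng.normal(0, 0.05, size=p0.size), 1e-5, None
            )
            start = start / start.sum()
            res = optimize.minimize(
                objective,
                start,
                method="SLSQP",
                bounds=[(0.0, 1.0)] * H.shape[0],
                constraints=constraints,
                options={"maxiter": 2000, "ftol": 1e-14},
            )
            if best is None or res.fun < best.fun:
                best = res
            if best.fun < (tol**2) / 10:
                break
        p = np.clip(best.x, 0.0, None)
        p = p / p.sum()
        out = HaplotypeSystem(H, p)
        errs = np.abs(r2_vec(p) - target_r2)
        worst = int(np.argmax(errs))
        if errs[worst] > tol:
            a, b = pairs[worst]
            raise InfeasibleLDError(
                f"could not reach r2={target_r2} for SNP pair ({a},{b}); "
                f"achieved {r2_vec(p)[worst]:.6f}"
            )

    if system.beta is not None:
        # nuisance dimensions carry no effect: beta depends on the causal part only
        out = out.with_beta(system.beta[causal_of_row])
    return out


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------


def rare_tagging_scenario(
    f_rare: float = 1.0 / 576.0,
    variance_explained: float = 0.01,
    r2_hap: float = 1.0,
    n_common_extra: int = 0,
    n: int = 5000,
    n_replicates: int = 5000,
    models: tuple[str, ...] = ("additive", "haplotype"),
    alpha: float = 5e-5,
    seed: int = 0,
    mask_rare: bool = True,
) -> ScenarioConfig:
    """Untyped rare causal variant tagged by the 1-1 haplotype of two common SNPs.

    The two common tagging SNPs are in mutual linkage equilibrium with equal
    allele frequency p; their 1-1 haplotype has frequency h = p^2.  The rare
    allele (frequency f_rare) resides only on that haplotype (D' = 1), with
    r2_hap = f(1-h) / (h(1-f)) between rare allele and tagging haplotype.
    The rare effect is sized so it contributes ``variance_explained`` to the
    trait variance: 2 f (1-f) beta^2 = variance_explained.  By default the
    rare SNP is masked from fitting (set ``mask_rare=False`` for the typed
    variant of the experiment).

    With the defaults (r2_hap = 1) p = 1/24, so the r2 between each common
    SNP and the rare allele is p/(1+p) = 0.04.
    """
    if f_rare > 0.01:
        raise ValueError("f_rare must be <= 0.01 (rare variant)")
    if not 0 < r2_hap <= 1:
        raise ValueError("r2_hap must be in (0, 1]")
    f = f_rare
    h = f / (r2_hap * (1 - f) + f)  # 1-1 haplotype frequency
    if not f <= h < 1:
        raise InfeasibleLDError("inconsistent (f_rare, r2_hap) geometry")
    p = float(np.sqrt(h))  # common SNP allele frequency (equal for both)
    rows = [
        ((0, 0, 0), (1 - p) * (1 - p)),
        ((0, 1, 0), (1 - p) * p),
        ((1, 0, 0), p * (1 - p)),
        ((1, 1, 1), f),
    ]
    if h - f > 1e-15:
        rows.append(((1, 1, 0), h - f))
    H = np.array([r[0] for r in rows], dtype=np.int8)
    pi = np.array([r[1] for r in rows], dtype=float)
    beta_r = float(np.sqrt(variance_explained / (2 * f * (1 - f))))
    beta = beta_r * H[:, 2].astype(float)
    system = HaplotypeSystem(H, pi, beta)
    if n_common_extra:
        system = extend_with_nuisance(system, n_common_extra, 0.0, nuisance_freq=0.2)
    mask = (2,) if mask_rare else ()
    return ScenarioConfig(
        system=system,
        n=n,
        n_replicates=n_replicates,
        models=models,
        alpha=alpha,
        seed=seed,
        mask=mask,
        label=f"rare_tagging r2_hap={r2_hap} ve={variance_explained}",
    )


def common_variant_scenario(
    pi: np.ndarray,
    sigma2_H: float,
    tau_prime: float,
    n_nuisance: int = 0,
    nuisance_r2: float = 0.0,
    n: int = 5000,
    n_replicates: int = 5000,
    models: tuple[str, ...] = ("additive",),
    alpha: float = 5e-5,
    seed: int = 0,
) -> ScenarioConfig:
    """Two causal SNPs (4 haplotypes) at fixed sigma2_H and non-additivity."""
    H = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
    base = HaplotypeSystem(H, np.asarray(pi, float))
    beta = effect_path(base, sigma2_H, tau_prime)
    system = base.with_beta(beta)
    if n_nuisance:
        system = extend_with_nuisance(system, n_nuisance, nuisance_r2)
    return ScenarioConfig(
        system=system,
        n=n,
        n_replicates=n_replicates,
        models=models,
        alpha=alpha,
        seed=seed,
        label=f"common tau'={tau_prime} s2H={sigma2_H}",
    )


# ---------------------------------------------------------------------------
# phased panels
# ---------------------------------------------------------------------------


@dataclass
class PhasedPanel:
    """A phased haplotype panel: rows are haplotypes, columns SNPs."""

    haplotypes: np.ndarray  # (n_hap, m) int8 0/1
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if len(self.snp_meta) != self.haplotypes.shape[1]:
            raise ValueError("snp_meta must match panel SNP count")

    @property
    def m(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    def maf(self) -> np.ndarray:
        freq = self.haplotypes.mean(axis=0)
        return np.minimum(freq, 1 - freq)

    def subset(self, snp_index: np.ndarray) -> "PhasedPanel":
        snp_index = np.asarray(snp_index)
        return PhasedPanel(
            self.haplotypes[:, snp_index],
            self.snp_meta.iloc[snp_index].reset_index(drop=True),
        )

    def r2_matrix(self) -> np.ndarray:
        X = self.haplotypes.astype(float)
        sd = X.std(axis=0)
        if (sd == 0).any():
            raise ValueError("panel contains monomorphic SNPs")
        C = np.corrcoef(X, rowvar=False)
        return C**2

    def as_system(self, beta_by_hap: np.ndarray | None = None) -> HaplotypeSystem:
        """Collapse to a HaplotypeSystem of the distinct panel haplotypes."""
        uniq, inv, counts = np.unique(
            self.haplotypes, axis=0, return_inverse=True, return_counts=True
        )
        pi = counts / counts.sum()
        beta = None
        if beta_by_hap is not None:
            beta = np.zeros(len(uniq))
            # beta supplied per panel row; rows mapping to the same distinct
            # haplotype must agree
            for row, b in zip(inv, np.asarray(beta_by_hap, float)):
                beta[row] = b
        return HaplotypeSystem(uniq, pi, beta)


def generate_fixture_panel(
    n_haplotypes: int = 400,
    n_snps: int = 300,
    ld_decay: float = 0.1,
    maf_spec: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    n_founders: int = 16,
    mean_spacing_bp: int = 3000,
    chrom: str = "1",
) -> PhasedPanel:
    """Synthetic phased haplotype panel from a founder-mosaic copying process.

    Each panel haplotype copies contiguous segments from ``n_founders``
    founder haplotypes, switching founders between adjacent SNPs with
    probability ``ld_decay`` (smaller = longer-range LD).  Founder allele
    frequencies are drawn uniformly on ``maf_spec``; columns whose realized
    minor-allele frequency falls outside the requested band are dropped, so
    the returned panel satisfies the MAF spec by construction (extra columns
    are generated to compensate).  Deterministic given ``seed``.
    """
    lo, hi = maf_spec
    if not 0 < lo < hi <= 0.5:
        raise ValueError("maf_spec must satisfy 0 < lo < hi <= 0.5")
    rng = np.random.default_rng(seed)
    m_gen = int(np.ceil(n_snps * 1.6)) + 20
    freq = rng.uniform(lo, hi, size=m_gen)
    founders = (rng.random((n_founders, m_gen)) < freq).astype(np.int8)

    source = np.empty((n_haplotypes, m_gen), dtype=np.int64)
    source[:, 0] = rng.integers(0, n_founders, size=n_haplotypes)
    switch = rng.random((n_haplotypes, m_gen - 1)) < ld_decay
    new_source = rng.integers(0, n_founders, size=(n_haplotypes, m_gen - 1))
    for j in range(1, m_gen):
        source[:, j] = np.where(switch[:, j - 1], new_source[:, j - 1], source[:, j - 1])
    hap = founders[source, np.arange(m_gen)]
    # sparse mutation so panel haplotypes are not pure founder mosaics
    mut = rng.random(hap.shape) < 0.005
    hap = np.where(mut, 1 - hap, hap).astype(np.int8)

    realized = hap.mean(axis=0)
    maf = np.minimum(realized, 1 - realized)
    ok = np.where((maf >= lo) & (maf <= hi))[0]
    if ok.size < n_snps:
        raise RuntimeError(
            f"mosaic produced only {ok.size} in-band SNPs of {n_snps} requested; "
            "widen maf_spec or raise n_founders"
        )
    keep = ok[:n_snps]
    hap = hap[:, keep]
    spacing = rng.integers(mean_spacing_bp // 2, mean_spacing_bp * 3 // 2, size=n_snps)
    pos = np.cumsum(spacing) + 10_000
    meta = pd.DataFrame(
        {
            "chrom": [chrom] * n_snps,
            "pos": pos.astype(int),
            "snp_id": [f"fx{j + 1}" for j in range(n_snps)],
            "ref": ["A"] * n_snps,
            "alt": ["G"] * n_snps,
        }
    )
    return PhasedPanel(hap, meta)


def panel_window_scenario(
    panel: PhasedPanel,
    window_size: int = 100,
    causal_r2: float = 0.0,
    sigma2_H: float = 0.006,
    tau_prime: float = 0.0,
    mask_causal: bool = False,
    maf_min: float = 0.01,
    prune_r2: float = 0.80,
    n: int = 5000,
    n_replicates: int = 1000,
    models: tuple[str, ...] = ("additive", "vc"),
    alpha: float = 1e-4,
    seed: int = 0,
) -> ScenarioConfig:
    """A window of panel SNPs with two designated causal SNPs.

    SNPs below ``maf_min`` are excluded and the window greedily pruned so no
    pair exceeds ``prune_r2``; the first ``window_size`` surviving SNPs form
    the region.  The causal pair is the pair whose panel r2 is closest to
    ``causal_r2``; its haplotype effects come from the non-additivity path at
    the requested tau' and sigma2_H.  With ``mask_causal`` the two causal
    SNPs are hidden from fitting (nuisance-only testing).
    """
    maf = panel.maf()
    keep = np.where(maf > maf_min)[0]
    sub = panel.subset(keep)
    # greedy prune on pairwise r2
    r2 = sub.r2_matrix()
    kept: list[int] = []
    for j in range(sub.m):
        if all(r2[j, i] <= prune_r2 for i in kept):
            kept.append(j)
    if len(kept) < window_size:
        raise ValueError(
            f"panel too small after filters: {len(kept)} SNPs < window {window_size}"
        )
    win = sub.subset(np.array(kept[:window_size]))

    r2w = win.r2_matrix()
    iu = np.triu_indices(window_size, k=1)
    best = int(np.argmin(np.abs(r2w[iu] - causal_r2)))
    ca, cb = int(iu[0][best]), int(iu[1][best])

    # causal 2-SNP subsystem from panel frequencies
    pair = win.haplotypes[:, [ca, cb]]
    uniq, counts = np.unique(pair, axis=0, return_counts=True)
    H2 = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
    pi2 = np.zeros(4)
    for row, c in zip(uniq, counts):
        pi2[int(row[0]) * 2 + int(row[1])] = c
    pi2 = pi2 / pi2.sum()
    present = pi2 > 0
    base = HaplotypeSystem(H2[present], pi2[present])
    beta2 = effect_path(base, sigma2_H, tau_prime)
    lookup = {tuple(h): b for h, b in zip(base.H, beta2)}
    beta_by_hap = np.array([lookup[tuple(r)] for r in pair])

    system = win.as_system(beta_by_hap)
    # causal SNP columns within the window, for optional masking
    mask = (ca, cb) if mask_causal else ()
    return ScenarioConfig(
        system=system,
        n=n,
        n_replicates=n_replicates,
        models=models,
        alpha=alpha,
        seed=seed,
        mask=mask,
        label=f"panel_window tau'={tau_prime} causal=({ca},{cb}) masked={mask_causal}",
    )


# ---------------------------------------------------------------------------
# the replicate loop
# ---------------------------------------------------------------------------


def run_scenario(config: ScenarioConfig, progress: bool = False) -> ScenarioResult:
    """Monte-Carlo estimate of per-model variance estimates and power.

    Per replicate: draw diplotypes under HWE, generate the phenotype, fit
    each requested model on the visible SNPs, and record raw/adjusted
    variance estimates and p-values.  Replicates use independent RNG streams
    spawned from the master seed, so results do not depend on execution
    order.  Model failures are recorded per replicate, not fatal.
    """
    system = config.system
    beta = system.require_beta()
    visible = config.visible_snps
    meta = default_snp_meta(system.m)
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_replicates)

    est_raw: dict[str, list[float]] = {mdl: [] for mdl in config.models}
    est_adj: dict[str, list[float]] = {mdl: [] for mdl in config.models}
    pvals: dict[str, list[float]] = {mdl: [] for mdl in config.models}
    failures: dict[str, int] = {mdl: 0 for mdl in config.models}

    Hv = system.H[:, visible].astype(np.int16)
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        idx = _draw_hap_indices(system, config.n, rng)
        G = Hv[idx[:, 0]] + Hv[idx[:, 1]]
        y = beta[idx[:, 0]] + beta[idx[:, 1]] + rng.standard_normal(config.n)
        # drop SNPs monomorphic in this sample (can happen with rare alleles)
        poly = G.std(axis=0) > 0
        Gd = GenotypeDataset(
            G[:, poly], meta.iloc[visible[poly]].reset_index(drop=True)
        )
        for mdl in config.models:
            try:
                fit = fit_model(mdl, Gd, y)
            except Exception:
                failures[mdl] += 1
                continue
            if isinstance(fit, dict):
                est_raw[mdl].append(fit["sigma2_raw"])
                est_adj[mdl].append(fit["sigma2_adj"])
                pvals[mdl].append(fit["p"])
            else:
                est_raw[mdl].append(fit.sigma2_raw)
                est_adj[mdl].append(fit.sigma2_adj)
                pvals[mdl].append(fit.p_value)

    rows = []
    for mdl in config.models:
        raw = np.asarray(est_raw[mdl])
        adj = np.asarray(est_adj[mdl])
        p = np.asarray(pvals[mdl])
        n_ok = raw.size
        rows.append(
            {
                "model": mdl,
                "mean_sigma2_raw": raw.mean() if n_ok else np.nan,
                "mean_sigma2_adj": adj.mean() if n_ok else np.nan,
                "se_sigma2_raw": raw.std(ddof=1) / np.sqrt(n_ok) if n_ok > 1 else np.nan,
                "se_sigma2_adj": adj.std(ddof=1) / np.sqrt(n_ok) if n_ok > 1 else np.nan,
                "power": float((p < config.alpha).mean()) if n_ok else np.nan,
                "n_replicates": n_ok,
                "n_failures": failures[mdl],
            }
        )
    return ScenarioResult(
        table=pd.DataFrame(rows),
        config=config,
        n_replicates_done=config.n_replicates,
        failures=failures,
    )
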