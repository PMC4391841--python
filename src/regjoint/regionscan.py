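"""Empirical sliding-window pipeline.

Phenotype preparation (log transform, percentile trimming, covariate and
candidate-SNP adjustment), greedy windowed LD pruning, fixed-size sliding
window scans with the additive multivariate model, and candidate-centered
scans slid away one SNP at a time.

Windows are defined per chromosome on the pruned SNP list: size-``s`` windows
starting every ``step`` SNPs, with trailing partial windows dropped, so the
per-chromosome count is floor((m_c - size)/step) + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc_models import design_additive, fit_linear
from .hapcore import GenotypeDataset, PhenotypeVector

__all__ = [
    "Window",
    "WindowResult",
    "prepare_phenotype",
    "ld_prune",
    "make_windows",
    "scan_windows",
    "centered_scan",
]


@dataclass(frozen=True)
class Window:
    """A contiguous run of SNPs on one chromosome.

    ``start_index``/``end_index`` are 0-based half-open positions in the
    chromosome-sorted (pruned) SNP list handed to the scan; bp spans are
    inclusive 1-based positions of the first and last SNP.
    """

    chrom: str
    start_index: int
    end_index: int
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")

    @property
    def n_snps(self) -> int:
        return self.end_index - self.start_index

    def contains_bp(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.end_bp


@dataclass
class WindowResult:
    window: Window
    p_value: float
    r2_raw: float
    r2_adj: float
    sigma2_raw: float
    sigma2_adj: float
    df1: int
    n_dropped: int
    coef_table: pd.DataFrame | None = None


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    C = np.column_stack([np.ones(y.size), covariates])
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ coef


def prepare_phenotype(
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    candidate_genotypes: np.ndarray | None = None,
    log2_transform: bool = False,
    trim_percentiles: tuple[float, float] | None = (1.0, 99.0),
    winsorize: bool = False,
) -> tuple[PhenotypeVector, np.ndarray]:
    """Standard trait preparation for the regional scan.

    Optional log2 transform; removal (or clamping, with ``winsorize=True``)
    of values outside the given percentile range; joint OLS residualization
    on all covariates and candidate-SNP dosages simultaneously; final
    standardization to mean 0, variance 1.

    Returns the prepared phenotype and the integer index of retained samples
    (trimming removes samples, so genotypes must be subset with it).
    """
    y = np.asarray(trait, dtype=float).ravel()
    if log2_transform:
        if (y <= 0).any():
            raise ValueError("log2 transform requires strictly positive trait values")
        y = np.log2(y)
    keep = np.arange(y.size)
    if trim_percentiles is not None:
        lo, hi = np.percentile(y, trim_percentiles)
        if winsorize:
            y = np.clip(y, lo, hi)
        else:
            keep = np.where((y >= lo) & (y <= hi))[0]
            y = y[keep]
            if y.size == 0:
                raise ValueError("all samples trimmed")
    adjusters = []
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        C = C.reshape(-1, 1) if C.ndim == 1 else C
        adjusters.append(C[keep])
    if candidate_genotypes is not None:
        X = np.asarray(candidate_genotypes, dtype=float)
        X = X.reshape(-1, 1) if X.ndim == 1 else X
        adjusters.append(X[keep])
    if adjusters:
        A = np.hstack(adjusters)
        sd = A.std(axis=0)
        if (sd == 0).any():
            import warnings

            warnings.warn("constant covariate column(s) ignored in adjustment")
            A = A[:, sd > 0]
        if A.shape[1]:
            y = _residualize(y, A)
    if y.std() == 0:
        raise ValueError("phenotype has zero variance after preparation")
    return PhenotypeVector((y - y.mean()) / y.std(), standardized=True), keep


def ld_prune(
    G: GenotypeDataset, window: int = 100, step: int = 50, r2_threshold: float = 0.80
) -> np.ndarray:
    """Greedy windowed LD pruning; returns indices of retained SNPs.

    Within each sliding window of the currently-kept SNPs, pairs exceeding
    the r2 threshold are resolved by removing the later-position SNP (the
    earlier SNP is kept on ties), until no retained pair within any window
    exceeds the threshold.  Operates per chromosome on position-sorted SNPs.
    """
    meta = G.snp_meta
    if not (
        meta.sort_values(["chrom", "pos"], kind="stable").index == meta.index
    ).all():
        raise ValueError("snp_meta must be sorted by (chrom, pos)")
    X = G.imputed()
    keep_mask = np.ones(G.m, dtype=bool)
    for chrom in meta["chrom"].unique():
        cidx = np.where(meta["chrom"].to_numpy() == chrom)[0]
        start = 0
        while True:
            kept = cidx[keep_mask[cidx]]
            if start >= kept.size:
                break
            block = kept[start : start + window]
            if block.size >= 2:
                Xb = X[:, block]
                sd = Xb.std(axis=0)
                ok = sd > 0
                r = np.zeros((block.size, block.size))
                if ok.sum() >= 2:
                    sub = np.corrcoef(Xb[:, ok], rowvar=False) ** 2
                    r[np.ix_(ok, ok)] = sub
                removed = False
                for a in range(block.size):
                    if not keep_mask[block[a]]:
                        continue
                    for b in range(a + 1, block.size):
                        if keep_mask[block[b]] and r[a, b] > r2_threshold:
                            keep_mask[block[b]] = False
                            removed = True
                if removed:
                    continue  # re-window over the surviving SNPs
            start += step
    return np.where(keep_mask)[0]


def make_windows(snp_meta: pd.DataFrame, size: int, step: int) -> list[Window]:
    """Fixed-size sliding windows per chromosome; partial windows dropped."""
    if size < 1 or not 1 <= step <= size:
        raise ValueError("need size >= 1 and 1 <= step <= size")
    windows: list[Window] = []
    pos = snp_meta["pos"].to_numpy()
    chroms = snp_meta["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cidx = np.where(chroms == chrom)[0]
        if cidx.size < size:
            import warnings

            warnings.warn(f"chromosome {chrom}: fewer than {size} SNPs, no windows")
            continue
        for s in range(0, cidx.size - size + 1, step):
            lo, hi = cidx[s], cidx[s + size - 1]
            windows.append(
                Window(
                    chrom=str(chrom),
                    start_index=s,
                    end_index=s + size,
                    start_bp=int(pos[lo]),
                    end_bp=int(pos[hi]),
                )
            )
    return windows


def _window_global_index(win: Window, snp_meta: pd.DataFrame) -> np.ndarray:
    cidx = np.where(snp_meta["chrom"].to_numpy() == win.chrom)[0]
    return cidx[win.start_index : win.end_index]


def scan_windows(
    G: GenotypeDataset,
    y: PhenotypeVector,
    windows: list[Window],
    keep_coefs: bool = False,
) -> list[WindowResult]:
    """Joint additive-model F-test of every window.

    Returns one WindowResult per window with the joint p-value, raw and
    adjusted variance estimates, and (optionally) the per-SNP multivariate
    coefficient table.
    """
    results: list[WindowResult] = []
    for win in windows:
        idx = _window_global_index(win, G.snp_meta)
        sub = G.subset_snps(idx)
        try:
            fit = fit_linear(design_additive(sub), y)
        except ValueError:
            results.append(
                WindowResult(win, np.nan, np.nan, np.nan, np.nan, np.nan, 0, win.n_snps)
            )
            continue
        results.append(
            WindowResult(
                window=win,
                p_value=fit.p_value,
                r2_raw=fit.r2_raw,
                r2_adj=fit.r2_adj,
                sigma2_raw=fit.sigma2_raw,
                sigma2_adj=fit.sigma2_adj,
                df1=fit.df1,
                n_dropped=len(fit.dropped_columns),
                coef_table=fit.coef_table if keep_coefs else None,
            )
        )
    return results


def results_table(results: list[WindowResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.window.chrom for r in results],
            "start_bp": [r.window.start_bp for r in results],
            "end_bp": [r.window.end_bp for r in results],
            "n_snps": [r.window.n_snps for r in results],
            "p": [r.p_value for r in results],
            "r2_raw": [r.r2_raw for r in results],
            "r2_adj": [r.r2_adj for r in results],
            "df1": [r.df1 for r in results],
        }
    )


@dataclass
class CenteredScan:
    """Per-offset results of windows slid away from candidate SNPs."""

    per_offset: dict[int, list[WindowResult]]
    center_distance_kb: dict[int, float]  # median |window center - candidate| in Kb
    boundary_distance_kb: dict[int, float]  # median min boundary distance in Kb
    truncated: dict[int, int] = field(default_factory=dict)  # offset -> dropped windows


def centered_scan(
    G: GenotypeDataset,
    y: PhenotypeVector,
    candidate_index: np.ndarray,
    size: int = 100,
    max_offset: int = 100,
) -> CenteredScan:
    """Windows centered on candidate SNPs and slid away one SNP at a time.

    For each offset d = 0..max_offset and each candidate SNP, two windows of
    ``size`` SNPs are placed with centers d SNPs to the left and right of the
    candidate (one window at d = 0).  Windows crossing the chromosome edge
    are dropped and counted in ``truncated``.  Genomic-distance summaries are
    the median |center - candidate| and the median minimal window-boundary
    distance (0 when the candidate lies inside the span), in Kb.
    """
    meta = G.snp_meta
    pos = meta["pos"].to_numpy()
    chroms = meta["chrom"].to_numpy()
    half = size // 2
    per_offset: dict[int, list[WindowResult]] = {}
    cdist: dict[int, float] = {}
    bdist: dict[int, float] = {}
    truncated: dict[int, int] = {}

    chrom_ranges = {
        c: (np.where(chroms == c)[0].min(), np.where(chroms == c)[0].max())
        for c in pd.unique(chroms)
    }

    for d in range(0, max_offset + 1):
        wins: list[Window] = []
        centers: list[tuple[int, int]] = []  # (center global idx, candidate idx)
        dropped = 0
        for c in np.asarray(candidate_index, dtype=int):
            lo_c, hi_c = chrom_ranges[chroms[c]]
            for sign in ((0,) if d == 0 else (-1, 1)):
                center = c + sign * d
                start = center - half
                end = start + size
                if start < lo_c or end - 1 > hi_c:
                    dropped += 1
                    continue
                local_start = start - lo_c
                wins.append(
                    Window(
                        chrom=str(chroms[c]),
                        start_index=local_start,
                        end_index=local_start + size,
                        start_bp=int(pos[start]),
                        end_bp=int(pos[end - 1]),
                    )
                )
                centers.append((center, c))
        res = scan_windows(G, y, wins)
        per_offset[d] = res
        if res:
            cd, bd = [], []
            for (center, cand), r in zip(centers, res):
                cd.append(abs(pos[center] - pos[cand]) / 1000.0)
                w = r.window
                if w.start_bp <= pos[cand] <= w.end_bp:
                    bd.append(0.0)
                else:
                    bd.append(
                        min(abs(w.start_bp - pos[cand]), abs(w.end_bp - pos[cand]))
                        / 1000.0
                    )
            cdist[d] = float(np.median(cd))
            bdist[d] = float(np.median(bd))
        truncated[d] = dropped
    return CenteredScan(per_offset, cdist, bdist, truncated)
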