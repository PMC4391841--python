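"""Enrichment of candidate loci among window association results.

Windows encompassing a known candidate locus are treated as true positives
and all other windows as true negatives; ranking windows by p-value (smaller
= more positive) gives a ROC curve whose AUC measures how much candidate
windows stand out.  The AUC p-value is the one-sided Mann-Whitney test
(enrichment direction, AUC > 0.5).  Threshold-based enrichment is summarized
by the odds ratio of a 2x2 table of {p < threshold} x {contains candidate}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .regionscan import CenteredScan, WindowResult

__all__ = ["EnrichmentResult", "roc_auc", "enrichment_or", "offset_enrichment",
           "label_windows"]


@dataclass
class EnrichmentResult:
    auc: float | None
    auc_p: float | None
    threshold: float | None
    a: int  # significant & candidate
    b: int  # significant & not
    c: int  # not significant & candidate
    d: int  # neither
    odds_ratio: float | None
    or_ci_low: float | None
    or_ci_high: float | None
    or_p: float | None
    haldane_corrected: bool = False


def roc_auc(p_values: np.ndarray, positive: np.ndarray) -> tuple[float, float]:
    """AUC of candidate windows vs the rest, with one-sided Mann-Whitney p.

    Smaller p-values rank as "more positive"; ties are handled by midranks,
    and the normal approximation uses the tie-corrected variance.
    """
    p = np.asarray(p_values, dtype=float)
    lab = np.asarray(positive, dtype=bool)
    if p.shape != lab.shape:
        raise ValueError("p_values and labels must align")
    n1, n0 = int(lab.sum()), int((~lab).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one positive and one negative window")
    ranks = stats.rankdata(-p)  # larger score = smaller p
    u = ranks[lab].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)

    n = n1 + n0
    _, tie_counts = np.unique(p, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n0 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return float(auc), 1.0
    z = (u - n1 * n0 / 2.0) / np.sqrt(var_u)
    p_one_sided = float(stats.norm.sf(z))
    return float(auc), p_one_sided


def enrichment_or(
    p_values: np.ndarray, positive: np.ndarray, threshold: float
) -> EnrichmentResult:
    """Odds ratio of containing a candidate given window p < threshold.

    CI by the Woolf log-OR normal method, with the Haldane 0.5 correction
    applied (and flagged) when any cell is empty; p by Fisher's exact test
    on the uncorrected table.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    p = np.asarray(p_values, dtype=float)
    lab = np.asarray(positive, dtype=bool)
    sig = p < threshold
    a = int(np.sum(sig & lab))
    b = int(np.sum(sig & ~lab))
    c = int(np.sum(~sig & lab))
    d = int(np.sum(~sig & ~lab))

    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    orr = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci = (float(np.exp(np.log(orr) - 1.96 * se)), float(np.exp(np.log(orr) + 1.96 * se)))
    _, fisher_p = stats.fisher_exact([[a, b], [c, d]])
    auc, auc_p = (None, None)
    try:
        auc, auc_p = roc_auc(p, lab)
    except ValueError:
        pass
    return EnrichmentResult(
        auc=auc,
        auc_p=auc_p,
        threshold=threshold,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=float(orr),
        or_ci_low=ci[0],
        or_ci_high=ci[1],
        or_p=float(fisher_p),
        haldane_corrected=corrected,
    )


def label_windows(results: list[WindowResult], candidates) -> np.ndarray:
    """True for windows whose bp span contains >= 1 candidate (chrom, pos)."""
    out = np.zeros(len(results), dtype=bool)
    for i, r in enumerate(results):
        out[i] = any(r.window.contains_bp(str(ch), int(pos)) for ch, pos in candidates)
    return out


def offset_enrichment(
    scan: CenteredScan, all_p_values: np.ndarray, alpha: float = 0.05
):
    """Per-offset AUC of candidate-centered windows vs the full window set.

    For each offset d, the windows slid d SNPs away from the candidates are
    the positives and all scan windows the negatives.  Returns a dict with
    per-offset (auc, auc_p), the largest offset such that every offset up to
    it is significant at ``alpha`` (the contiguous significant range), and
    that offset's genomic-distance summaries in Kb.
    """
    all_p = np.asarray(all_p_values, dtype=float)
    per = {}
    for d, results in sorted(scan.per_offset.items()):
        pos_p = np.array([r.p_value for r in results if np.isfinite(r.p_value)])
        if pos_p.size == 0:
            per[d] = (np.nan, np.nan)
            continue
        pooled = np.concatenate([pos_p, all_p])
        labels = np.concatenate(
            [np.ones(pos_p.size, bool), np.zeros(all_p.size, bool)]
        )
        per[d] = roc_auc(pooled, labels)

    max_sig = -1
    for d in sorted(per):
        auc_p = per[d][1]
        if np.isfinite(auc_p) and auc_p < alpha:
            max_sig = d
        else:
            break
    out = {
        "per_offset": per,
        "max_significant_offset": max_sig,
        "center_distance_kb": scan.center_distance_kb.get(max_sig, np.nan),
        "boundary_distance_kb": scan.boundary_distance_kb.get(max_sig, np.nan),
    }
    return out
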