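"""Differential NFR occupancy between conditions.

Per gene, the reference/comparison ratio of normalized NFR reads calls the
promoter "activated" (ratio > 1, NFR emptier in the comparison) or
"repressed" (ratio < 1); a scaled-difference chi-square test on the raw
counts against the per-condition library totals gives a p-value, adjusted
to q-values by Benjamini-Hochberg.  The significance filter keeps genes
with |log2 ratio| above a fold cutoff and q below a threshold.

Also here: decile occupancy classes (top/bottom 10% of NFR occupancy),
Pearson correlation reports and Wilcoxon rank-sum comparisons used for the
class- and TATA-stratified summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ACTIVATED, REPRESSED, NS = "activated", "repressed", "NS"


def nfr_ratio(ref_count: float, cmp_count: float, pseudocount: float = 0.5):
    """(ratio, log2_ratio, direction) with a pseudocount guarding zeros.

    direction: "activated" if ratio > 1, "repressed" if < 1, "none" if = 1.
    """
    if ref_count < 0 or cmp_count < 0:
        raise ValueError("counts must be >= 0")
    ratio = (ref_count + pseudocount) / (cmp_count + pseudocount)
    direction = ACTIVATED if ratio > 1 else REPRESSED if ratio < 1 else "none"
    return ratio, float(np.log2(ratio)), direction


def scaled_chisq(ref_count: float, ref_total: float, cmp_count: float, cmp_total: float):
    """Chi-square (1 df, no Yates correction) on the 2x2 table

        [[ref_count, ref_total - ref_count],
         [cmp_count, cmp_total - cmp_count]]

    so library-size scaling enters through the per-condition totals.
    Returns (chi2, p); a degenerate margin (both counts 0, or both equal to
    their totals) gives (0.0, 1.0).
    """
    if ref_total <= 0 or cmp_total <= 0:
        raise ValueError("totals must be > 0")
    if ref_count > ref_total or cmp_count > cmp_total:
        raise ValueError("count exceeds its total")
    table = np.array(
        [[ref_count, ref_total - ref_count], [cmp_count, cmp_total - cmp_count]], dtype=float
    )
    if (table.sum(axis=0) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j>=i} p_(j) * m / j over the ascending-sorted p, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-d sequence")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def diff_nfr_table(
    arch: pd.DataFrame,
    ref: str,
    cmp: str,
    totals: dict[str, int],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene differential table for one condition pair.

    ``arch`` is the gene-architecture table (``<cond>_NFR`` normalized and
    ``<cond>_NFR_raw`` raw count columns); ``totals`` maps condition to its
    genome-wide fragment count (the chi-square scaling totals).  Genes
    without an NFR (missing flank) are dropped.  One BH family per call.
    """
    need = [f"{ref}_NFR", f"{cmp}_NFR", f"{ref}_NFR_raw", f"{cmp}_NFR_raw"]
    missing = [c for c in need if c not in arch.columns]
    if missing:
        raise ValueError(f"architecture table missing columns: {missing}")
    sub = arch.dropna(subset=need).copy()
    if sub.empty:
        raise ValueError("no genes with defined NFRs")

    ratios = [nfr_ratio(a, b, pseudocount) for a, b in zip(sub[f"{ref}_NFR"], sub[f"{cmp}_NFR"])]
    chisq = [
        scaled_chisq(a, totals[ref], b, totals[cmp])
        for a, b in zip(sub[f"{ref}_NFR_raw"], sub[f"{cmp}_NFR_raw"])
    ]
    out = pd.DataFrame(
        dict(
            gene_id=sub["gene_id"].to_numpy(),
            ref=sub[f"{ref}_NFR"].to_numpy(),
            cmp=sub[f"{cmp}_NFR"].to_numpy(),
            ratio=[r[0] for r in ratios],
            log2_ratio=[r[1] for r in ratios],
            chi2=[c[0] for c in chisq],
            p=[c[1] for c in chisq],
        )
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    if "tata" in sub.columns:
        out["tata"] = sub["tata"].to_numpy()
    return out


def significant_calls(
    results: pd.DataFrame,
    fold_log2: float = 1.0,
    q_max: float = 1.0e-30,
) -> pd.DataFrame:
    """Annotate calls and return the significant subset.

    Keeps genes with |log2_ratio| > fold_log2 AND q < q_max; the call sign
    follows the ratio direction.  Adds a ``call`` column to ``results``
    in place (activated / repressed / NS).
    """
    keep = (results["log2_ratio"].abs() > fold_log2) & (results["q"] < q_max)
    results["call"] = NS
    results.loc[keep & (results["ratio"] > 1), "call"] = ACTIVATED
    results.loc[keep & (results["ratio"] < 1), "call"] = REPRESSED
    return results[results["call"] != NS].copy()


def decile_classes(nfr_occupancy: pd.Series, decile: float = 0.1) -> pd.DataFrame:
    """Top/bottom decile occupancy classes over per-gene NFR occupancy.

    ``nfr_occupancy`` is indexed by gene id.  Returns (gene_id, class) with
    class in {high, low, mid}; high = the ceil(decile*n) largest values,
    low = the same number of smallest, ties broken by gene id so runs are
    reproducible.
    """
    n = len(nfr_occupancy)
    if n < 10:
        raise ValueError(f"need >= 10 genes for decile classes, got {n}")
    k = int(np.ceil(decile * n))
    df = pd.DataFrame({"gene_id": nfr_occupancy.index.astype(str), "value": nfr_occupancy.to_numpy()})
    if df["value"].nunique() == 1:
        log.warning("all NFR occupancy values equal; decile classes set by gene id order")
    lo = df.sort_values(["value", "gene_id"], kind="mergesort").head(k)
    hi = df.drop(lo.index).sort_values(["value", "gene_id"], ascending=[False, True],
                                       kind="mergesort").head(k)
    df["class"] = "mid"
    df.loc[lo.index, "class"] = "low"
    df.loc[hi.index, "class"] = "high"
    return df[["gene_id", "class"]].reset_index(drop=True)


def correlation_report(x, y):
    """Pearson (r, r_squared, n) over complete pairs; raises on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~ok).sum())
    if dropped:
        log.info("correlation: dropped %d incomplete pairs", dropped)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r, int(x.size)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def wilcoxon_compare(group_a, group_b, exact_max_n: int = 12):
    """Two-sided Wilcoxon rank-sum p-value with star coding.

    Exact enumeration when both groups have <= ``exact_max_n`` values and
    no cross-group ties; otherwise the normal approximation with tie
    correction (no continuity correction, so identical groups give p = 1).
    Returns (p, stars).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0, _stars(1.0)  # all values equal: no evidence of shift
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= exact_max_n and b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    p = float(min(1.0, res.pvalue))
    return p, _stars(p)


def diff_summary(results: pd.DataFrame) -> dict:
    """Counts of activated / repressed / NS calls, plus TATA breakdown."""
    counts = results["call"].value_counts().to_dict() if "call" in results else {}
    out = {
        "n_genes": int(len(results)),
        "n_activated": int(counts.get(ACTIVATED, 0)),
        "n_repressed": int(counts.get(REPRESSED, 0)),
        "n_ns": int(counts.get(NS, 0)),
    }
    if "tata" in results.columns and "call" in results.columns:
        tab = pd.crosstab(results["call"], results["tata"])
        out["call_by_tata"] = {str(k): {str(c): int(v) for c, v in row.items()}
                               for k, row in tab.iterrows()}
    return out
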