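"""qRT-PCR fold changes by the 2^-ddCt method and concordance with
nucleosome-based activation/repression calls.

Replicate Ct values are averaged on the Ct scale; dCt = mean Ct(gene) -
mean Ct(reference gene, default ACT1) within each condition; ddCt =
dCt(condition) - dCt(control); fold = 2^-ddCt.  Adding a constant to every
Ct of one condition cancels in dCt, so folds are invariant to per-run
baseline shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_REF_GENE = "ACT1"


@dataclass(frozen=True)
class FoldChange:
    gene: str
    condition: str
    control: str
    ddct: float
    fold: float

    @property
    def log2_fold(self) -> float:
        return -self.ddct


def load_ct_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene, condition, ct_rep1..ct_repN (>=1 replicate).

    Gene names are canonicalized case-insensitively (upper-cased); the alias
    mapping is logged when any name changes.
    """
    df = pd.read_csv(path, sep="\t")
    rep_cols = [c for c in df.columns if c.startswith("ct_rep")]
    if "gene" not in df.columns or "condition" not in df.columns or not rep_cols:
        raise ValueError(f"{path}: expected columns gene, condition, ct_rep1..N")
    cts = df[rep_cols].to_numpy(dtype=float)
    finite = cts[np.isfinite(cts)]
    if finite.size == 0 or (finite <= 0).any() or (finite >= 45).any():
        raise ValueError(f"{path}: Ct values must lie in (0, 45)")
    canonical = df["gene"].astype(str).str.upper()
    aliases = {a: b for a, b in zip(df["gene"], canonical) if a != b}
    if aliases:
        log.info("canonicalized gene names: %s", aliases)
    out = df.copy()
    out["gene"] = canonical
    return out


def _mean_ct(ct: pd.DataFrame, gene: str, condition: str) -> float:
    rep_cols = [c for c in ct.columns if c.startswith("ct_rep")]
    rows = ct[(ct["gene"].str.upper() == gene.upper()) & (ct["condition"] == condition)]
    if rows.empty:
        raise KeyError(f"no Ct measurements for {gene!r} in condition {condition!r}")
    return float(np.nanmean(rows[rep_cols].to_numpy(dtype=float)))


def ddct_fold(
    ct: pd.DataFrame,
    gene: str,
    condition: str,
    control_condition: str,
    ref_gene: str = DEFAULT_REF_GENE,
) -> FoldChange:
    """2^-ddCt fold change of ``gene`` in ``condition`` vs ``control_condition``."""
    for cond in (condition, control_condition):
        try:
            _mean_ct(ct, ref_gene, cond)
        except KeyError:
            raise ValueError(
                f"reference gene {ref_gene!r} not measured in condition {cond!r}"
            ) from None
    dct_cond = _mean_ct(ct, gene, condition) - _mean_ct(ct, ref_gene, condition)
    dct_ctrl = _mean_ct(ct, gene, control_condition) - _mean_ct(ct, ref_gene, control_condition)
    ddct = dct_cond - dct_ctrl
    return FoldChange(gene.upper(), condition, control_condition, float(ddct), float(2.0 ** -ddct))


def fold_change_table(
    ct: pd.DataFrame,
    control_condition: str,
    conditions: list[str] | None = None,
    ref_gene: str = DEFAULT_REF_GENE,
) -> pd.DataFrame:
    """Fold changes for every (gene, non-control condition) in the table."""
    if conditions is None:
        conditions = [c for c in ct["condition"].unique() if c != control_condition]
    genes = [g for g in ct["gene"].unique() if g != ref_gene.upper()]
    rows = []
    for cond in conditions:
        for gene in genes:
            try:
                fc = ddct_fold(ct, gene, cond, control_condition, ref_gene)
            except KeyError:
                continue
            rows.append(dict(gene=fc.gene, condition=cond, control=control_condition,
                             ddct=fc.ddct, log2_fold=fc.log2_fold, fold=fc.fold))
    return pd.DataFrame(rows)


def concordance(fold_changes: pd.DataFrame, diff_calls: pd.DataFrame) -> dict:
    """Cross-tabulate nucleosome-profile calls against expression direction.

    ``fold_changes``: gene, fold (one comparison).  ``diff_calls``: gene_id,
    call in {activated, repressed}.  Fold changes exactly 1 are boundary
    cases, counted separately rather than forced up or down.
    Returns the 2x2 table and, per call class, the fraction up-regulated;
    ``concordance_activated`` is that fraction among activated genes.
    """
    calls = diff_calls[["gene_id", "call"]].copy()
    calls["gene_id"] = calls["gene_id"].astype(str).str.upper()
    merged = calls.merge(
        fold_changes[["gene", "fold"]], left_on="gene_id", right_on="gene", how="inner"
    )
    if merged.empty:
        raise ValueError("no genes shared between fold changes and differential calls")
    out: dict = {"table": {}, "n_boundary": int((merged["fold"] == 1).sum())}
    for call in ("activated", "repressed"):
        sub = merged[merged["call"] == call]
        n_up = int((sub["fold"] > 1).sum())
        n_down = int((sub["fold"] < 1).sum())
        out["table"][call] = {"up": n_up, "down_or_equal": int(len(sub)) - n_up}
        out[f"n_{call}"] = int(len(sub))
        out[f"fraction_up_{call}"] = n_up / len(sub) if len(sub) else float("nan")
    out["concordance_activated"] = out["fraction_up_activated"]
    return out
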