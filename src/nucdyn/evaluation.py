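"""Benchmarking helpers: compare pipeline calls against simulation truth."""

from __future__ import annotations

import numpy as np
import pandas as pd


def dyad_recovery(truth_dyads, called_dyads, tol_bp: int = 20) -> float:
    """Fraction of truth dyads with a call within ``tol_bp`` (0 = exact)."""
    truth = np.asarray(truth_dyads, dtype=int)
    called = np.sort(np.asarray(called_dyads, dtype=int))
    if truth.size == 0:
        raise ValueError("no truth dyads")
    if called.size == 0:
        return 0.0
    idx = np.searchsorted(called, truth)
    lo = np.clip(idx - 1, 0, called.size - 1)
    hi = np.clip(idx, 0, called.size - 1)
    nearest = np.minimum(np.abs(truth - called[lo]), np.abs(truth - called[hi]))
    return float((nearest <= tol_bp).mean())


def nfr_overlap_fraction(truth_genes: pd.DataFrame, arch: pd.DataFrame) -> float:
    """Fraction of genes (with both flanks called) whose called NFR interval
    overlaps the truth NFR interval."""
    called = arch.dropna(subset=["nfr_start", "nfr_end"]).set_index("gene_id")
    truth = truth_genes.set_index("gene_id")
    if called.empty:
        raise ValueError("no genes with a called NFR")
    n_overlap = 0
    for gid in called.index:
        s1, e1 = called.loc[gid, "nfr_start"], called.loc[gid, "nfr_end"]
        s2, e2 = truth.loc[gid, "nfr_start"], truth.loc[gid, "nfr_end"]
        if min(e1, e2) > max(s1, s2):
            n_overlap += 1
    return n_overlap / len(called)
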