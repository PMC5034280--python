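"""Nucleosome calls, +1/-1 assignment, NFR delineation and region read counts.

A positioned nucleosome is a local maximum of the normalized occupancy
track, selected greedily in descending height with an exclusion radius
(default 120 bp, below the 147 bp core so closely packed nucleosomes remain
separable).  Its occupancy score is the log10 of the estimated read count
at the peak, with a +1 pseudocount.

Per gene (transcription-oriented): the +1 nucleosome is the call whose
147 bp footprint overlaps the TSS (nearest dyad wins; a rescue window
downstream of the TSS catches slightly shifted +1s), the -1 is the nearest
call strictly transcription-upstream of the +1, and the NFR is the gap
between the 3'-edge of the -1 footprint and the 5'-edge of the +1 footprint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .occupancy import FragmentSet, OccupancyTrack

log = logging.getLogger(__name__)

HALF_CORE = 73  # footprint = [dyad-73, dyad+74), 147 bp


@dataclass(frozen=True)
class NucleosomeCall:
    chrom: str
    dyad: int
    peak_height: float
    occupancy_score: float

    @property
    def footprint(self) -> tuple[int, int]:
        return self.dyad - HALF_CORE, self.dyad + HALF_CORE + 1


def occupancy_score(peak_height: float, total_fragments: int, genome_length: int) -> float:
    """log10(estimated reads at the peak + 1).

    ``peak_height`` is fold-over-genome-mean; multiplying by the mean
    fragment density and the 147 bp footprint recovers an estimated read
    count at the peak.
    """
    reads = peak_height * total_fragments / genome_length * 147.0
    return math.log10(reads + 1.0)


def call_nucleosomes(
    track: OccupancyTrack,
    min_spacing: int = 120,
    min_height: float = 0.25,
) -> pd.DataFrame:
    """Greedy peak calling on a normalized track.

    Returns a DataFrame (chrom, dyad, peak_height, occupancy_score) sorted
    by chromosome then dyad.  Candidates are strict local maxima of height
    >= min_height (plateaus contribute their leftmost point); selection is
    by descending height, ties to the leftmost coordinate, with calls
    closer than ``min_spacing`` to an accepted call discarded.
    """
    rows = []
    for chrom in sorted(track.data):
        v = track.data[chrom]
        peaks, props = find_peaks(v, height=min_height, plateau_size=1)
        pos = props["left_edges"]  # leftmost point of each (possibly flat) peak
        heights = v[pos]
        order = np.lexsort((pos, -heights))
        accepted: list[int] = []
        acc = np.empty(len(pos), dtype=int)
        n_acc = 0
        for i in order:
            p = pos[i]
            if n_acc and np.min(np.abs(acc[:n_acc] - p)) < min_spacing:
                continue
            acc[n_acc] = p
            n_acc += 1
            accepted.append(i)
        for i in sorted(accepted, key=lambda i: pos[i]):
            rows.append((chrom, int(pos[i]), float(heights[i])))
    df = pd.DataFrame(rows, columns=["chrom", "dyad", "peak_height"])
    df["occupancy_score"] = [
        occupancy_score(h, track.total_fragments, track.genome_length)
        for h in df["peak_height"]
    ]
    return df


def assign_flanking_nucleosomes(
    calls: pd.DataFrame,
    gene: pd.Series,
    rescue_bp: int = 200,
) -> tuple[pd.Series | None, pd.Series | None]:
    """Pick the +1 and -1 nucleosome calls for one gene.

    +1: the call whose footprint overlaps the TSS; among several, the dyad
    nearest the TSS (tie: the transcription-downstream one); failing that,
    the nearest call with dyad within ``rescue_bp`` transcription-downstream
    of the TSS; else None.  -1: the nearest call strictly
    transcription-upstream of the +1 dyad, else None.
    """
    sub = calls[calls["chrom"] == gene["chrom"]]
    if sub.empty:
        return None, None
    d = 1 if gene["strand"] == "+" else -1
    tss = int(gene["tss"])
    dyads = sub["dyad"].to_numpy()

    rel = d * (dyads - tss)  # transcription-oriented offset of each dyad
    overlapping = np.abs(dyads - tss) <= HALF_CORE
    plus1_idx = None
    if overlapping.any():
        cand = np.flatnonzero(overlapping)
        dist = np.abs(dyads[cand] - tss)
        # nearest dyad; tie broken toward transcription-downstream
        order = np.lexsort((-rel[cand], dist))
        plus1_idx = cand[order[0]]
    else:
        cand = np.flatnonzero((rel > 0) & (rel <= rescue_bp))
        if cand.size:
            plus1_idx = cand[np.argmin(rel[cand])]
    if plus1_idx is None:
        return None, None
    plus1 = sub.iloc[plus1_idx]

    up = np.flatnonzero(d * (dyads - plus1["dyad"]) < 0)
    minus1 = None
    if up.size:
        minus1 = sub.iloc[up[np.argmax(d * dyads[up])]]
    return plus1, minus1


def define_nfr(plus1_dyad: int, minus1_dyad: int, strand: str) -> tuple[int, int, int]:
    """Genomic NFR interval (start, end) and width between the two footprints.

    Transcription-oriented: from the 3'-edge of the -1 footprint to the
    5'-edge of the +1 footprint.  Touching or overlapping footprints give
    width 0 with an empty interval at the midpoint.
    """
    if strand == "+":
        start, end = minus1_dyad + HALF_CORE + 1, plus1_dyad - HALF_CORE
    else:
        start, end = plus1_dyad + HALF_CORE + 1, minus1_dyad - HALF_CORE
    if end <= start:
        mid = (start + end) // 2
        return mid, mid, 0
    return start, end, end - start


class _MidpointIndex:
    """Sorted fragment midpoints per chromosome for fast interval counts."""

    def __init__(self, frags: FragmentSet | pd.DataFrame):
        df = frags.records if isinstance(frags, FragmentSet) else frags
        mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
        self.by_chrom: dict[str, np.ndarray] = {}
        for chrom, grp in pd.DataFrame({"chrom": df["chrom"], "mid": mid}).groupby("chrom"):
            self.by_chrom[str(chrom)] = np.sort(grp["mid"].to_numpy())
        self.total = len(df)

    def count(self, chrom: str, start: int, end: int) -> int:
        if end <= start:
            return 0
        mids = self.by_chrom.get(chrom)
        if mids is None:
            return 0
        return int(np.searchsorted(mids, end, "left") - np.searchsorted(mids, start, "left"))


def count_region_reads(
    frags: FragmentSet | pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    total_fragments: int,
) -> float:
    """Fragments with midpoint in [start, end), scaled to reads per million."""
    if total_fragments <= 0:
        raise ValueError("total_fragments must be > 0")
    n = _MidpointIndex(frags).count(chrom, start, end)
    return n * 1e6 / total_fragments


def build_gene_architecture(
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    fragments_by_condition: dict[str, FragmentSet | pd.DataFrame],
    rescue_bp: int = 200,
) -> pd.DataFrame:
    """Per-gene +1/-1/NFR table with per-condition normalized read counts.

    ``calls`` is a single call set (typically from the reference condition's
    track) defining the geometry for all conditions; reads are then counted
    per condition in the fixed NFR and gene-body intervals.  Column names
    follow the <condition>_NFR / <condition>_gene convention; raw counts are
    kept in *_raw columns.  Genes missing a flank have NaN NFR fields.
    """
    indices = {cond: _MidpointIndex(f) for cond, f in fragments_by_condition.items()}
    rows = []
    n_missing = 0
    for _, gene in annotation.iterrows():
        plus1, minus1 = assign_flanking_nucleosomes(calls, gene, rescue_bp)
        row: dict = dict(
            gene_id=gene["gene_id"], chrom=gene["chrom"], strand=gene["strand"],
            tss=int(gene["tss"]), tata=int(gene["tata"]),
            plus1_dyad=np.nan, minus1_dyad=np.nan, plus1_score=np.nan,
            nfr_start=np.nan, nfr_end=np.nan, nfr_width=np.nan,
        )
        if plus1 is not None:
            row["plus1_dyad"] = int(plus1["dyad"])
            row["plus1_score"] = float(plus1["occupancy_score"])
        if plus1 is not None and minus1 is not None:
            row["minus1_dyad"] = int(minus1["dyad"])
            s, e, w = define_nfr(int(plus1["dyad"]), int(minus1["dyad"]), gene["strand"])
            row["nfr_start"], row["nfr_end"], row["nfr_width"] = s, e, w
        else:
            n_missing += 1
            log.info("gene %s: missing %s flank, excluded from NFR analyses",
                     gene["gene_id"], "+1" if plus1 is None else "-1")

        g_lo = int(min(gene["tss"], gene["stop_codon"]))
        g_hi = int(max(gene["tss"], gene["stop_codon"])) + 1  # [TSS, stop] inclusive
        for cond, idx in indices.items():
            if idx.total == 0:
                raise ValueError(f"condition {cond!r} has no fragments")
            scale = 1e6 / idx.total
            if plus1 is not None and minus1 is not None:
                n_nfr = idx.count(gene["chrom"], int(row["nfr_start"]), int(row["nfr_end"]))
            else:
                n_nfr = np.nan
            n_gene = idx.count(gene["chrom"], g_lo, g_hi)
            row[f"{cond}_NFR_raw"] = n_nfr
            row[f"{cond}_NFR"] = n_nfr * scale if n_nfr == n_nfr else np.nan
            row[f"{cond}_gene_raw"] = n_gene
            row[f"{cond}_gene"] = n_gene * scale
        rows.append(row)
    if n_missing:
        log.info("%d genes lacked a +1 or -1 call", n_missing)
    return pd.DataFrame(rows)


def calls_to_bed(calls: pd.DataFrame) -> pd.DataFrame:
    """Calls as BED6: footprint interval, score = occupancy_score*100 rounded."""
    return pd.DataFrame(
        dict(
            chrom=calls["chrom"],
            start=calls["dyad"] - HALF_CORE,
            end=calls["dyad"] + HALF_CORE + 1,
            name=[f"nuc{i:06d}" for i in range(len(calls))],
            score=(calls["occupancy_score"] * 100).round().astype(int),
            strand=".",
        )
    )
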