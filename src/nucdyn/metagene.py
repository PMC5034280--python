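"""Strand-aware metagene occupancy profiles around TSSs and stop codons.

The profile at offset k (k = -1000..+1000, transcription-oriented, offset 0
= the anchor base, both endpoints included: 2001 points) is the mean
normalized occupancy over genes at anchor+k for + strand genes and anchor-k
for - strand genes.  Genes whose window overhangs a chromosome end are
excluded and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occupancy import OccupancyTrack

log = logging.getLogger(__name__)

STRATA = ("all", "TATA1", "TATA0")


@dataclass
class MetageneProfile:
    anchor: str  # "tss" or "stop_codon"
    stratum: str  # "all", "TATA1", "TATA0"
    condition: str
    offsets: np.ndarray  # -flank..+flank
    mean_occupancy: np.ndarray
    n_genes: int
    n_excluded: int = 0

    def value_at(self, offset: int) -> float:
        return float(self.mean_occupancy[int(offset) + (len(self.offsets) - 1) // 2])


def _select_stratum(annotation: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return annotation
    if stratum == "TATA1":
        sub = annotation[annotation["tata"] == 1]
    elif stratum == "TATA0":
        sub = annotation[annotation["tata"] == 0]
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    if sub.empty:
        raise ValueError(f"stratum {stratum!r} contains no genes")
    return sub


def metagene(
    track: OccupancyTrack,
    annotation: pd.DataFrame,
    anchor: str = "tss",
    stratum: str = "all",
    flank: int = 1000,
) -> MetageneProfile:
    if anchor not in ("tss", "stop_codon"):
        raise ValueError(f"unknown anchor {anchor!r}")
    genes = _select_stratum(annotation, stratum)
    acc = np.zeros(2 * flank + 1)
    n_used = n_excluded = 0
    for row in genes.itertuples():
        a = int(getattr(row, anchor))
        v = track.data[row.chrom]
        if a - flank < 0 or a + flank + 1 > v.size:
            n_excluded += 1
            continue
        window = v[a - flank: a + flank + 1]
        if row.strand == "-":
            window = window[::-1]
        acc += window
        n_used += 1
    if n_excluded:
        log.info("metagene %s/%s: excluded %d genes with out-of-bounds windows",
                 anchor, stratum, n_excluded)
    if n_used == 0:
        raise ValueError(f"no usable genes for stratum {stratum!r}")
    return MetageneProfile(
        anchor=anchor, stratum=stratum, condition=track.condition,
        offsets=np.arange(-flank, flank + 1), mean_occupancy=acc / n_used,
        n_genes=n_used, n_excluded=n_excluded,
    )


def profiles_table(profiles: list[MetageneProfile]) -> pd.DataFrame:
    """Tidy table: anchor, stratum, condition, offset, mean_occupancy, n_genes."""
    if not profiles:
        raise ValueError("no profiles given")
    frames = [
        pd.DataFrame(
            dict(anchor=p.anchor, stratum=p.stratum, condition=p.condition,
                 offset=p.offsets, mean_occupancy=p.mean_occupancy, n_genes=p.n_genes)
        )
        for p in profiles
    ]
    return pd.concat(frames, ignore_index=True)


def profile_report(profiles: list[MetageneProfile], tsv_path, plot_path=None) -> pd.DataFrame:
    """Write the tidy TSV and, optionally, one line plot per anchor."""
    table = profiles_table(profiles)
    table.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        anchors = sorted({p.anchor for p in profiles})
        fig, axes = plt.subplots(1, len(anchors), figsize=(6 * len(anchors), 4), squeeze=False)
        for ax, anchor in zip(axes[0], anchors):
            for p in profiles:
                if p.anchor != anchor:
                    continue
                ax.plot(p.offsets, p.mean_occupancy,
                        label=f"{p.condition} {p.stratum} (n={p.n_genes})", lw=1)
            ax.set_xlabel(f"position relative to {anchor} (bp)")
            ax.set_ylabel("mean occupancy (fold over genome mean)")
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return table
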