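"""Per-bp nucleosome occupancy tracks from aligned MNase-seq fragments.

Each fragment contributes unit mass at its midpoint (the dyad estimate for
mononucleosomal fragments); the midpoint pileup is smoothed with a Gaussian
kernel (default sd 20 bp, truncated at 4 sd) and normalized so the
genome-wide mean is 1, making occupancy read as fold over genome average.
Kernel mass falling off a chromosome end is truncated, not reflected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

log = logging.getLogger(__name__)

GENOME_MEAN_ONE = "genome_mean_one"
PER_MILLION = "per_million"


@dataclass
class FragmentSet:
    """Aligned fragments for one condition (0-based, half-open)."""

    records: pd.DataFrame  # chrom, start, end, strand
    condition: str = ""
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def midpoints(self) -> pd.DataFrame:
        mid = (self.records["start"].to_numpy() + self.records["end"].to_numpy()) // 2
        return pd.DataFrame({"chrom": self.records["chrom"].to_numpy(), "mid": mid})


@dataclass
class OccupancyTrack:
    """Per-chromosome occupancy vectors plus provenance metadata."""

    data: dict[str, np.ndarray]
    condition: str = ""
    bandwidth_bp: float = 20.0
    normalization: str = "raw"
    total_fragments: int = 0

    @property
    def genome_length(self) -> int:
        return sum(len(v) for v in self.data.values())

    def genome_mean(self) -> float:
        total = sum(float(v.sum()) for v in self.data.values())
        return total / self.genome_length

    def copy(self) -> "OccupancyTrack":
        return OccupancyTrack(
            {c: v.copy() for c, v in self.data.items()},
            self.condition, self.bandwidth_bp, self.normalization, self.total_fragments,
        )

    def to_bedgraph(self, path, precision: int = 6) -> None:
        """Write as 4-column bedGraph, merging runs of equal value."""
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                v = np.round(self.data[chrom], precision)
                if v.size == 0:
                    continue
                change = np.flatnonzero(np.diff(v)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [v.size]])
                for s, e in zip(starts, ends):
                    if v[s] != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.{precision}g}\n")


def load_fragments_bed(
    path,
    chrom_sizes: dict[str, int],
    length_window: tuple[int, int] = (100, 200),
    condition: str = "",
) -> FragmentSet:
    """Read BED(3+) fragments, dropping lengths outside ``length_window``."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
            dtype={0: str, 1: np.int64, 2: np.int64},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed BED file {path}: {exc}") from exc
    if df.empty:
        log.warning("empty fragment file %s", path)
        df["strand"] = pd.Series(dtype=str)
        return FragmentSet(df, condition)
    unknown = set(df["chrom"]) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"unknown chromosome(s) in {path}: {sorted(unknown)}")
    bad = (df["start"] < 0) | (df["start"] >= df["end"])
    if bad.any():
        raise ValueError(f"invalid interval at line {int(np.flatnonzero(bad)[0]) + 1} of {path}")
    sizes = df["chrom"].map(chrom_sizes)
    if (df["end"] > sizes).any():
        i = int(np.flatnonzero(df["end"] > sizes)[0]) + 1
        raise ValueError(f"fragment beyond chromosome end at line {i} of {path}")
    lengths = df["end"] - df["start"]
    keep = (lengths >= length_window[0]) & (lengths <= length_window[1])
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropped %d fragments outside length window %s", n_dropped, length_window)
    df = df[keep].reset_index(drop=True)
    df["strand"] = "."
    return FragmentSet(df, condition, n_dropped)


def load_fragments_sam(
    path,
    chrom_sizes: dict[str, int],
    length_window: tuple[int, int] = (100, 200),
    condition: str = "",
    single_end_extension: int | None = None,
    dyad_shift: int = 73,
) -> FragmentSet:
    """Read fragments from SAM/BAM via pysam.

    Paired-end: proper pairs yield one fragment per template (leftmost mate,
    span = |TLEN|).  Single-end: each read is shifted ``dyad_shift`` bp along
    its strand to the inferred dyad and expanded to ``single_end_extension``
    bp (required for single-end input).
    """
    import pysam

    rows = []
    n_dropped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            chrom = read.reference_name
            if read.is_paired:
                if not read.is_proper_pair or read.template_length <= 0:
                    continue  # count each template once, from the leftmost mate
                start, end = read.reference_start, read.reference_start + read.template_length
            else:
                if single_end_extension is None:
                    raise ValueError("single-end SAM input requires an extension length")
                if read.is_reverse:
                    dyad = read.reference_end - 1 - dyad_shift
                else:
                    dyad = read.reference_start + dyad_shift
                start = dyad - single_end_extension // 2
                end = start + single_end_extension
            length = end - start
            if length < length_window[0] or length > length_window[1]:
                n_dropped += 1
                continue
            size = chrom_sizes.get(chrom)
            if size is None:
                raise ValueError(f"unknown chromosome {chrom!r} in {path}")
            start = max(0, start)
            end = min(size, end)
            rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["strand"] = "."
    if df.empty:
        log.warning("no usable fragments in %s", path)
    return FragmentSet(df, condition, n_dropped)


def compute_occupancy(
    frags: FragmentSet,
    chrom_sizes: dict[str, int],
    bandwidth_bp: float = 20.0,
) -> OccupancyTrack:
    """Gaussian-smoothed fragment-midpoint density (raw, unnormalized).

    Pre-normalization track mass equals the fragment count up to kernel mass
    truncated at chromosome edges.
    """
    if len(frags) == 0:
        raise ValueError("no usable fragments")
    data: dict[str, np.ndarray] = {}
    mids = frags.midpoints()
    for chrom, size in chrom_sizes.items():
        m = mids.loc[mids["chrom"] == chrom, "mid"].to_numpy()
        counts = np.bincount(m, minlength=size).astype(float)
        data[chrom] = gaussian_filter1d(counts, sigma=bandwidth_bp, mode="constant", truncate=4.0)
    return OccupancyTrack(
        data, condition=frags.condition, bandwidth_bp=bandwidth_bp,
        normalization="raw", total_fragments=len(frags),
    )


def normalize_track(track: OccupancyTrack, mode: str = GENOME_MEAN_ONE) -> OccupancyTrack:
    """Return a normalized copy: genome-wide mean 1, or per-million scaling."""
    if mode not in (GENOME_MEAN_ONE, PER_MILLION):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if track.normalization == mode:
        return track.copy()
    mean = track.genome_mean()
    if mean == 0:
        raise ValueError("cannot normalize an all-zero track")
    out = track.copy()
    if mode == GENOME_MEAN_ONE:
        scale = 1.0 / mean
    else:
        if track.normalization != "raw":
            raise ValueError("per_million normalization requires a raw track")
        if track.total_fragments == 0:
            raise ValueError("per_million normalization requires total_fragments")
        scale = 1e6 / track.total_fragments
    for chrom in out.data:
        out.data[chrom] = out.data[chrom] * scale
    out.normalization = mode
    return out


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV (name, length) or FASTA (sizes via pyfaidx)."""
    p = str(path)
    if p.endswith((".fa", ".fasta", ".fa.gz", ".fasta.gz")):
        from pyfaidx import Fasta

        with Fasta(p) as fa:
            return {name: len(fa[name]) for name in fa.keys()}
    df = pd.read_csv(p, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))
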