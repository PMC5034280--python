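"""Peak calling, +1/-1 assignment, NFR arithmetic and region counting."""

import numpy as np
import pandas as pd
import pytest

from nucdyn.geometry import (
    assign_flanking_nucleosomes,
    build_gene_architecture,
    call_nucleosomes,
    count_region_reads,
    define_nfr,
    occupancy_score,
)
from nucdyn.occupancy import FragmentSet, OccupancyTrack, compute_occupancy, normalize_track


def track_from(values, total=1000):
    return OccupancyTrack({"chr1": np.asarray(values, dtype=float)},
                          normalization="genome_mean_one", total_fragments=total)


def gaussian_bump(size, center, height=2.0, sd=20.0):
    x = np.arange(size)
    return height * np.exp(-((x - center) ** 2) / (2 * sd**2))


def brute_force_local_maxima(v, min_height):
    """Independent oracle: exhaustive scan for strict local maxima."""
    out = []
    for i in range(1, len(v) - 1):
        if v[i] >= min_height and v[i] > v[i - 1] and v[i] > v[i + 1]:
            out.append(i)
    return out


def calls_frame(dyads, height=2.0):
    df = pd.DataFrame({"chrom": "chr1", "dyad": dyads, "peak_height": height})
    df["occupancy_score"] = 1.0
    return df


def gene(tss, strand="+", chrom="chr1"):
    return pd.Series({"chrom": chrom, "tss": tss, "strand": strand, "gene_id": "g"})


class TestCalling:
    def test_constant_track_yields_no_calls(self):
        assert len(call_nucleosomes(track_from(np.ones(500)))) == 0

    def test_single_bump_called_at_center(self):
        calls = call_nucleosomes(track_from(gaussian_bump(1000, 500)))
        assert list(calls["dyad"]) == [500]

    def test_two_separated_bumps_both_called(self):
        v = gaussian_bump(1200, 400) + gaussian_bump(1200, 700)
        calls = call_nucleosomes(track_from(v), min_spacing=120, min_height=0.25)
        oracle = brute_force_local_maxima(v, 0.25)
        assert sorted(calls["dyad"]) == sorted(oracle) == [400, 700]

    def test_greedy_exclusion_keeps_higher_of_close_pair(self):
        v = gaussian_bump(1000, 400, height=3.0) + gaussian_bump(1000, 480, height=2.0)
        calls = call_nucleosomes(track_from(v), min_spacing=120, min_height=0.25)
        assert len(calls) == 1
        assert abs(int(calls["dyad"][0]) - 400) <= 5

    def test_min_height_filters_low_peaks(self):
        v = gaussian_bump(1000, 300, height=0.2) + gaussian_bump(1000, 700, height=2.0)
        calls = call_nucleosomes(track_from(v), min_height=0.25)
        assert list(calls["dyad"]) == [700]

    def test_occupancy_score_monotone_in_peak_height(self):
        heights = np.linspace(0.1, 10, 50)
        scores = [occupancy_score(h, 10_000, 100_000) for h in heights]
        assert (np.diff(scores) > 0).all()


class TestFlankAssignment:
    def test_overlapping_call_is_plus1(self):
        plus1, _ = assign_flanking_nucleosomes(calls_frame([1030]), gene(1000))
        assert int(plus1["dyad"]) == 1030

    def test_upstream_call_is_minus1(self):
        plus1, minus1 = assign_flanking_nucleosomes(calls_frame([850, 1030]), gene(1000))
        assert int(plus1["dyad"]) == 1030 and int(minus1["dyad"]) == 850

    def test_minus_strand_mirror(self):
        plus1, minus1 = assign_flanking_nucleosomes(
            calls_frame([4970, 5150]), gene(5000, strand="-")
        )
        assert int(plus1["dyad"]) == 4970 and int(minus1["dyad"]) == 5150

    def test_nearest_of_multiple_overlapping_calls_wins(self):
        plus1, _ = assign_flanking_nucleosomes(calls_frame([940, 1020]), gene(1000))
        assert int(plus1["dyad"]) == 1020

    def test_rescue_window_catches_shifted_plus1(self):
        plus1, _ = assign_flanking_nucleosomes(calls_frame([1150]), gene(1000))
        assert int(plus1["dyad"]) == 1150
        plus1, _ = assign_flanking_nucleosomes(
            calls_frame([1150]), gene(1000), rescue_bp=100
        )
        assert plus1 is None

    def test_no_calls_on_chromosome_gives_absent_flanks(self):
        plus1, minus1 = assign_flanking_nucleosomes(calls_frame([1030]), gene(1000, chrom="chr9"))
        assert plus1 is None and minus1 is None


class TestNfr:
    def test_plus_strand_edge_arithmetic(self):
        start, end, width = define_nfr(plus1_dyad=1030, minus1_dyad=850, strand="+")
        assert (start, end, width) == (924, 957, 33)

    def test_minus_strand_mirror_same_width(self):
        start, end, width = define_nfr(plus1_dyad=1030, minus1_dyad=1210, strand="-")
        assert width == 33
        assert (start, end) == (1104, 1137)

    def test_overlapping_footprints_clamp_to_zero_width(self):
        _, _, width = define_nfr(plus1_dyad=1000, minus1_dyad=900, strand="+")
        assert width == 0

    def test_width_equals_interval_length(self):
        start, end, width = define_nfr(plus1_dyad=2000, minus1_dyad=1700, strand="+")
        assert width == end - start == 300 - 147


class TestRegionCounts:
    FRAGS = pd.DataFrame(
        {"chrom": ["chr1"] * 3, "start": [100, 200, 300], "end": [247, 347, 447],
         "strand": ["+"] * 3}
    )  # midpoints 173, 273, 373

    def test_half_open_boundaries(self):
        n = count_region_reads(self.FRAGS, "chr1", 173, 273, total_fragments=10**6)
        assert n == 1.0  # start included, end excluded

    def test_per_million_scaling(self):
        n = count_region_reads(self.FRAGS, "chr1", 0, 500, total_fragments=3)
        assert n == pytest.approx(3 * 1e6 / 3)

    def test_empty_interval_counts_zero(self):
        assert count_region_reads(self.FRAGS, "chr1", 200, 200, 10) == 0.0


class TestStrandAntiSymmetry:
    def test_mirrored_genome_preserves_widths_and_scores(self, small_dataset):
        ds = small_dataset
        cond = "Gln"
        sizes = ds.chrom_sizes

        def arch_of(frags, ann):
            fs = FragmentSet(frags, condition=cond)
            track = normalize_track(compute_occupancy(fs, sizes))
            calls = call_nucleosomes(track, 120, 2.0)
            return build_gene_architecture(calls, ann, {cond: frags})

        fwd = arch_of(ds.fragments[cond], ds.annotation)

        flipped = ds.fragments[cond].copy()
        L = flipped["chrom"].map(sizes)
        flipped["start"], flipped["end"] = L - ds.fragments[cond]["end"], L - ds.fragments[cond]["start"]
        ann = ds.annotation.copy()
        La = ann["chrom"].map(sizes)
        ann["tss"] = La - 1 - ds.annotation["tss"]
        ann["stop_codon"] = La - 1 - ds.annotation["stop_codon"]
        ann["strand"] = ds.annotation["strand"].map({"+": "-", "-": "+"})
        rev = arch_of(flipped, ann)

        merged = fwd.merge(rev, on="gene_id", suffixes=("_f", "_r"))
        both = merged.dropna(subset=["nfr_width_f", "nfr_width_r"])
        assert len(both) >= 0.9 * len(merged)
        # fragment midpoints shift by <=1 bp under mirroring (integer
        # division), so allow the NFR edges to move by 1 bp either side
        assert (np.abs(both["nfr_width_f"] - both["nfr_width_r"]) <= 2).all()
        np.testing.assert_allclose(
            both["plus1_score_f"], both["plus1_score_r"], atol=0.02
        )
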