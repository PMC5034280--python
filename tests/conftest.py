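import pytest

from nucdyn.simulate import SimConfig, simulate_dataset
from nucdyn.occupancy import FragmentSet, compute_occupancy, normalize_track
from nucdyn.geometry import build_gene_architecture, call_nucleosomes

# analysis parameters used for all benchmark-scale fixtures (the pipeline's
# demo settings: Gaussian bandwidth 20 bp, 120 bp exclusion, call threshold
# 2x genome mean so sub-nucleosomal NFR density is not called)
BANDWIDTH = 20.0
MIN_SPACING = 120
MIN_HEIGHT = 2.0

EFFECT_MULT = 4.0
N_EFFECT = 20
EFFECT_IDS = tuple(f"g{i:04d}" for i in range(N_EFFECT))


@pytest.fixture(scope="session")
def bench_config():
    """200 genes, 3 conditions, 50x depth, 20 bp dyad jitter, 20 effect
    genes whose NFR occupancy quadruples in the Pro condition."""
    return SimConfig(
        seed=11,
        n_genes=200,
        effect_genes=tuple((g, "Pro", EFFECT_MULT) for g in EFFECT_IDS),
    )


@pytest.fixture(scope="session")
def bench_dataset(bench_config):
    return simulate_dataset(bench_config)


@pytest.fixture(scope="session")
def bench_tracks(bench_dataset):
    return {
        cond: normalize_track(
            compute_occupancy(
                FragmentSet(frags, condition=cond), bench_dataset.chrom_sizes, BANDWIDTH
            )
        )
        for cond, frags in bench_dataset.fragments.items()
    }


@pytest.fixture(scope="session")
def bench_calls(bench_tracks):
    return {
        cond: call_nucleosomes(track, MIN_SPACING, MIN_HEIGHT)
        for cond, track in bench_tracks.items()
    }


@pytest.fixture(scope="session")
def bench_arch(bench_calls, bench_dataset):
    """Gene architecture from the reference (Gln) call set."""
    return build_gene_architecture(
        bench_calls["Gln"], bench_dataset.annotation, bench_dataset.fragments
    )


@pytest.fixture(scope="session")
def small_dataset():
    """30 genes, two chromosomes; for fast unit-level checks."""
    cfg = SimConfig(seed=3, n_genes=30, n_chromosomes=2)
    return simulate_dataset(cfg)
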