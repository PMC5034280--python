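"""Synthetic multi-condition MNase-seq data with known ground truth.

Emulates the chromatin organisation of a budding-yeast promoter: a phased
nucleosome array in the gene body, a +1 nucleosome whose footprint overlaps
the TSS, a nucleosome-free region (NFR) upstream of it, a -1 nucleosome and
a short upstream array.  Three growth conditions (by default the nitrogen
regimes ``Gln``, ``Pro`` and ``Gln-Pro``) share the same nucleosome
geometry; condition-dependent biology enters only through per-gene NFR
occupancy multipliers for a designated "effect" gene subset, mimicking
nitrogen-responsive promoter remodelling.

Mononucleosomal fragments are drawn per nucleosome (Poisson counts, Gaussian
dyad jitter, Gaussian length truncated to the mononucleosome gel-selection
window), the NFR contributes a low uniform sub-nucleosomal read density, and
a uniform genome-wide background models naked-DNA contamination.

All coordinates are 0-based, half-open (BED convention).  The dyad of a
147 bp footprint ``[s, s+147)`` is ``s + 73``; the footprint of a dyad ``d``
is ``[d-73, d+74)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CORE_BP = 147
HALF_CORE = 73  # footprint = [dyad-73, dyad+74)

DEFAULT_CONDITIONS = ("Gln", "Pro", "Gln-Pro")

# spawn keys for deriving independent per-stage RNG streams from one seed
_KEY_GENOME = 0
_KEY_PLACE = 1
_KEY_FRAGS = 2
_KEY_CT = 3


class SimConfigError(ValueError):
    """A simulation parameter is outside its valid domain."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic MNase-seq experiment.

    Lengths are in bp, depths in expected fragments per nucleosome per
    condition.  ``effect_genes`` designates condition-specific NFR occupancy
    changes as ``(gene_id, condition, multiplier)`` triples; a multiplier
    above 1 raises NFR reads in that condition (the reference/comparison
    ratio drops: "repression"), below 1 lowers them ("activation").
    """

    seed: int
    n_chromosomes: int = 1
    n_genes: int = 200
    gene_spacing_bp: int = 3000
    gene_length_bp: int = 1200
    nucleosome_core_bp: int = CORE_BP
    linker_bp: int = 18
    nfr_width_mean: float = 140.0
    nfr_width_sd: float = 20.0
    plus1_offset_bp: int = 60
    upstream_nucleosomes: int = 3
    fragment_len_mean: float = 147.0
    fragment_len_sd: float = 15.0
    fragment_len_bounds: tuple[int, int] = (100, 200)
    depth: float = 50.0
    nfr_depth: float = 25.0
    background_frac: float = 0.05
    tata_fraction: float = 0.2
    tata_plus1_boost: float = 2.0
    fuzziness_sd_bp: float = 20.0
    effect_genes: tuple[tuple[str, str, float], ...] = ()
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    chrom_margin_bp: int = 1500

    @property
    def repeat_bp(self) -> int:
        """Nucleosome repeat length (core + linker)."""
        return self.nucleosome_core_bp + self.linker_bp

    @property
    def upstream_reserve_bp(self) -> int:
        """Space reserved transcription-upstream of each TSS for the -1
        nucleosome, the upstream array and a generously sized NFR."""
        nfr_max = int(self.nfr_width_mean + 4 * self.nfr_width_sd)
        return (self.upstream_nucleosomes + 1) * self.repeat_bp + nfr_max + self.nucleosome_core_bp

    def validate(self) -> None:
        positive = [
            ("n_chromosomes", self.n_chromosomes),
            ("n_genes", self.n_genes),
            ("gene_spacing_bp", self.gene_spacing_bp),
            ("gene_length_bp", self.gene_length_bp),
            ("nucleosome_core_bp", self.nucleosome_core_bp),
            ("nfr_width_mean", self.nfr_width_mean),
            ("fragment_len_mean", self.fragment_len_mean),
        ]
        for name, value in positive:
            if value <= 0:
                raise SimConfigError(f"{name} must be > 0, got {value!r}")
        for name, value in [
            ("linker_bp", self.linker_bp),
            ("depth", self.depth),
            ("nfr_depth", self.nfr_depth),
            ("background_frac", self.background_frac),
            ("fuzziness_sd_bp", self.fuzziness_sd_bp),
            ("nfr_width_sd", self.nfr_width_sd),
            ("fragment_len_sd", self.fragment_len_sd),
        ]:
            if value < 0:
                raise SimConfigError(f"{name} must be >= 0, got {value!r}")
        if not 0.0 <= self.tata_fraction <= 1.0:
            raise SimConfigError(f"tata_fraction must be in [0, 1], got {self.tata_fraction!r}")
        if self.tata_plus1_boost < 1.0:
            raise SimConfigError(f"tata_plus1_boost must be >= 1, got {self.tata_plus1_boost!r}")
        if abs(self.plus1_offset_bp) > HALF_CORE:
            raise SimConfigError(
                f"plus1_offset_bp must keep the +1 footprint over the TSS "
                f"(|offset| <= {HALF_CORE}), got {self.plus1_offset_bp!r}"
            )
        for gene_id, cond, mult in self.effect_genes:
            if mult <= 0:
                raise SimConfigError(f"effect multiplier for {gene_id}/{cond} must be > 0, got {mult!r}")
            if cond not in self.conditions:
                raise SimConfigError(f"effect condition {cond!r} not among conditions {self.conditions}")
        min_spacing = self.upstream_reserve_bp + self.gene_length_bp + 200
        if self.gene_spacing_bp < min_spacing:
            raise SimConfigError(
                f"gene_spacing_bp={self.gene_spacing_bp} too small for the promoter layout "
                f"(needs >= {min_spacing}); genes would overlap"
            )
        if self.chrom_margin_bp < 1000:
            raise SimConfigError(
                f"chrom_margin_bp must be >= 1000 so +/-1000 bp metagene windows fit, "
                f"got {self.chrom_margin_bp!r}"
            )


@dataclass
class TruthTable:
    """Ground truth emitted by the generator.

    nucleosomes: one row per positioned nucleosome
        (chrom, dyad, gene_id, role, expected_<condition> ...)
    genes: one row per gene
        (gene_id, chrom, strand, tss, plus1_dyad, minus1_dyad,
         nfr_start, nfr_end, nfr_width, mult_<condition> ...,
         nfr_expected_<condition> ...)
    """

    nucleosomes: pd.DataFrame
    genes: pd.DataFrame
    conditions: tuple[str, ...]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Tile genes along chromosomes and draw a random genome sequence.

    Returns ``(genome, annotation)`` where genome maps chromosome name to
    sequence and annotation has one row per gene with columns
    gene_id, chrom, start, end, strand, tss, stop_codon, tata.

    TATA-containing genes (flag 1, drawn with probability ``tata_fraction``)
    get a TATA box planted ~100 bp transcription-upstream of the TSS.
    """
    config.validate()
    rng = _rng(config.seed, _KEY_GENOME)

    n_per_chrom = -(-config.n_genes // config.n_chromosomes)  # ceil
    chrom_len = 2 * config.chrom_margin_bp + n_per_chrom * config.gene_spacing_bp
    reserve = config.upstream_reserve_bp

    rows = []
    g = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        for slot in range(n_per_chrom):
            if g >= config.n_genes:
                break
            slot_start = config.chrom_margin_bp + slot * config.gene_spacing_bp
            strand = "+" if rng.random() < 0.5 else "-"
            tata = int(rng.random() < config.tata_fraction)
            if strand == "+":
                start = slot_start + reserve
                end = start + config.gene_length_bp
                tss, stop_codon = start, end - 1
            else:
                end = slot_start + config.gene_spacing_bp - reserve
                start = end - config.gene_length_bp
                tss, stop_codon = end - 1, start
            rows.append(
                dict(gene_id=f"g{g:04d}", chrom=chrom, start=start, end=end,
                     strand=strand, tss=tss, stop_codon=stop_codon, tata=tata)
            )
            g += 1

    annotation = pd.DataFrame(rows)

    bases = np.array(list("ACGT"))
    genome: dict[str, str] = {}
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq = rng.integers(0, 4, size=chrom_len)
        genome[chrom] = "".join(bases[seq])

    # plant a TATA box ~100 bp upstream of TATA-flagged TSSs
    box = "TATAAA"
    comp = str.maketrans("ACGT", "TGCA")
    for row in annotation.itertuples():
        if not row.tata:
            continue
        seq = genome[row.chrom]
        if row.strand == "+":
            pos = row.tss - 100
            genome[row.chrom] = seq[:pos] + box + seq[pos + len(box):]
        else:
            pos = row.tss + 100 - len(box) + 1
            genome[row.chrom] = seq[:pos] + box.translate(comp)[::-1] + seq[pos + len(box):]

    return genome, annotation


def place_nucleosomes(annotation: pd.DataFrame, config: SimConfig) -> TruthTable:
    """Lay out the per-gene nucleosome architecture and expected counts.

    Transcription-oriented per gene: an upstream array, the -1 nucleosome,
    an NFR of sampled width, the +1 nucleosome at TSS + plus1_offset, then
    a phased array through the gene body at the configured repeat.
    Expected fragment counts are ``depth`` per nucleosome, times
    ``tata_plus1_boost`` for the +1 of TATA-containing genes; the NFR
    carries ``nfr_depth`` expected sub-nucleosomal fragments, times the
    per-gene per-condition effect multiplier.
    """
    config.validate()
    rng = _rng(config.seed, _KEY_PLACE)
    repeat = config.repeat_bp
    half = config.nucleosome_core_bp // 2

    effect = {(gid, cond): mult for gid, cond, mult in config.effect_genes}

    nuc_rows, gene_rows = [], []
    for row in annotation.itertuples():
        d = 1 if row.strand == "+" else -1
        plus1 = row.tss + d * config.plus1_offset_bp

        w = rng.normal(config.nfr_width_mean, config.nfr_width_sd)
        while w < 1:  # never emit nonpositive NFR widths
            w = rng.normal(config.nfr_width_mean, config.nfr_width_sd)
        w = int(round(w))

        minus1 = plus1 - d * (config.nucleosome_core_bp + w)
        dyads = [(plus1, "plus1"), (minus1, "minus1")]
        for k in range(1, config.upstream_nucleosomes + 1):
            dyads.append((minus1 - d * repeat * k, f"upstream{k}"))
        n_body = max(0, (config.gene_length_bp - config.plus1_offset_bp - half - 1) // repeat)
        for k in range(1, n_body + 1):
            dyads.append((plus1 + d * repeat * k, f"body{k}"))

        for dyad, role in dyads:
            exp = config.depth
            if role == "plus1" and row.tata:
                exp *= config.tata_plus1_boost
            nuc = dict(chrom=row.chrom, dyad=int(dyad), gene_id=row.gene_id, role=role)
            for cond in config.conditions:
                nuc[f"expected_{cond}"] = exp
            nuc_rows.append(nuc)

        # genomic NFR interval between the -1 and +1 footprints
        if d == 1:
            nfr_start, nfr_end = minus1 + half + 1, plus1 - half
        else:
            nfr_start, nfr_end = plus1 + half + 1, minus1 - half
        grow = dict(gene_id=row.gene_id, chrom=row.chrom, strand=row.strand, tss=row.tss,
                    plus1_dyad=int(plus1), minus1_dyad=int(minus1),
                    nfr_start=int(nfr_start), nfr_end=int(nfr_end),
                    nfr_width=int(nfr_end - nfr_start))
        for cond in config.conditions:
            mult = effect.get((row.gene_id, cond), 1.0)
            grow[f"mult_{cond}"] = mult
            grow[f"nfr_expected_{cond}"] = config.nfr_depth * mult
        gene_rows.append(grow)

    return TruthTable(
        nucleosomes=pd.DataFrame(nuc_rows),
        genes=pd.DataFrame(gene_rows),
        conditions=config.conditions,
    )


def sample_fragments(
    truth: TruthTable,
    condition: str,
    config: SimConfig,
    chrom_sizes: dict[str, int],
) -> pd.DataFrame:
    """Draw mononucleosomal fragments for one condition (BED6 columns).

    Per positioned nucleosome: Poisson(expected) fragments, midpoints at the
    dyad plus Gaussian jitter; per NFR: Poisson(expected) fragments with
    midpoints uniform over the NFR; plus a uniform genome-wide background.
    Fragment lengths are Gaussian, truncated (clipped) to the configured
    mononucleosome window.
    """
    if condition not in truth.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cond_idx = truth.conditions.index(condition)
    rng = _rng(config.seed, _KEY_FRAGS, cond_idx)

    nuc = truth.nucleosomes
    genes = truth.genes
    exp_col = f"expected_{condition}"

    counts = rng.poisson(nuc[exp_col].to_numpy())
    mids = np.repeat(nuc["dyad"].to_numpy(), counts).astype(float)
    if config.fuzziness_sd_bp > 0:
        mids += rng.normal(0.0, config.fuzziness_sd_bp, size=mids.size)
    chroms = np.repeat(nuc["chrom"].to_numpy(), counts)

    nfr_counts = rng.poisson(genes[f"nfr_expected_{condition}"].to_numpy())
    nfr_mids = []
    for n, s, e in zip(nfr_counts, genes["nfr_start"], genes["nfr_end"]):
        nfr_mids.append(rng.integers(s, max(s + 1, e), size=n))
    nfr_mids = np.concatenate(nfr_mids) if nfr_mids else np.array([], dtype=int)
    nfr_chroms = np.repeat(genes["chrom"].to_numpy(), nfr_counts)

    total_expected = nuc[exp_col].sum() + genes[f"nfr_expected_{condition}"].sum()
    n_bg = rng.poisson(config.background_frac * total_expected)
    names = np.array(sorted(chrom_sizes))
    lens = np.array([chrom_sizes[c] for c in names], dtype=float)
    bg_chroms = names[rng.choice(len(names), size=n_bg, p=lens / lens.sum())]
    bg_mids = rng.integers(0, lens[np.searchsorted(names, bg_chroms)].astype(int))

    all_mids = np.concatenate([np.rint(mids).astype(int), nfr_mids, bg_mids])
    all_chroms = np.concatenate([chroms, nfr_chroms, bg_chroms])

    if all_mids.size == 0:
        warnings.warn(f"no fragments drawn for condition {condition!r} (zero depth?)")
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])

    lo, hi = config.fragment_len_bounds
    if config.fragment_len_sd > 0:
        lengths = np.rint(
            np.clip(rng.normal(config.fragment_len_mean, config.fragment_len_sd, size=all_mids.size), lo, hi)
        ).astype(int)
    else:
        lengths = np.full(all_mids.size, int(round(config.fragment_len_mean)))

    starts = all_mids - lengths // 2
    sizes = np.array([chrom_sizes[c] for c in all_chroms])
    starts = np.clip(starts, 0, sizes - lengths)
    ends = starts + lengths
    strands = np.where(rng.random(all_mids.size) < 0.5, "+", "-")

    return pd.DataFrame(
        dict(
            chrom=all_chroms,
            start=starts,
            end=ends,
            name=[f"f{i:07d}" for i in range(all_mids.size)],
            score=0,
            strand=strands,
        )
    )


def simulate_ct_table(
    truth: TruthTable,
    config: SimConfig,
    control_condition: str = "Gln",
    ref_gene: str = "ACT1",
    n_null_genes: int = 20,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Synthetic qRT-PCR Ct table tied to the simulated NFR dynamics.

    Expression fold change relative to the control condition is the inverse
    of the gene's NFR occupancy multiplier (promoter opening, i.e. NFR reads
    dropping, drives expression up), so nucleosome-profile "activated" genes
    come out up-regulated.  Ct values are on the usual cycle scale with the
    reference gene fixed across conditions; replicate noise is Gaussian on
    the Ct scale.
    """
    rng = _rng(config.seed, _KEY_CT)
    genes = truth.genes
    effect_ids = sorted({gid for gid, _, _ in config.effect_genes})
    null_ids = [g for g in genes["gene_id"] if g not in set(effect_ids)][:n_null_genes]
    measured = effect_ids + null_ids

    rows = []
    base_ct = {g: 20.0 + rng.normal(0, 1.0) for g in measured}
    for cond in truth.conditions:
        for gid in measured:
            mult = float(genes.loc[genes.gene_id == gid, f"mult_{cond}"].iloc[0])
            fold = 1.0 / mult if cond != control_condition else 1.0
            ct = base_ct[gid] - np.log2(fold)
            reps = ct + rng.normal(0, ct_noise_sd, size=n_replicates)
            rows.append([gid, cond] + list(np.round(reps, 3)))
        reps = 15.0 + rng.normal(0, ct_noise_sd, size=n_replicates)
        rows.append([ref_gene, cond] + list(np.round(reps, 3)))

    cols = ["gene", "condition"] + [f"ct_rep{i + 1}" for i in range(n_replicates)]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# writers

def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_annotation(annotation: pd.DataFrame, bed_path: str | Path, tsv_path: str | Path) -> None:
    """Gene annotation as BED6 plus a sidecar TSV carrying the TATA flag."""
    bed = annotation[["chrom", "start", "end", "gene_id", "tata", "strand"]].copy()
    bed.columns = ["chrom", "start", "end", "name", "score", "strand"]
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    annotation[["gene_id", "chrom", "tss", "stop_codon", "strand", "tata"]].to_csv(
        tsv_path, sep="\t", index=False
    )


def read_annotation(tsv_path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(tsv_path, sep="\t")
    required = {"gene_id", "chrom", "tss", "stop_codon", "strand", "tata"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    ann["start"] = ann[["tss", "stop_codon"]].min(axis=1)
    ann["end"] = ann[["tss", "stop_codon"]].max(axis=1) + 1
    return ann


def write_fragments_bed(frags: pd.DataFrame, path: str | Path) -> None:
    frags.to_csv(path, sep="\t", header=False, index=False)


def write_truth(truth: TruthTable, nuc_path: str | Path, gene_path: str | Path) -> None:
    truth.nucleosomes.to_csv(nuc_path, sep="\t", index=False)
    truth.genes.to_csv(gene_path, sep="\t", index=False)


@dataclass
class SimulatedDataset:
    """In-memory bundle produced by :func:`simulate_dataset`."""

    config: SimConfig
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    annotation: pd.DataFrame
    truth: TruthTable
    fragments: dict[str, pd.DataFrame]  # condition -> BED6 frame
    ct_table: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: genome, truth, fragments per condition, Ct table."""
    genome, annotation = simulate_genome(config)
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    truth = place_nucleosomes(annotation, config)
    fragments = {
        cond: sample_fragments(truth, cond, config, chrom_sizes) for cond in config.conditions
    }
    ct = simulate_ct_table(truth, config)
    return SimulatedDataset(config, genome, chrom_sizes, annotation, truth, fragments, ct)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every generator output under ``outdir``; returns name->path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome_fasta"] = outdir / "genome.fa"
    write_fasta(ds.genome, paths["genome_fasta"])
    paths["annotation_bed"] = outdir / "genes.bed"
    paths["annotation_tsv"] = outdir / "genes.tsv"
    write_annotation(ds.annotation, paths["annotation_bed"], paths["annotation_tsv"])
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    with open(paths["chrom_sizes"], "w") as fh:
        for c in sorted(ds.chrom_sizes):
            fh.write(f"{c}\t{ds.chrom_sizes[c]}\n")
    for cond, frags in ds.fragments.items():
        key = f"fragments_{cond}"
        paths[key] = outdir / f"fragments_{cond}.bed"
        write_fragments_bed(frags, paths[key])
    paths["truth_nucleosomes"] = outdir / "truth_nucleosomes.tsv"
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    write_truth(ds.truth, paths["truth_nucleosomes"], paths["truth_genes"])
    paths["ct_table"] = outdir / "ct.tsv"
    ds.ct_table.to_csv(paths["ct_table"], sep="\t", index=False)
    return paths
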