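"""End-to-end orchestration: simulate -> occupancy -> call -> metagene ->
diff -> qpcr -> report, with one mandatory seed, a flat config and a
manifest sufficient to reproduce byte-identical results."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import SimConfig, simulate_dataset, write_dataset
from .occupancy import (FragmentSet, compute_occupancy, normalize_track, GENOME_MEAN_ONE)
from .geometry import call_nucleosomes, build_gene_architecture, calls_to_bed
from .metagene import metagene, profile_report, STRATA
from .differential import (diff_nfr_table, significant_calls, decile_classes,
                           correlation_report, wilcoxon_compare, diff_summary)
from .qpcr import fold_change_table, concordance, load_ct_table

log = logging.getLogger(__name__)


class RunConfigError(ValueError):
    """A pipeline parameter is outside its documented domain."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def make_demo_effects(
    n_genes: int,
    conditions: tuple[str, ...],
    n_activated: int = 10,
    n_repressed: int = 10,
    activated_mult: float = 0.25,
    repressed_mult: float = 4.0,
) -> tuple[tuple[str, str, float], ...]:
    """Default effect-gene panel: the first genes lose NFR occupancy in the
    non-reference conditions (activated promoters), the next gain it."""
    out = []
    for i in range(n_activated):
        for cond in conditions[1:]:
            out.append((f"g{i:04d}", cond, activated_mult))
    for i in range(n_activated, n_activated + n_repressed):
        for cond in conditions[1:]:
            out.append((f"g{i:04d}", cond, repressed_mult))
    if n_activated + n_repressed > n_genes:
        raise RunConfigError("more effect genes than genes")
    return tuple(out)


@dataclass
class RunConfig:
    """Merged pipeline configuration (flat key=value file + CLI overrides).

    The nucleosome-call threshold ``min_height`` defaults to 2x the
    genome-mean occupancy here (stricter than the library-level default)
    so that sub-nucleosomal NFR read density at the simulated depths is
    never called as a nucleosome.
    """

    seed: int
    n_genes: int = 200
    n_chromosomes: int = 1
    depth: float = 50.0
    nfr_depth: float = 25.0
    fuzziness_sd_bp: float = 20.0
    background_frac: float = 0.05
    tata_fraction: float = 0.2
    tata_plus1_boost: float = 2.0
    conditions: tuple[str, ...] = ("Gln", "Pro", "Gln-Pro")
    effect_genes: tuple[tuple[str, str, float], ...] | str = "demo"
    bandwidth: float = 20.0
    min_spacing: int = 120
    min_height: float = 2.0
    rescue_bp: int = 200
    pseudocount: float = 0.5
    fold_log2: float = 1.0
    q_max: float = 0.05
    decile: float = 0.1
    plot: bool = False

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise RunConfigError("seed is mandatory and must be an integer")
        checks = [
            ("bandwidth", self.bandwidth, 0 < self.bandwidth <= 1000),
            ("min_spacing", self.min_spacing, 0 < self.min_spacing),
            ("min_height", self.min_height, self.min_height >= 0),
            ("rescue_bp", self.rescue_bp, self.rescue_bp >= 0),
            ("pseudocount", self.pseudocount, self.pseudocount >= 0),
            ("fold_log2", self.fold_log2, self.fold_log2 >= 0),
            ("q_max", self.q_max, 0 < self.q_max <= 1),
            ("decile", self.decile, 0 < self.decile <= 0.5),
        ]
        for name, value, ok in checks:
            if not ok:
                raise RunConfigError(f"{name}={value!r} outside its documented domain")
        if len(self.conditions) < 2:
            raise RunConfigError("need at least two conditions")

    def sim_config(self) -> SimConfig:
        effects = self.effect_genes
        if effects == "demo":
            effects = make_demo_effects(self.n_genes, tuple(self.conditions))
        elif isinstance(effects, str):
            raise RunConfigError(f"unknown effect_genes preset {effects!r}")
        return SimConfig(
            seed=int(self.seed),
            n_genes=self.n_genes,
            n_chromosomes=self.n_chromosomes,
            depth=self.depth,
            nfr_depth=self.nfr_depth,
            fuzziness_sd_bp=self.fuzziness_sd_bp,
            background_frac=self.background_frac,
            tata_fraction=self.tata_fraction,
            tata_plus1_boost=self.tata_plus1_boost,
            conditions=tuple(self.conditions),
            effect_genes=tuple(effects),
        )


_FIELD_TYPES = {f.name: f for f in fields(RunConfig)}


def parse_config_file(path: str | Path) -> dict:
    """Flat key=value config; '#' comments; unknown keys rejected."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise RunConfigError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in _FIELD_TYPES:
            raise RunConfigError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = _parse_value(key, value)
    return values


def _parse_value(key: str, value: str):
    if key == "conditions":
        return tuple(v.strip() for v in value.split(","))
    if key == "effect_genes":
        if value == "demo" or value == "":
            return value or ()
        triples = []
        for item in value.split(","):
            gene, cond, mult = item.strip().split(":")
            triples.append((gene, cond, float(mult)))
        return tuple(triples)
    if key == "plot":
        return value.lower() in ("1", "true", "yes")
    if key in ("seed", "n_genes", "n_chromosomes", "min_spacing", "rescue_bp"):
        return int(value)
    return float(value)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run every stage under ``outdir``; returns the run directory.

    On stage failure, partial outputs are retained and a FAILED marker
    naming the stage is written before the error propagates.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        simcfg = config.sim_config()

        stage = "simulate"
        ds = simulate_dataset(simcfg)
        write_dataset(ds, outdir / "sim")

        stage = "occupancy"
        occdir = outdir / "occupancy"
        occdir.mkdir(exist_ok=True)
        tracks, totals = {}, {}
        for cond in config.conditions:
            frags = FragmentSet(ds.fragments[cond], condition=cond)
            raw = compute_occupancy(frags, ds.chrom_sizes, bandwidth_bp=config.bandwidth)
            tracks[cond] = normalize_track(raw, GENOME_MEAN_ONE)
            totals[cond] = len(frags)
            tracks[cond].to_bedgraph(occdir / f"occupancy_{cond}.bedGraph")
            _write_json(
                dict(condition=cond, bandwidth_bp=config.bandwidth,
                     normalization=GENOME_MEAN_ONE, total_fragments=totals[cond]),
                occdir / f"occupancy_{cond}.json",
            )

        stage = "call"
        calldir = outdir / "calls"
        calldir.mkdir(exist_ok=True)
        calls = {}
        for cond in config.conditions:
            calls[cond] = call_nucleosomes(tracks[cond], config.min_spacing, config.min_height)
            calls[cond].to_csv(calldir / f"calls_{cond}.tsv", sep="\t", index=False,
                               float_format="%.6g")
            calls_to_bed(calls[cond]).to_csv(calldir / f"calls_{cond}.bed", sep="\t",
                                             header=False, index=False)
        ref = config.conditions[0]
        arch = build_gene_architecture(
            calls[ref], ds.annotation,
            {c: ds.fragments[c] for c in config.conditions}, config.rescue_bp,
        )
        arch.to_csv(calldir / "gene_architecture.tsv", sep="\t", index=False,
                    float_format="%.6g")
        _write_json({"reference_condition": ref, "totals": totals,
                     "min_spacing": config.min_spacing, "min_height": config.min_height,
                     "occupancy_score": "log10(peak reads + 1)"},
                    calldir / "gene_architecture.json")

        stage = "metagene"
        metadir = outdir / "metagene"
        metadir.mkdir(exist_ok=True)
        profiles = []
        for cond in config.conditions:
            for anchor in ("tss", "stop_codon"):
                for stratum in STRATA:
                    profiles.append(metagene(tracks[cond], ds.annotation, anchor, stratum))
        profile_report(profiles, metadir / "metagene.tsv",
                       metadir / "metagene.png" if config.plot else None)

        stage = "diff"
        diffdir = outdir / "diff"
        diffdir.mkdir(exist_ok=True)
        diff_results = {}
        for cond in config.conditions[1:]:
            res = diff_nfr_table(arch, ref, cond, totals, config.pseudocount)
            significant_calls(res, config.fold_log2, config.q_max)
            res.to_csv(diffdir / f"diff_{ref}_vs_{cond}.tsv", sep="\t", index=False,
                       float_format="%.6g")
            _write_json(diff_summary(res), diffdir / f"diff_{ref}_vs_{cond}.json")
            diff_results[cond] = res
        # Fig 3-style correlations (NFR vs gene-body reads) per condition
        correlations = {}
        for cond in config.conditions:
            sub = arch.dropna(subset=[f"{cond}_NFR"])
            r, r2, n = correlation_report(sub[f"{cond}_NFR"], sub[f"{cond}_gene"])
            correlations[cond] = dict(r=r, r_squared=r2, n=n)
        _write_json(correlations, diffdir / "nfr_gene_correlation.json")
        # decile occupancy classes on reference NFR occupancy, TATA breakdown
        with_nfr = arch.dropna(subset=[f"{ref}_NFR"]).set_index("gene_id")
        classes = decile_classes(with_nfr[f"{ref}_NFR"], config.decile)
        classes.to_csv(diffdir / "occupancy_classes.tsv", sep="\t", index=False)
        merged = classes.merge(arch[["gene_id", "tata"]], on="gene_id")
        tab = pd.crosstab(merged["class"], merged["tata"])
        class_tata = {str(k): {f"TATA{c}": int(v) for c, v in row.items()}
                      for k, row in tab.iterrows()}
        # Fig 5-style Wilcoxon: gene-body reads across conditions per class
        wilcox = {}
        for cls in ("high", "low"):
            ids = set(classes.loc[classes["class"] == cls, "gene_id"])
            sub = arch[arch["gene_id"].isin(ids)]
            for cond in config.conditions[1:]:
                p, stars = wilcoxon_compare(sub[f"{ref}_gene"], sub[f"{cond}_gene"])
                wilcox[f"{cls}:{ref}_vs_{cond}"] = dict(p=p, stars=stars, n=int(len(sub)))
        _write_json({"class_by_tata": class_tata, "wilcoxon_gene_body": wilcox},
                    diffdir / "occupancy_classes.json")

        stage = "qpcr"
        qdir = outdir / "qpcr"
        qdir.mkdir(exist_ok=True)
        ct = load_ct_table(outdir / "sim" / "ct.tsv")
        folds = fold_change_table(ct, control_condition=ref)
        folds.to_csv(qdir / "fold_changes.tsv", sep="\t", index=False, float_format="%.6g")
        conc = {}
        for cond in config.conditions[1:]:
            called = diff_results[cond][diff_results[cond]["call"] != "NS"]
            fsub = folds[folds["condition"] == cond]
            if called.empty or fsub.empty:
                conc[cond] = {"note": "no significant calls or no fold changes"}
            else:
                conc[cond] = concordance(fsub, called)
        _write_json(conc, qdir / "concordance.json")

        stage = "manifest"
        files = sorted(p for p in outdir.rglob("*")
                       if p.is_file() and p.name not in ("manifest.json", "report.md")
                       and p.suffix != ".png")
        manifest = dict(
            version=__version__,
            seed=int(config.seed),
            parameters={k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(config).items()},
            checksums={str(p.relative_to(outdir)): _sha256(p) for p in files},
        )
        _write_json(manifest, outdir / "manifest.json")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{stage}\n{exc}\n")
        raise StageError(stage, exc) from exc
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    return outdir


def _read_json(path: Path):
    if not path.exists():
        return None
    with open(path) as fh:
        return json.load(fh)


def report(run_dir: str | Path) -> Path:
    """Render a single markdown summary of a completed run (idempotent)."""
    run_dir = Path(run_dir)
    manifest = _read_json(run_dir / "manifest.json")
    lines = ["# Nucleosome dynamics run report", ""]
    if manifest:
        lines += [f"Package version {manifest['version']}, seed {manifest['seed']}.", ""]

    def section(title: str, render) -> None:
        lines.append(f"## {title}")
        try:
            body = render()
        except Exception as exc:  # missing stage output
            body = [f"*absent: {exc}*"]
        lines.extend(body + [""])

    def _sim():
        genes = pd.read_csv(run_dir / "sim" / "genes.tsv", sep="\t")
        return [f"{len(genes)} genes simulated; "
                f"{int(genes['tata'].sum())} TATA-containing, "
                f"{int((genes['tata'] == 0).sum())} TATA-less."]

    def _occ():
        out = []
        for p in sorted((run_dir / "occupancy").glob("occupancy_*.json")):
            meta = _read_json(p)
            out.append(f"- {meta['condition']}: {meta['total_fragments']} fragments, "
                       f"bandwidth {meta['bandwidth_bp']} bp, {meta['normalization']}")
        if not out:
            raise FileNotFoundError("no occupancy metadata")
        return out

    def _calls():
        meta = _read_json(run_dir / "calls" / "gene_architecture.json")
        arch = pd.read_csv(run_dir / "calls" / "gene_architecture.tsv", sep="\t")
        n_nfr = int(arch["nfr_width"].notna().sum())
        return [f"Reference condition {meta['reference_condition']}; "
                f"{n_nfr}/{len(arch)} genes with both flanks and a defined NFR; "
                f"median NFR width {arch['nfr_width'].median():.0f} bp."]

    def _metagene():
        table = pd.read_csv(run_dir / "metagene" / "metagene.tsv", sep="\t")
        tss = table[(table["anchor"] == "tss") & (table["stratum"] == "all")]
        out = []
        for cond, grp in tss.groupby("condition"):
            imax = grp.loc[grp["mean_occupancy"].idxmax()]
            out.append(f"- {cond}: TSS-profile maximum {imax['mean_occupancy']:.2f} "
                       f"at {int(imax['offset'])} bp")
        return out

    def _classes():
        meta = _read_json(run_dir / "diff" / "occupancy_classes.json")
        out = ["Decile occupancy classes by TATA status:"]
        for cls, row in sorted(meta["class_by_tata"].items()):
            out.append(f"- {cls}: " + ", ".join(f"{k}={v}" for k, v in sorted(row.items())))
        return out

    def _diff():
        out = []
        for p in sorted((run_dir / "diff").glob("diff_*.json")):
            s = _read_json(p)
            out.append(f"- {p.stem}: {s['n_activated']} activated, "
                       f"{s['n_repressed']} repressed, {s['n_ns']} NS")
        corr = _read_json(run_dir / "diff" / "nfr_gene_correlation.json")
        if corr:
            for cond, c in sorted(corr.items()):
                out.append(f"- NFR vs gene-body reads, {cond}: R^2 = {c['r_squared']:.4f}")
        if not out:
            raise FileNotFoundError("no differential outputs")
        return out

    def _qpcr():
        conc = _read_json(run_dir / "qpcr" / "concordance.json")
        if conc is None:
            raise FileNotFoundError("no qPCR outputs")
        out = []
        for cond, c in sorted(conc.items()):
            if "concordance_activated" in c:
                out.append(f"- {cond}: concordance among activated genes "
                           f"{c['concordance_activated']:.2f} "
                           f"(n={c['n_activated']} activated, {c['n_repressed']} repressed)")
            else:
                out.append(f"- {cond}: {c.get('note', 'unavailable')}")
        return out

    section("Simulation", _sim)
    section("Occupancy tracks", _occ)
    section("Nucleosome calls and NFR geometry", _calls)
    section("Metagene profiles", _metagene)
    section("Decile occupancy classes", _classes)
    section("Differential NFR occupancy", _diff)
    section("qPCR concordance", _qpcr)

    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
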