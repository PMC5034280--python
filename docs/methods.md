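# Methods

This note documents the models, estimators, defaults and design choices
behind `nucdyn`, and what the synthetic benchmark does and does not show
about real data.

## The biological setting

In *S. cerevisiae*, ~147 bp of DNA wraps a histone octamer to form a
nucleosome; genes typically carry a phased nucleosome array starting at a
**+1 nucleosome** whose footprint overlaps the TSS, with a **nucleosome-free
region (NFR)** and a **−1 nucleosome** immediately transcription-upstream.
Shifting cells between preferred (glutamine) and non-preferred (proline)
nitrogen sources remodels promoter chromatin, particularly at nitrogen
catabolite repression (NCR)–sensitive genes, and these changes can be read
out from MNase-seq as changes in NFR read density. The pipeline quantifies
exactly that: per-gene promoter geometry per condition, NFR read-count
ratios and their significance, and agreement with qRT-PCR expression.

## Occupancy estimation

Each mononucleosomal fragment contributes unit mass at its midpoint — the
natural dyad estimate for ~147 bp protected fragments. The midpoint pileup
is convolved with a Gaussian kernel (default sd **20 bp**, truncated at
4 sd). This bandwidth is narrow enough to keep adjacent nucleosomes at the
~165 bp yeast repeat separable and wide enough to bridge single-bp sampling
noise at typical depths; it is exposed as `--bandwidth`. Any smooth dyad
density estimator would serve the downstream definitions equally; the
Gaussian kernel was chosen for linearity, symmetry (peaks stay centred on
dyads) and a one-line implementation on top of a standard filter.

Kernel mass falling off a chromosome end is truncated rather than
reflected: the bias is confined to the outermost ~80 bp, where no genes are
anchored. Tracks are normalized to genome-wide mean 1
(`genome_mean_one`), so values read as fold over genome average;
`per_million` scaling is available when absolute read density is wanted.
Single-end reads, if supplied as SAM, are shifted +73 bp along their strand
to the inferred dyad and expanded to a caller-specified extension — the
standard MNase convention; paired-end templates are used directly.

## Nucleosome calling and promoter geometry

Calls are strict local maxima of the normalized track, selected greedily in
descending height with a **120 bp exclusion radius** (below the 147 bp core,
so tightly packed nucleosomes survive; overlapping calls cannot). Ties in
height break to the leftmost coordinate, making calls deterministic. Each
call's occupancy score is `log10(reads at peak + 1)`, with the read count
estimated as peak height × mean fragment density × 147 bp; the log base and
+1 pseudocount are recorded in the output metadata.

The library-level default height threshold is **0.25× genome mean**, a
floor against naked-DNA background. The pipeline's demo configuration uses
**2.0× genome mean** instead: the simulated NFRs carry a deliberate
sub-nucleosomal read density (~0.7–1.0× genome mean at demo depth), and a
threshold below that occasionally promotes NFR noise into a call sitting
between the true −1 and +1, which then corrupts the −1 assignment. On real
data the appropriate threshold depends on digestion quality and depth, and
is a flag.

Per gene (always transcription-oriented; minus-strand genes mirror all
rules): the +1 is the call whose footprint overlaps the TSS, choosing the
dyad nearest the TSS when several overlap (ties to the downstream call);
when none overlaps, a call with dyad within a **200 bp rescue window**
downstream of the TSS is accepted, since modest +1 shifts at this smoothing
otherwise orphan genes. The −1 is the nearest call strictly upstream of the
+1. The NFR runs from the 3′ edge of the −1 footprint to the 5′ edge of the
+1 footprint; touching or overlapping footprints give width 0. The stated
edge-to-edge reading is applied in transcription orientation so both
strands yield nonnegative widths — an interpretation, recorded here.

NFR and gene-body read counts use fragment **midpoints** in half-open
intervals (consistent with the track, and never double-counting a fragment
spanning a boundary), scaled to reads per million. The gene body is
[TSS, stop codon] inclusive. Geometry is defined once, from the reference
condition's call set, and reads are counted per condition in those fixed
intervals; this keeps the per-gene comparison well-defined even where a
condition fills in its NFR.

## Metagene profiles

Profiles average normalized (linear, not log) occupancy at each offset in
−1000..+1000 bp around the TSS or stop codon, offset 0 being the anchor
base and both endpoints included (2001 points); minus-strand windows are
reversed so positive offsets are transcription-downstream. Genes whose
window overhangs a chromosome end are excluded and counted. Strata are
`all`, `TATA1` (TATA-containing) and `TATA0` (TATA-less); the all-genes
profile equals the stratum-size-weighted mean of the two strata by
construction, and the test suite holds this identity to 1e-9.

## Differential NFR occupancy

For a reference/comparison pair (reference Gln by convention):

- **Ratio** = (ref + c) / (cmp + c) on normalized NFR reads, with
  pseudocount c = 0.5 guarding sparse NFRs (c = 0 gives the pure textbook
  definition). Ratio > 1 is *activation* (NFR emptier in the comparison),
  < 1 *repression*.
- **Scaled-difference chi-square**: the 2×2 test without Yates correction
  on [[k_ref, N_ref − k_ref], [k_cmp, N_cmp − k_cmp]] with raw NFR counts k
  and per-condition genome-wide totals N, so sequencing-depth scaling
  enters through the margins; p from χ²(1 df). It reduces to the standard
  two-proportion test; both counts zero is degenerate (χ² = 0, p = 1).
  Per-gene totals (NFR + gene body) are available behind a flag.
- **Benjamini–Hochberg** step-up q-values, one family per condition pair.
- **Filter**: |log2 ratio| > 1 and q below a threshold. The threshold is a
  flag defaulting to 1e-30 at the library level — attainable only at
  genome-scale read totals — while the pipeline's desk-scale demo uses
  q < 0.05, which the ~25-count NFRs of the simulation can reach.

Decile occupancy classes take the ⌈0.1 n⌉ largest (high) and smallest (low)
per-gene NFR occupancies, ties broken by gene id so runs are reproducible;
the class × TATA contingency table is reported. Pearson R² (complete pairs)
and two-sided Wilcoxon rank-sum comparisons (exact enumeration when both
groups ≤ 12 without cross-group ties, otherwise the normal approximation
with tie correction and no continuity correction — so identical groups give
exactly p = 1) round out the per-class summaries, with stars at
p < 0.05 / 0.01 / 0.001.

## qRT-PCR fold changes

Replicate Ct values are averaged on the Ct scale; ΔCt subtracts the
reference gene (*ACT1*) within each condition, ΔΔCt subtracts the control
condition, and fold = 2^−ΔΔCt. Folds are therefore invariant to per-run
constant Ct shifts. Concordance cross-tabulates nucleosome calls against
expression direction; genes with fold exactly 1 are reported as boundary
cases, not forced up or down. Gene names match case-insensitively with a
logged alias table. Amplification-efficiency correction is out of scope.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
defaults chosen as a realistic yeast-like regime:

| parameter | default | meaning |
|---|---|---|
| core / linker | 147 / 18 bp | ~165 bp repeat, typical yeast spacing |
| NFR width | N(140, 20) bp | resampled if < 1 bp |
| +1 offset | +60 bp | +1 dyad downstream of TSS, footprint over TSS |
| upstream array | 3 nucleosomes | beyond the −1 |
| depth | 50 fragments/nucleosome/condition | "50×" benchmark depth |
| NFR density | 25 expected fragments/NFR | sub-nucleosomal, ~0.75× genome mean |
| fragment length | N(147, 15), clipped to [100, 200] bp | gel selection window |
| dyad jitter | sd 20 bp | positioning fuzziness |
| background | 5 % uniform | naked-DNA contamination |
| TATA fraction / +1 boost | 0.2 / 2× | ~20 % TATA genes, stronger +1 |
| conditions | Gln, Pro, Gln-Pro | shared geometry |

Genes tile chromosomes at 3 kb spacing with randomized strand, at least
1.5 kb from chromosome ends so ±1000 bp windows always fit; a TATA box is
planted ~100 bp upstream of TATA-flagged TSSs. Condition effects enter only
as per-gene NFR multipliers (the demo panel: 10 genes × 0.25 — activated —
and 10 genes × 4.0 — repressed — in the non-reference conditions). The
matched synthetic Ct table ties expression to promoter state as fold =
1 / multiplier (NFR loss ⇒ up-regulation) with 0.1-cycle replicate noise,
so activated calls should be up-regulated.

What the generator does **not** model: sequence-dependent nucleosome
affinity, MNase sequence bias, replicate-level biological variance,
overdispersion beyond Poisson, chromatin heterogeneity between cells, and
genes with atypical promoter architecture. Passing benchmarks therefore
demonstrates the pipeline's correctness and statistical calibration under
its own assumptions — not that real libraries meet those assumptions.

## Numerical and reproducibility choices

- Coordinates are 0-based half-open throughout; the dyad of footprint
  [s, s+147) is s+73.
- One mandatory seed drives every random draw; per-stage, per-condition
  streams are spawned via `SeedSequence` keys, so outputs are byte-identical
  across runs and stage reruns reproduce their files exactly (checksummed
  in the run manifest).
- Peak ties break leftmost; decile ties break by gene id; fragment-length
  truncation clips rather than resamples (negligible at the default sd).
- Degenerate inputs: empty fragment sets are an error in occupancy but a
  warning in simulation (zero depth); all-zero tracks cannot be normalized;
  chi-square zero margins return (0, 1); genes missing a flank are excluded
  from NFR analyses with a logged reason.
- Benchmark problem sizes: 200 genes × 3 conditions × ~14 nucleosomal
  positions at 50× depth (~120k fragments/condition on a ~600 kb genome),
  chosen so the whole benchmark including a doubled determinism run
  completes in well under a minute on one CPU while leaving wide margins on
  every recovery threshold.

## Known limitations

- The occupancy estimator is a stand-alone kernel smoother, not a wavelet
  decomposition; absolute peak heights depend on the chosen bandwidth.
- The chi-square on genome-wide totals treats fragments as independent;
  real MNase libraries are overdispersed, so q-values on real data are
  anti-conservative and the fold filter should carry the weight.
- The −1/NFR definitions assume a called +1; promoters with fragile or
  absent +1 nucleosomes are excluded rather than modelled.
- 3′ NFRs are only visible in the stop-codon metagene; no 3′ NFR calling
  is performed.
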