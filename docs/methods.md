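# Methods

## CGH conservation calling

### Signal processing

Input is a probe-level two-channel intensity table (one row per spot:
foreground and local-background mean/SD per channel, probe→gene map with
genome order). The stages, in run order:

1. **Probe QC.** A spot is eliminated iff its reference-channel
   foreground is *strictly* lower than 2 × the local-background SD; a
   spot at exactly the boundary is retained. The test channel is not
   consulted by default (`qc_channel="ref"`): a dim test signal is the
   biology being measured, not a defective spot. `qc_channel="both"` is
   available for arrays whose spot quality must be ascertained in both
   channels. Spots with missing background statistics are eliminated and
   recorded as per-spot errors without aborting the run.
2. **Ratios.** log2(test_fg / ref_fg) per retained spot, with no
   background subtraction anywhere.
3. **Normalization.** A single additive log2 shift. Two methods:
   - `"none"` (default): s = 0. Correct when both channels are on a
     common absolute scale (equal labelled-DNA input, equal scanner
     gain), which is the regime the simulator emits and the only one in
     which a genuine species-level efficiency shift (the conserved-peak
     mode at −1 in inter-species comparisons) survives into the final
     distribution.
   - `"total"`: s = log2(Σ ref_fg / Σ test_fg) over retained spots,
     equalizing channel totals. Appropriate for uncalibrated
     *intra-species* arrays, where gene content is nearly shared and the
     total is dominated by conserved genes. It must not be used when an
     inter-species efficiency shift is of interest: because the final
     distribution under total equalization is invariant to any global
     test-channel gain, a truth with conserved fraction f at per-gene
     efficiency 2^m is always relocated to a conserved peak near
     −log2(f·2^m + ε) > 0 — the global shift is mathematically
     unrecoverable from totals. This is why the shift, not the method, is
     reported: the normalization applied is part of the result.
4. **Summarization.** Per gene, the median of its surviving probes'
   log2 ratios (even counts: midpoint of the two central values). Genes
   with fewer than `min_probes` (default 2) surviving probes get no
   median: they are flagged `no_call` rather than absent, so QC dropout
   is never conflated with divergence.
5. **Calling.** `conserved` iff median ≥ threshold (default −3.5,
   inclusive); else `absent_divergent`; `no_call` genes are excluded
   from the conserved-fraction denominator (the fraction is over
   array-detectable genes).

### Histogram and classification

Ratio histograms use fixed left-closed bins `[k·w, (k+1)·w)` aligned to
0; the mode is the center of the highest-count bin, ties broken toward
the bin nearer 0. The default bin width is 0.1 log2 units: mode
granularity is then 0.05, fine enough to locate a zero-centered
self-hybridization peak within ±0.1 and an inter-species conserved peak
within ±0.15 of −1. (A coarser 0.25 width is usable per call, but with
edge-aligned bins its mode granularity is ±0.125, too coarse for those
checks by construction.)

`classify_profile` labels a profile `intra_species` iff mode ≥ −0.5
**and** conserved fraction ≥ 0.7 (both inclusive, both configurable);
these cutoffs operationalize the qualitative contrast between
zero-centered/high-conservation profiles and shifted/low-conservation
ones, and sit roughly midway between the two observed regimes (mode 0
vs −1; fractions ~0.83 vs ~0.51).

### Reconciliation with DDH

`reconcile_global_intensity(f, m) = 100 · f · 2^m` converts a conserved
fraction f and conserved-peak mode m into the percentage of global
hybridization signal the test strain retains — the quantity a
whole-genome DDH (re-association) assay measures. It is exact under the
idealization that conserved genes all hybridize at 2^m relative
efficiency and non-conserved genes contribute nothing.

### Multi-strain comparison

Joint categories over 2 (4 categories) or 3 (8 categories) strains are
computed per gene after an inner join on gene id; genes `no_call` in any
compared strain are excluded from every category and reported
separately, since a filtered gene carries no evidence either way.
Variable-region detection finds maximal genome-order runs of a target
call class, bridging up to `max_gap` (default 1) interior genes of
another class, discarding runs with fewer than `min_run` (default 3)
target genes; region coordinates are exported 0-based half-open over
gene index (the genome map operates on gene order, not base pairs).

## Synthetic data generator

The generator emulates one two-color array of a test strain against a
sequenced reference:

- **Genome**: n ordered genes (default free parameter, 2000 in the
  shipped study-scale checks), each tiled by 5 or 6 probes (uniform).
- **Truth**: a conserved fraction, with the non-conserved remainder
  split between `absent` and `diverged` (default: half and half —
  hybridization data cannot distinguish the two, so neither is
  privileged) and placed as `n_variable_regions` contiguous blocks
  (sizes uniform on [3, 15]) plus scattered singletons, at least 3
  conserved genes apart while space allows — mirroring the clustering
  of strain-variable loci (mobilome islands, sugar operons) in real
  genomes. Dense truths (small conserved fractions) necessarily relax
  the separation once singleton slots run out.
- **Signal** (per spot, log2 scale): gene effect A_g ~ N(μ, σ_gene)
  with μ = 13 over a lognormal background of mean 100 (SD 30) — a
  signal:background ratio around 80:1 for a typical present gene, in
  line with real two-color array dynamics; probe effect
  P_p ~ N(0, σ_probe = 0.5) shared by both channels (same physical
  spot); independent channel noise N(0, 0.25). The test channel adds
  the strain's global `efficiency_shift` and, for diverged genes,
  subtracts 0.35 log2 units per mismatched base with mismatches =
  round(divergence × 60) over the 60-mer (default divergence 0.3 → 18
  mismatches, ~−6.3 log2: linear attenuation is the minimal model that
  cleanly separates the diverged from the conserved peak). Absent genes
  draw their test foreground from the background distribution alone.
  The local background is drawn once per spot and shared by both
  channels, so a noiseless self-hybridization has ratio exactly 1 at
  every spot.

At μ = 13 the background floors the test/ref ratio of an absent gene
around log2(100/8300) ≈ −6.4, safely below −3.5 even for dim genes.
(At lower signal levels the dimmest absent genes rise above the cutoff —
a real array-CGH failure mode, but not part of the emulated study
conditions.)

What the generator does **not** emulate: dye-swap/labelling bias,
spatial print-tip effects, probe-sequence-specific thermodynamics,
cross-hybridization between paralogs, and saturation. Passing recovery
tests therefore demonstrate correctness of the analysis chain under a
well-behaved signal model, not robustness to those artefacts on real
scans.

## Numerical taxonomy

- **Encoding**: + → 1, − → 0, d (variable) → 0.5 by default — the
  symmetric choice for a state meaning "sometimes positive"; `negative`
  (d → 0) and `positive` (d → 1) schemes are exposed because the
  historical treatment of "d" in phenotype matrices is rarely recorded.
  Growth characters are treated identically to fermentation characters.
- **Similarity**: Pearson r between strain character vectors × 100.
  A zero-variance vector has no defined correlation; its pairs are set
  to 0 (maximal ignorance on this scale) with a warning, rather than
  aborting the run.
- **UPGMA**: iteratively join the pair with *maximal* similarity; the
  merged cluster's similarity to any other is the size-weighted
  arithmetic mean (equivalently: the mean over all cross leaf pairs).
  Node heights are join similarities, non-increasing from leaves (100)
  to root; average linkage is reducible, so no inversions can occur.
  Ties are broken by lexicographic strain-id order (each cluster
  represented by its smallest leaf id) to make results reproducible
  across platforms — the tie conventions of the historical GUI packages
  are unknowable.
- **Newick export**: branch length = (child height − parent height)/2,
  i.e. ultrametric depth (100 − h)/2; internal labels carry the join
  similarity. Newick files deliberately carry no `#` header (illegal in
  the format); all tabular outputs carry a header comment stating their
  coordinate convention and the config hash.
- **DDH**: per replicate (membranes and DNA aliquot amounts pooled
  equally), relative value = 100 × signal(target)/signal(self); table
  cells are mean ± SD over replicates, self cells fixed at exactly 100
  with SD omitted. Values above 100 are legal (a non-self target can
  out-hybridize the self dot).

The packaged fixtures are the printed 26-strain × 29-character
phenotype table and the 26 × 6 DDH relative re-association table of the
*L. acidophilus*-group study the pipeline was validated against.

## Problem sizes and determinism

Study-scale checks simulate 2000-gene genomes (~11,000 spots) — the
size of a small lactobacillus genome and large enough that a ±0.02
recovery tolerance on conserved fractions is meaningful. Oracle
equivalence checks use 100 random ≤7-leaf matrices for UPGMA and
hundreds of random profiles for set algebra. All randomness flows
through `numpy.random.default_rng` seeds; identical seeds reproduce
byte-identical tables, and the end-to-end pipeline is deterministic
given config + seed.

## Known limitations

- The −3.5 cutoff is a hard threshold; borderline genes flip with probe
  noise. No mixture-model/EM alternative is provided (deliberately out
  of scope — the validated procedure uses the fixed cutoff).
- Total-equalization normalization cannot recover global efficiency
  shifts (see above); analyses of uncalibrated inter-species arrays
  therefore carry an unavoidable scale ambiguity that only external
  calibration (spike-ins, self-self arrays) can resolve.
- GEO ingestion handles series-matrix text at the processed level the
  series provides; when that level is already-normalized ratios, probe
  QC and normalization are skipped and results depending on them are
  approximate.
- Variable-region detection operates on gene order only; rearrangements
  between test and reference genomes are invisible to it.
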