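# Methods

## The measurement model

Clone-based NOMe-seq reads chromatin structure one molecule at a time.
M.CviPI methylates cytosines in GpC context wherever the enzyme can
physically reach the DNA; nucleosomes and stably bound proteins block
it. Bisulfite conversion then deaminates unmethylated cytosines to
uracil (read as T) while methylated cytosines resist. A sequenced
clone is therefore a binary accessibility trace over the amplicon's
GpC sites, and independently a binary endogenous-methylation trace
over its CpG sites.

The two signals are separated purely by sequence context of the
cytosine, with the standard resolution of the overlap:

| class | definition | read as |
|-------|------------|---------|
| GCH | G·C, next base ≠ G | accessibility (exogenous enzyme) |
| HCG | C·G, previous base ≠ G | endogenous methylation |
| GCG | G·C·G | confounded — always called ambiguous |
| CH  | any other C | bisulfite-conversion control |

A boundary cytosine with a missing neighbour is treated as if the
neighbour were H (non-G): a terminal `GC` is still GCH. Positions are
0-based indices of the C; display labels convert to signed kb from a
genomic anchor (a TSS), e.g. `-9.9 kb`.

Calling polarity at GCH sites: a retained C means the enzyme reached
the site — the molecule was *accessible* there; a converted T means
*inaccessible*. At HCG sites retained means methylated.

## Alignment and calling

Clones are registered to the fully converted reference (every C → T)
by global alignment with free end gaps (Biopython `PairwiseAligner`,
match +1, mismatch −1, internal gap open −4, extend −1). At
reference-cytosine columns a clone C or T both score as a match — the
C/T degeneracy of bisulfite data, applied asymmetrically and on the
top strand only (clones model the bisulfite-converted sense strand;
bottom-strand GpC calling is out of scope). Identity QC uses only the
non-degenerate columns, where chemistry predicts exact agreement;
clones below 80% identity, or deviating more than 20% in length, are
rejected with a reason.

Per clone, conversion efficiency is the converted fraction of CH
control cytosines; clones under 0.95 are dropped, as are clones with
more than 20% ambiguous calls over GCH+HCG reporter sites (GCG sites
are excluded from this fraction since they are ambiguous by
construction). These thresholds are conventional clone-screening
values, configurable at the CLI; a run in which every clone fails QC
is an explicit error, never a silent empty table.

## Statistics

**Per-site inaccessibility** is
100·n_inaccessible/(n_inaccessible + n_accessible). "Total molecules"
means molecules with a determinate call at that site; a site where
every molecule is ambiguous is undefined (NaN), never 0.

**Windowed profile**: unweighted mean of per-site percentages over
GCH sites within fixed 100-bp windows tiling the amplicon — averaging
over sites, not bp-interpolated, as the simplest reading of averaging
over a distance. Empty windows are flagged, not interpolated.

**Condition comparison** tests one GpC site per 100-bp window — the
site nearest the window center, ties toward the smaller coordinate
(pooling sites per window would mix heterogeneous sites; nearest-to-
center is one defensible, documented, configurable choice). The
default test is Pearson chi-square on the 2×2
condition × (accessible, inaccessible) table, df = 1, no continuity
correction. p-values are reported per site without multiple-testing
adjustment by default; Benjamini–Hochberg is available via a flag. A
zero margin leaves the statistic undefined and the site flagged.

**Exact option.** At clone depth (n ≈ 15 per condition) the classical
Fisher test is badly conservative: exact enumeration over binomial
nulls with p ∈ {0.3, 0.5, 0.7} gives a true size of ~0.017 at nominal
0.05. The `midp` option (default exact method) instead sums the
probability of conditional tables strictly less likely than the
observed one plus half the probability of equally likely tables; its
enumerated size is 0.040–0.043 at the same operating points, which is
the behaviour a calibrated test should have. The conservative Fisher
p-value remains available as `method="fisher"`.

**Footprints** are maximal runs of inaccessible GCH sites per
molecule. Ambiguous sites neither break a run nor extend its ends;
the span is measured between the outermost inaccessible sites,
inclusive, with no extrapolation toward flanking accessible sites
(conservative: the called span is bounded by the GpC grid, so a
147-bp nucleosome on a 10-bp grid can show at most a 141-bp span).
Runs with span ≥ 150 bp are classified nucleosome-sized. Open runs
(NDR candidates) are the exact dual with threshold 147 bp — the DNA
length a nucleosome core covers. Run-length rules only; no HMM or
changepoint segmentation.

**CpG-rich regions** follow the Takai–Jones scan: 200-bp windows
stepping 1 bp must reach %GC ≥ 55 and obs/exp CpG ≥ 0.65, where
obs/exp = n_CpG·L/(n_C·n_G) (defined 0 when a window lacks C or G);
overlapping qualifying windows are merged, each merged region is
trimmed to begin and end at a CpG (skipped when it contains none,
which keeps degenerate-threshold scans meaningful), and the trimmed
region must re-satisfy both ratios plus a 500-bp minimum length. All
three thresholds are configurable; the trimming step is what makes a
clean construct (a CG repeat in A/T filler) come out with exact
boundaries rather than half-window overhangs.

**qPCR.** Percent of input is the dilution-adjusted ΔCt,
100·f·E^(Ct_input − Ct_IP), with amplification efficiency E = 2.0 by
default (configurable per primer pair; no standard curves are
modelled). FAIRE uses the same form with the aqueous-phase DNA as
numerator. Expression is ΔΔCt against a reference gene. Replicate
summaries are mean and range (min/max), not SD — the convention for
duplicate PCR reactions — and ranges propagate through ratios by
min/max arithmetic. Input dilution fractions are required metadata on
every record.

## The simulator

The generator emulates the study conditions a clone experiment
presents, with ground truth emitted as a sidecar table keyed by clone
id so tests never re-infer it from sequence:

- **Reference plan**: GpC dinucleotides on a regular grid (default
  examples use 20 bp; footprint-resolution studies use 10 bp), CpG
  dinucleotides concentrated in declared blocks, optional isolated-C
  conversion controls, and all filler drawn from {A, T} so no
  accidental cytosine context can arise. Deterministic per seed.
- **Chromatin states**: each clone samples one cell state by weight; a
  GpC inside that state's protected intervals is accessible with the
  leakage probability (default 0), outside with the linker
  accessibility. Enzyme action, state sampling and conversion are
  independent Bernoulli events; the two sequential enzyme incubations
  of the bench protocol collapse into one efficiency parameter.
- **Chemistry noise**: unmethylated C → T with the conversion rate,
  methylated C → T with the inappropriate-conversion rate, then
  uniform substitution errors. Achieved conversion efficiencies and
  clone-rejection criteria are not fixed by the protocol this models,
  so they are free parameters with perfect-chemistry defaults.
- **Clone depth**: 15 clones per amplicon per experiment by default —
  the sequencing depth of a typical clone-based study.
- **Ct tables**: Ct = baseline − log2(quantity) + N(0, sd). `noise_sd`
  applies to assay reactions; INPUT reference reactions default to
  noiseless (`input_noise_sd = 0`, configurable), reflecting that the
  input aliquot is quantified from abundant template. With sd = 0,
  percent-input recovers the simulated recovery fraction exactly.

What the simulator does **not** model: Sanger chromatogram noise,
cloning-vector sequence, PCR duplicates, strand-specific artefacts,
or correlated nucleosome positioning between molecules beyond the
state mixture. Passing tests therefore demonstrate correctness of the
computation under the stated generative model, not robustness to
every artefact of real clone data.

## Numerical and interface choices

- Seeds: every generator takes an explicit integer seed
  (`numpy.random.default_rng`); the CLI derives per-condition seeds
  from the run seed, kept below 2³¹. Identical seeds give
  byte-identical text outputs.
- TSV outputs use a fixed `%.6g` float format and POSIX newlines so
  determinism is testable at the byte level; BED intervals are 0-based
  half-open with name = clone id and score = span.
- Undefined quantities (all-ambiguous sites, zero margins, zero
  denominators) are NaN plus an explicit flag, never silently 0, and
  zero-denominator ratios raise.
- The problem sizes used by the verification script — 200 clones for
  parameter recovery, 1000 replicate site-tests at n = 15 for null
  calibration, 30 clones for footprint recovery, 100 random ≤2-kb
  sequences for the island-scan oracle — are chosen so each property
  has comfortable statistical headroom while the whole script stays
  quick to re-run.

## Known limitations

- Amplicon/clone scale only: no genome-wide NOMe-seq, no paired-end
  short reads, no bottom-strand calling.
- The chi-square comparison treats molecules as independent draws;
  clones from the same PCR are assumed deduplicated upstream.
- Footprint spans under-estimate true protected intervals by up to
  one GpC spacing per boundary (no midpoint extrapolation); an
  alternative span convention is a flagged option at the API level.
- Ct quantification starts from called Ct values; raw fluorescence
  processing is out of scope.
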