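# nomeamp

Single-molecule chromatin accessibility (clone-based NOMe-seq),
bisulfite CpG-methylation mapping, and ChIP/FAIRE/qRT-PCR
quantification for amplicon-scale studies of regulatory elements —
the desk half of a locus-resolution chromatin-structure experiment
such as dissecting an estrogen-responsive enhancer in breast cancer
cells.

## What it computes

**NOMe-seq.** Intact chromatin is treated with the GpC
methyltransferase M.CviPI, which methylates GpC cytosines only where
DNA is free of nucleosomes and bound proteins. After bisulfite
conversion, every unmethylated C reads as T, so each sequenced clone
is a single-molecule accessibility footprint. Cytosines are classified
by context: **GCH** (GpC not followed by G) report accessibility,
**HCG** (CpG not preceded by G) report endogenous methylation, **GCG**
are confounded and excluded, remaining **CH** cytosines are
conversion controls. Per GpC site,

```
percent inaccessibility = 100 · n_inaccessible / (n_inaccessible + n_accessible)
```

with ambiguous molecules excluded; profiles are averaged in 100-bp
windows. Conditions are compared per site (one GpC site per 100 bp) by
Pearson chi-square on the 2×2 accessible/inaccessible table (df = 1),
with a mid-p exact option for clone-depth samples. Per molecule,
maximal runs of inaccessible GpC sites become footprints, classified
nucleosome-sized when their span reaches ~150 bp; accessible runs of
≥147 bp are nucleosome-depleted-region (NDR) candidates.

**Methylation maps.** The same alignment/calling machinery read at HCG
sites yields per-clone lollipop maps and per-site percent methylation;
a Takai–Jones-style sliding-window scan (200-bp windows, %GC ≥ 55,
obs/exp CpG ≥ 0.65, length ≥ 500 bp) finds CpG-rich regions, where
obs/exp = n_CpG·L / (n_C·n_G).

**qPCR.** ChIP and FAIRE signals use the dilution-adjusted ΔCt,
`% input = 100 · input_fraction · E^(Ct_input − Ct_IP)` (E = 2 by
default); expression uses ΔΔCt against a reference gene (e.g. GAPDH).
Replicates are summarised as mean and min/max range, and ranges
propagate through enrichment and induction ratios.

**Simulator.** Every stage is testable against ground truth: clones
are drawn from a mixture of per-cell chromatin states (protected
intervals vs. accessible linkers, with enzyme efficiency, bisulfite
conversion/inappropriate-conversion rates and sequencing error), and
Ct tables are generated as `Ct = baseline − log2(quantity) + noise`.

## Worked example

```python
import nomeamp as na
from nomeamp.pipeline import call_clones

# amplicon with a GpC every 20 bp; one state with a nucleosome at 200-350
ref = na.make_reference(600, 20, seed=1)
model = na.ChromatinStateModel(states=(
    na.CellState(weight=1.0, protected_intervals=((200, 350),),
                 linker_accessibility=1.0),))
sim = na.simulate_clones(ref, model, noise=na.NoiseModel(seed=3),
                         n_clones=15)
matrix, rejected = call_clones(ref, sim.clones)
stats = na.site_stats(matrix)
print(stats.loc[stats.site.between(200, 350),
                "percent_inaccessible"].unique())   # [100.]
print(stats.loc[~stats.site.between(200, 350),
                "percent_inaccessible"].unique())   # [0.]
fp = na.call_footprints(matrix, min_span=150)[0]
print(fp.start, fp.end, fp.span, fp.classification)
# 211 331 121 SUBTHRESHOLD
```

All 15 molecules are fully protected between 200 and 350 bp and fully
accessible elsewhere; the footprint spans the outermost inaccessible
GpC sites (211–331 on this site grid inside the 150-bp protected
interval), so its 121-bp span stays below the nucleosome-sized
threshold — the called span is bounded by the GpC grid, not the true
interval.

The same pipeline runs from the shell:

```sh
nomeamp simulate --config sim.yaml --out-dir sim
nomeamp call --reference sim/reference.fasta \
             --clones sim/clones_ethanol.fasta --out-dir call_etoh
nomeamp nome --calls call_etoh/calls.tsv \
             --reference sim/reference.fasta --out-dir nome_etoh
nomeamp compare --calls-a call_etoh/calls.tsv --calls-b call_e2/calls.tsv \
                --reference sim/reference.fasta --out-dir cmp
```

Each stage writes TSV/BED/SVG outputs and a `manifest_<stage>.json`
with parameters and output checksums.

## Layout

- `src/nomeamp/reference.py` — amplicon references, context classification
- `src/nomeamp/simulate.py` — chromatin-state, clone and Ct simulators
- `src/nomeamp/align.py`, `calls.py` — bisulfite-aware alignment, calling, QC
- `src/nomeamp/nome_stats.py` — accessibility statistics, tests, footprints
- `src/nomeamp/methylation.py` — methylation maps, CpG-rich region scan
- `src/nomeamp/qpcr.py` — percent-input, folds, ΔΔCt, locus profiles
- `src/nomeamp/cli.py`, `pipeline.py`, `io.py`, `plotting.py` — wiring
- `docs/methods.md` — models, parameters, design choices, limitations
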