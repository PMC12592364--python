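# compartshift

Downstream Hi-C and chromatin-track analysis for studies of A/B compartment
reorganisation — for example the question of whether a chromatin-assembly
perturbation (loss of a histone chaperone) moves genomic regions between the
active A and inactive B compartments, weakens compartmentalisation, or
shifts early-replication initiation-zone sites between compartments. The
package bundles every stage of such an analysis as a tested library, together
with a synthetic-data generator that plants known structure so each stage can
be validated against ground truth without any sequencing data.

## What it computes

* **Contact-map core** — sparse-triplet import, blacklist masking, iterative
  correction (ICE) balancing (single-pass or converged), per-arm expected
  contacts, observed/expected (O/E) maps, P(s) decay curves, cis/trans QC
  ratios, and 1 Mb log2 differential maps.
* **Compartments** — per-chromosome EV1: the leading eigenvector of the
  double-centred Pearson correlation matrix of O/E columns, scaled by
  √|eigenvalue| and sign-oriented by GC content. Positive EV1 = compartment
  A. Domains are maximal same-sign runs. A bin *switches* between two
  conditions only when its EV1 sign changes in the same direction in **both**
  replicate cell lines. Saddle plots average O/E over 50×50 EV1-percentile
  pairs; corner means quantify compartmentalisation strength.
* **Insulation** — 100 kb diamond-window insulation score at 10 kb bins,
  normalised per chromosome as log2(window mean / mean of window means);
  borders are prominent local minima; border sets are compared with greedy
  one-to-one matching at ±20 kb.
* **Tracks** — fragment binning (midpoint rule), cpm, log2(IP/input),
  per-chromosome z-scores, smoothing over non-zero bins, log2(cpm+1) RNA
  scaling, with unit tags that enforce the pipeline order.
* **Sites** — stack-up heatmaps and size-windowed mean profiles around site
  midpoints, per-site mean EV1 (50 kb → 10 kb piecewise-constant re-binning),
  quadrant switching classification (A-to-B / B-to-A / stable) summarised as
  mean ± SD across cell lines, randomised size- (and compartment-) matched
  controls, and rank-test group comparisons.
* **Statistics** — two-tailed Mann-Whitney U (exact enumeration for small
  samples, tie-corrected normal approximation otherwise) and
  Benjamini-Hochberg FDR, with the `*/**/***` significance convention.
* **Synthetic data** — contact maps with power-law distance decay modulated
  by planted compartment signs (`E[c_ij] ∝ |i−j|^(−α) · exp(κ·s_i·s_j)`,
  Poisson counts), planted TAD blocks, IP/input tracks with log-scale
  enrichment β in A bins or at site boundaries, and log-uniform site sets.

## A worked example

```bash
python examples/01_compartments_from_simulation.py
```

```
bins with defined EV1: 1200 of 1200
Pearson r between EV1 and planted sign: 0.969
called domains: 61 (A: 31, B: 30)
```

The simulation plants alternating A/B blocks (mean 1 Mb) on two 30 Mb
chromosomes and draws ~1.5 million cis contacts with compartment strength
κ = 0.4. The EV1 track recovers the planted signs almost perfectly
(r = 0.97), and the called domains alternate between A and B as planted.
The other examples cover switching + saddles, TAD borders, the track
normalisation chain, and the site quadrant analysis; each prints the numbers
it computes with a closing comment on how to read them.

The full pipeline also runs from the shell:

```bash
compartshift run --outdir out --seed 3
```

writing EV1 bedGraphs, domain/switch BED files, saddle and border TSVs, the
site quadrant tables and a markdown report.

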