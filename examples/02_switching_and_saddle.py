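"""Concordant compartment switching between conditions, plus saddle corners.

Plants 5% of bins to switch sign between a WT-like and a KO-like condition
concordantly in two replicate cell lines, calls EV1 four times, classifies
per-bin switching (a switch requires the same sign change in both lines) and
summarises compartmentalisation strength as saddle corner means.
"""

import numpy as np

import compartshift as cs

genome = cs.GenomeSpec((("chr1", 30_000_000), ("chr2", 30_000_000)), 50_000)
truth = cs.generate_compartment_profile(genome, 1_000_000, switch_fraction=0.05,
                                        concordant=True, seed=10)
params = cs.SimParams(compartment_strength=0.4, sequencing_depth=1.5e6)
gc = cs.gc_track(truth, seed=11)

ev = {}
oe_wt = None
for line in range(2):
    for cond in range(2):
        cmap = cs.simulate_hic(truth, params, seed=20 + 2 * line + cond,
                               line=line, condition=cond)
        bal = cs.ice_normalize(cmap, tol=1e-5)
        oe = cs.observed_over_expected(bal, cs.expected_cis(bal))
        ev[(line, cond)] = cs.compute_ev1(oe, gc)
        if (line, cond) == (0, 0):
            oe_wt = oe

switch = cs.classify_switch_bins(ev[(0, 0)], ev[(0, 1)], ev[(1, 0)], ev[(1, 1)])
print(f"switching bins: {switch.counts()}")
print(f"genome proportion switching: {100 * switch.proportion():.2f}% "
      f"(planted: {100 * truth.switch_bins.size / genome.n_bins:.2f}%)")

sad = cs.saddle(oe_wt, ev[(0, 0)], n_quantiles=50)
print(f"saddle corners  AA: {sad.corner_mean('AA'):.2f}  "
      f"BB: {sad.corner_mean('BB'):.2f}  AB: {sad.corner_mean('AB'):.2f}")
# AA/BB corner means above 1 and AB below 1 quantify preferential same-
# compartment contact; the switching proportion matches the planted fraction.
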