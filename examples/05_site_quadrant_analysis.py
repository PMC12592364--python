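"""Site-level compartment quadrant analysis with a randomised control.

Generates a site set, computes per-site mean EV1 in two conditions (with 5%
of bins planted to switch), classifies each site into switching quadrants
(A-to-B, B-to-A, stable) per cell line, and compares the switching
proportion with a size-matched randomised control.
"""

import compartshift as cs

genome = cs.GenomeSpec((("chr1", 40_000_000), ("chr2", 40_000_000)), 50_000)
truth = cs.generate_compartment_profile(genome, 1_000_000, switch_fraction=0.05,
                                        concordant=True, seed=30)
params = cs.SimParams(compartment_strength=0.4, sequencing_depth=1.6e6)
gc = cs.gc_track(truth, seed=31)

ev = {}
for line in range(2):
    for cond in range(2):
        cmap = cs.simulate_hic(truth, params, seed=40 + 2 * line + cond,
                               line=line, condition=cond)
        bal = cs.ice_normalize(cmap, tol=1e-5)
        ev[(line, cond)] = cs.compute_ev1(
            cs.observed_over_expected(bal, cs.expected_cis(bal)), gc)

sites = cs.generate_sites(genome, 80, (40_000, 200_000), seed=50)
random_sites = cs.randomize_sites(sites, genome, seed=51)

pairs = [(cs.site_mean_ev1(ev[(line, 0)], sites),
          cs.site_mean_ev1(ev[(line, 1)], sites)) for line in range(2)]
rand_pairs = [(cs.site_mean_ev1(ev[(line, 0)], random_sites),
               cs.site_mean_ev1(ev[(line, 1)], random_sites)) for line in range(2)]

table = cs.cross_line_quadrants(pairs)
rand_table = cs.cross_line_quadrants(rand_pairs)

print("site quadrant proportions (mean ± SD over two cell lines):")
for _, row in table.iterrows():
    print(f"  {row['category']:>9}: {row['mean']:.3f} ± {row['sd']:.3f}")
sw = table.set_index("category").loc["switching"]
rsw = rand_table.set_index("category").loc["switching"]
print(f"switching  sites: {sw['mean']:.3f} ± {sw['sd']:.3f}   "
      f"random control: {rsw['mean']:.3f} ± {rsw['sd']:.3f}")
# With planted switches both site and control proportions sit near the
# planted 5% bin-flip rate; a site-specific effect would separate them.
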