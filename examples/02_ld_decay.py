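"""LD decay profile and the H statistic for one population.

Computes genotype-correlation r^2 for all SNP pairs within 500 kb, bins by
distance into 100 five-kb bins, and sums the per-bin means into the scalar
H statistic (an area-under-the-curve analog: 0 = no LD, 100 = perfect LD
everywhere). Populations with stronger bottlenecks show larger H.
"""

import breedscan as bs

cfg = bs.SimConfig(seed=3, n_chrom=1, chrom_length=1_000_000,
                   n_wolf=9, n_indigenous=9, n_chow=9)
panel = bs.simulate_panel(cfg)

for pop in ("wolf", "indigenous", "chow"):
    pairs = bs.pairwise_r2(panel, max_dist=500_000, samples=pop)
    prof = bs.ld_profile(pairs)
    near = prof.bins["mean_r2"].iloc[0]
    far = prof.bins["mean_r2"].iloc[-1]
    print(f"{pop:12s} H = {prof.H:6.2f}   mean r2: {near:.3f} at <5 kb "
          f"-> {far:.3f} at 500 kb   ({len(pairs)} pairs)")

print("\nH sums mean r^2 over the 100 distance bins; the bottlenecked "
      "chow shows the slowest LD decay and the largest H.")
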