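"""Call A/B compartments and find where they differ between groups.

The compartment signal is the leading eigenvector of the Pearson
correlation of the O/E map, oriented so positive = A (active). A bin is
differential when its eigenvector moves by more than 0.42 (one quartile
shift) between conditions. The demo world plants a 40-bin sign flip on
chrX in the Pro group, emulating an A<->B switch.
"""

import numpy as np

from cyclehic import compartments as comp
from cyclehic import contacts as ct
from cyclehic.genome import intervals_per_bin
from cyclehic.simulate import demo_spec, generate

ds = generate(demo_spec(seed=1))
activity = intervals_per_bin(ds.atac, ds.bins)  # sign orientation proxy

tracks = {}
for cond in ("Die", "Pro", "Male"):
    balanced = ct.balance(ct.sum_maps(ds.maps[cond]))
    tracks[cond] = comp.call_eigenvector(balanced, orient_track=activity)

for name, other in [("Pro_vs_Die", "Pro"), ("Male_vs_Die", "Male")]:
    diffs = {
        chrom: comp.diff_compartments(tracks[other][chrom], tracks["Die"][chrom])
        for chrom in tracks["Die"]
    }
    print(name)
    print(comp.diff_summary(diffs, ds.bins.bin_size).to_string(index=False))
    res = comp.compare_groups(diffs, sex_chroms={"chrX"})
    print(f"  X vs autosome |delta| rank-sum p = {res['p_value']:.2g} "
          f"(medians {res['median_x']:.3f} vs {res['median_autosome']:.3f})")

# do the two contrasts move bins in the same direction?
d1 = {c: comp.diff_compartments(tracks["Pro"][c], tracks["Die"][c]) for c in tracks["Die"]}
d2 = {c: comp.diff_compartments(tracks["Male"][c], tracks["Die"][c]) for c in tracks["Die"]}
conc = comp.direction_concordance(d1, d2)
print(f"direction concordance Pro|Male vs Die: {conc['agreement']:.2f} "
      f"(rho={conc['rho']:.2f}, n={conc['n']})")
print("-> only chrX carries differential bins (the planted flip), and the "
      "two contrasts agree in direction on the shared window.")
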