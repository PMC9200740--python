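"""Call significant interactions, strip CTCF loops, classify E-P / E-E /
P-P, and find differential enhancer-promoter contacts.

Significance is a one-pass binomial distance model (equal-occupancy
distance strata, BH q < 0.05). Anything within 20 kb of a called CTCF
loop is removed as "a loop, not an E-P contact". Enhancers are ATAC peaks
more than 10 kb from every TSS; a differential interaction needs z > 2
and a >= 2.5-fold change, like loops.
"""

from cyclehic import contacts as ct
from cyclehic import interactions as ia
from cyclehic import loops as lp
from cyclehic.simulate import demo_spec, generate

ds = generate(demo_spec(seed=1))

maps, zmaps, sets = {}, {}, {}
for cond in ("Die", "Pro"):
    m = ct.sum_maps(ds.maps[cond])
    _, expected, z = ct.prepare(m)
    maps[cond], zmaps[cond] = m, z
    sets[cond] = lp.call_loops(z, m, expected, sample=cond)

master = lp.merge_master(list(sets.values()), bin_size=ds.bins.bin_size)
pooled = ct.sum_maps(list(maps.values()))

sig = ia.call_significant(pooled, q_max=0.05)
print(f"significant pixels (q<0.05): {len(sig)}")
sig = ia.exclude_loops(sig, master, ds.bins, radius_bp=20_000)
print(f"after 20-kb CTCF-loop exclusion: {len(sig)}")

ann = ia.build_bin_annotation(ds.bins, ds.atac, ds.tss, enhancer_min_dist=10_000)
sig = ia.classify(sig, ann)
print("categories:", sig["category"].value_counts().to_dict())

diff = ia.diff_interactions(sig, zmaps["Die"], zmaps["Pro"], labels=("Die", "Pro"))
ep = diff[(diff["category"] == "E-P") & diff["flagged"]]
print(f"differential E-P interactions: {len(ep)}")
print(ep[["chrom", "bin1", "bin2", "z_Die", "z_Pro", "fold", "direction"]]
      .to_string(index=False))
print("-> the planted E-P losses survive loop exclusion (they are diffuse, "
      "not punctate) and are flagged in the Die direction.")
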