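"""Call differentially expressed genes per injury stage and partition them.

A gene is DE when its floored fold change exceeds 2 in either direction and
an unpaired two-sided t-test on replicate FPKMs gives p < 0.05.  The Venn
partition shows stage-specific versus shared responses.
"""

import sciseq

cfg = sciseq.SimulationConfig(n_genes=2000, seed=1)
study, truth = sciseq.simulate_study(cfg)
floored = sciseq.floor_fpkm(study, floor=0.1)

de_2d = sciseq.call_de(floored, ("D2", "CTR"))
de_7d = sciseq.call_de(floored, ("D7", "CTR"))
venn = sciseq.venn_partition(de_2d, de_7d)

for name, table in (("2 d", de_2d), ("7 d", de_7d)):
    n = int(table["is_significant"].sum())
    up = int((table["is_significant"] & (table["direction"] == "up")).sum())
    print(f"{name}: {n} DE genes ({up} up, {n - up} down)")
print(f"shared up: {venn.counts['up_shared']}, "
      f"shared down: {venn.counts['down_shared']}")

top = sciseq.select_top_fraction(de_2d, fraction=0.10)
print(f"top 10% up-regulated at 2 d ({len(top['up'])} genes): "
      f"{', '.join(top['up'][:5])} ...")
planted = truth.de_genes("D2_vs_CTR")
called = set(de_2d.index[de_2d["is_significant"]])
tp = len(called & planted)
print(f"vs ground truth: sensitivity {tp / len(planted):.3f}, "
      f"false discoveries {len(called) - tp}")
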