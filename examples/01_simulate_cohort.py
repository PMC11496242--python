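"""Simulate a mother-father-offspring trio cohort and inspect its genetics.

Parental genotypes at eight coffee-consumption loci are drawn under
Hardy-Weinberg equilibrium and each offspring inherits one uniformly chosen
allele from each parent, so parent-child dosage correlation sits at 0.5 by
construction. Maternal coffee intake follows a hurdle model (a consumer /
non-consumer coin, then a positive intake level for consumers).
"""

import numpy as np

from triomr import SimConfig, simulate_trios

cfg = SimConfig(seed=7, n=5000)
trios = simulate_trios(cfg)

print(f"families simulated:            {cfg.n}")
print(f"instrument variants:           {cfg.m}")

# Mendelian consistency: each child dose lies between what the parents must
# and can transmit
lo = (trios.dosage_m == 2).astype(int) + (trios.dosage_f == 2).astype(int)
hi = (trios.dosage_m > 0).astype(int) + (trios.dosage_f > 0).astype(int)
violations = int(((trios.dosage_o < lo) | (trios.dosage_o > hi)).sum())
print(f"Mendelian violations:          {violations}")

for j, v in enumerate(cfg.variants[:3]):
    r = np.corrcoef(trios.dosage_m[:, j], trios.dosage_o[:, j])[0, 1]
    maf = trios.dosage_o[:, j].mean() / 2
    print(f"{v.id:<12} offspring allele freq {maf:.3f} "
          f"(target {v.maf:.3f}), mother-child dosage corr {r:.3f}")

ph = trios.phenos
print(f"\nconsumers at week 15:          {ph['consumer'].mean():.1%}")
print(f"mean cups/day among consumers: "
      f"{ph.loc[ph['consumer'], 'coffee_wk15'].mean():.2f}")
print(f"maternal PGS sd:               {ph['pgs_m'].std():.3f}")
print(f"PGS-coffee correlation:        "
      f"{np.corrcoef(ph['pgs_m'], ph['coffee_wk15'])[0, 1]:.3f}")
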