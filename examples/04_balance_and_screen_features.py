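"""Class balancing and ANOVA feature screening.

Balances the study's healthy-group class imbalance (445/280/2172/573/
1184/1409 epochs) to 1000 per stage by seeded over/under-sampling,
then ranks synthetic features by one-way ANOVA F statistic and runs a
Fisher LSD post-hoc comparison on the top feature.
"""

import numpy as np
import pandas as pd

import somnowave as sw
from somnowave.stages import STAGES

# -- balancing on the real class imbalance (labels only, no signals) --
counts = {"W": 445, "S1": 280, "S2": 2172, "S3": 573, "S4": 1184, "REM": 1409}
labels = [s for s in STAGES for _ in range(counts[s])]
fm = pd.DataFrame({"feat": np.arange(len(labels), dtype=float), "label": labels})
balanced = sw.balance_classes(fm, sw.BalanceSpec(target_per_class=1000, seed=0))
print("balanced class counts:")
print(balanced["label"].value_counts().loc[list(STAGES)])
print(f"total after balancing: {len(balanced)} (from {len(fm)})")

# -- ANOVA screening on stage-separated synthetic features --
rng = np.random.default_rng(1)
stage_idx = np.repeat(np.arange(6), 50)
frame = pd.DataFrame({
    "separated": stage_idx * 2.0 + rng.standard_normal(300),
    "noise": rng.standard_normal(300),
    "label": np.repeat(STAGES, 50),
})
ranking = sw.rank_features(frame)
print("\nANOVA ranking (rank 1 = most discriminative):")
print(ranking[["rank", "F", "p"]].round(4))

lsd = sw.fisher_lsd(frame["separated"], frame["label"])
n_sig = int(lsd.pairs["significant"].sum())
print(f"\nFisher LSD: {n_sig}/15 stage pairs significantly different "
      f"(omnibus p = {lsd.omnibus_p:.2e})")

# the class-separated feature earns rank 1 with an underflowing
# p-value, while pure noise ranks last -- the pattern used to confirm
# that every sub-band norm carries stage information.
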