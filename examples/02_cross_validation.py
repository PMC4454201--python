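"""Leave-one-out cross-validation against the topological baseline.

Each known seed is held out in turn, mixed with 99 random control proteins,
and re-ranked by similarity to the remaining seeds.  Both methods see
identical held-out/control draws, so the AUC and mean-rank-ratio deltas
isolate what the proteomics fold changes contribute beyond topology.
"""

import numpy as np

from proteinrank import compare_methods, random_seed_control
from proteinrank.synthetic import SyntheticSpec, generate

print("paired leave-one-out cross-validation, 5 replicate studies "
      "(10 seeds, 100-protein test lists):")
deltas = []
for rep in range(1, 6):
    net, fold_changes, seeds, _ = generate(
        SyntheticSpec(model="modular", rng_seed=rep)
    )
    paired = compare_methods(net, fold_changes, seeds, rng_seed=rep)
    deltas.append(paired.auc_delta)
    print(f"  study {rep}: weighted AUC={paired.proteinrank.auc:.4f} "
          f"MRR={paired.proteinrank.mrr:.4f} | baseline "
          f"AUC={paired.topological.auc:.4f} "
          f"MRR={paired.topological.mrr:.4f} | "
          f"AUC delta {paired.auc_delta:+.4f}")
print(f"mean AUC delta (weighted - baseline): {np.mean(deltas):+.4f} "
      "(positive = fold changes help)\n")

net, fold_changes, seeds, _ = generate(
    SyntheticSpec(model="modular", rng_seed=1)
)
control = random_seed_control(net, fold_changes, k=seeds.k, rng_seed=1)
print("negative control (random proteins as seeds):")
print(f"  AUC={control.auc:.4f} MRR={control.mrr:.4f}")
print("  random seeds share no impact pattern, so performance collapses to "
      "chance or below:\n  high-fold-change control proteins outrank the "
      "held-out random seeds.")
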