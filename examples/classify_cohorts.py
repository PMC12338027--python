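"""End-to-end cohort classification on synthetic data.

Runs the whole pipeline at a reduced scale — simulate cohorts, extract the
four feature dimensions, train the boosted-tree model per contrast on the
stratified 7:3 split — and prints validation metrics for each contrast.
"""

import copy

from cfpipe import load_default_config, run_experiment

cfg = copy.deepcopy(load_default_config())
cfg["cohorts"]["healthy"]["n_subjects"] = 60
cfg["cohorts"]["benign"]["n_subjects"] = 20
cfg["cohorts"]["npc"]["n_subjects"] = 20
cfg["cnv"]["n_reference"] = 4

result = run_experiment(cfg, seed=1)
print(f"feature matrix: {result.X.shape[0]} subjects x {result.X.shape[1]} features "
      f"({', '.join(f'{b.block_name}={b.n_features}' for b in result.blocks)})")
for name, rep in result.reports.items():
    print(f"  {name:18s} AUC {rep.auc:.3f}  sens {100 * rep.sensitivity:5.1f}%  "
          f"spec {100 * rep.specificity:5.1f}%  acc {100 * rep.accuracy:5.1f}%  "
          f"(n_val {rep.extra['n_val']})")
print("Sensitivity/specificity are read at the validation-ROC Youden point; "
      "AUC is threshold-free. The harder benign-vs-NPC contrast has the "
      "smallest cohorts, mirroring the real difficulty ordering.")
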