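"""Build the relapse-risk signature and evaluate it against follow-up data.

Runs the full flow on a simulated cohort: rank-disruption DEGs between stage
I and IV, DEG-anchored significant opposite pairs, the paired FF/FFPE
concordance filter, coverage-difference (C_IVI) ranking, candidate-block
partition and selection, the strict 49% relapse vote on stage II/III
tumours, and the survival comparison of the predicted risk groups.
"""

import numpy as np

import reosig
from reosig import pipeline

cohort = reosig.simulate_cohort(reosig.SimulationConfig(seed=3))
run = pipeline.run_relapse_pipeline(cohort, block_base=200, block_step=100)

m = run.manifest
print(f"stage I vs IV rank-disruption DEGs: {m['n_degs']}")
print(f"DEG-anchored significant opposite pairs (FDR<{m['pair_fdr']}): "
      f"{m['n_deg_anchored_pairs']}")
print(f"kept after FF/FFPE concordance filter (>= {m['min_concordant']} of "
      f"{len(cohort.pairing)} pairs): {m['n_after_ffpe_filter']}")
print(f"candidate blocks: {m['block_sizes']}")
print(f"selected block {m['selected_block']} ({m['n_signature_pairs']} pairs) "
      f"at cut-off {m['selected_cutoff']:.0%}\n")

print("training selection grid (fraction correctly voted per stage):")
print(run.selection_grid.to_string(index=False))

truth = cohort.ground_truth.high_risk
acc = np.mean([(run.predictions.loc[s, "label"] == "high_risk") == truth[s]
               for s in run.predictions.index])
print(f"\nlatent-risk accuracy on stage II/III tumours: {acc:.2f}")

s = run.survival_report
print(f"predicted high risk n={s['n_high_risk']}, low risk n={s['n_low_risk']}")
print(f"log-rank chi2={s['logrank_chi2']:.2f} p={s['logrank_p']:.4f}")
print(f"Cox HR={s['hazard_ratio']:.2f} (95% CI {s['hr_ci'][0]:.2f}-{s['hr_ci'][1]:.2f}), "
      f"Schoenfeld p={s.get('schoenfeld_p', float('nan')):.2f}")
print("a hazard ratio well above 1 with a non-significant Schoenfeld test means the")
print("predicted groups separate relapse risk under proportional hazards")
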