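"""Why within-sample orderings survive FFPE degradation while magnitudes do not.

Degrades a clean cohort at increasing zero-inflation rates and reports (a)
how well each sample's gene ordering and each gene's magnitude correlate with
the clean data, and (b) the retention rate of the planted cancer signature —
the quantity the diagnosis vote relies on.
"""

import numpy as np
from scipy import stats

import reosig
from reosig import reo
from reosig.simulate import apply_ffpe_degradation

# a large signature of tightly-spaced pairs, where degradation has visible bite
cohort = reosig.simulate_cohort(
    reosig.SimulationConfig(
        seed=2, dropout_rate=0.0, noise_sd=0.0,
        n_planted_diag_pairs=136, n_planted_relapse_pairs=0, diag_pair_gap=0.04,
        n_ff_ffpe_pairs=5,
    )
)
clean = cohort.clean_expression
cancers = cohort.phenotype.loc[cohort.phenotype.group == "cancer", "sample_id"].tolist()

degraded = apply_ffpe_degradation(clean, dropout_rate=0.3, noise_sd=0.5, seed=3)
rank_corr = np.mean([stats.spearmanr(clean[s], degraded[s]).statistic for s in clean.columns])
value_corr = np.mean(
    [stats.pearsonr(clean.loc[g], degraded.loc[g]).statistic
     for g in clean.index if clean.loc[g].std() > 0 and degraded.loc[g].std() > 0]
)
print(f"dropout 0.30 + log-noise 0.5:")
print(f"  mean per-sample rank (Spearman) correlation vs clean: {rank_corr:.3f}")
print(f"  mean per-gene value (Pearson) correlation vs clean:   {value_corr:.3f}")
print("  -> orderings degrade far more gracefully than magnitudes\n")

print("mean retention of the planted cancer pattern in tumours, by dropout rate:")
for rate in (0.0, 0.2, 0.4, 0.54):
    deg = apply_ffpe_degradation(clean[cancers], rate, seed=4) if rate else clean[cancers]
    ratios = [reo.retention_rate(deg[s], cohort.ground_truth.diag_pairs).ratio
              for s in cancers]
    print(f"  dropout {rate:4.2f}: retention {np.nanmean(ratios):.3f}")
print("retention stays far above the 60% vote cut-off even at 54% zeros")
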