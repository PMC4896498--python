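"""Check that correction preserves biology: clustering and associations.

On a simulated paired cohort, batch correction should let each subject's
baseline and follow-up samples find each other in a dendrogram, and should
leave phenotype-association effect estimates essentially unchanged.
"""

import logging
import warnings

import numpy as np

import longbatch as lb

logging.basicConfig(level=logging.ERROR)
warnings.filterwarnings("ignore")  # statsmodels boundary-fit chatter

cohort = lb.simulate_cohort(lb.SimulationConfig(
    n_subjects=80, n_probes=200, n_negative_controls=40,
    phenotype_model=lb.PhenotypeModel(n_associated_probes=20,
                                      effect_size=0.05), seed=9))
expr, meta = cohort.expression, cohort.meta
corrected, _ = lb.correct(expr, meta, "combat", qn_first=True)

for name, matrix in (("uncorrected", expr), ("QN+ComBat", corrected)):
    pp = lb.pair_proximity_statistic(matrix, meta, n_iterations=10,
                                     subset_size=40, seed=3)
    print(f"{name:12s} BL-FU pairs as dendrogram siblings: "
          f"{100 * pp.mean_proportion:5.1f}%")

bl = meta.index[meta.measurement_batch == "BL"]
assoc_raw = lb.phenotype_association(
    lb.quantile_normalize(expr[bl]), meta.loc[bl])
assoc_cor = lb.phenotype_association(corrected[bl], meta.loc[bl])
r_beta, r_logp = lb.association_concordance(assoc_raw, assoc_cor)
print(f"\nphenotype associations, QN vs QN+ComBat (BL batch): "
      f"r(beta) = {r_beta:.3f}, r(log10 p) = {r_logp:.3f}")
truth = cohort.truth["betas"]
hits = truth[truth != 0].index
est = assoc_cor.table.loc[hits, "beta"]
print(f"injected effects recovered: mean |beta_hat - beta| = "
      f"{np.abs(est - truth[hits]).mean():.4f} log2 per phenotype unit")
print("\nBatch correction turns near-zero pair proximity into a high rate")
print("while the association summary statistics stay tightly correlated -")
print("technical variation removed, biological signal intact.")
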