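"""Compare the seven batch-correction methods on the replicate study.

For each method (optionally after per-batch quantile normalization) the
script counts probes still differentially expressed between the two
technical-replicate batches (Welch t, BH FDR < 0.05) and the PVCA variance
share still attributable to batch. Technical replicates of the same RNA
should show no differential expression at all after a successful correction.
"""

import logging

import longbatch as lb

logging.basicConfig(level=logging.ERROR)

ds = lb.simulate_dataset(lb.SimulationConfig(seed=1))
expr, meta, probes = ds.expression, ds.meta, ds.probes
bl = meta.index[meta.replicate_group == "BL_rep"]
blfu = meta.index[meta.replicate_group == "BLFU_rep"]


def report(name, matrix):
    de = lb.differential_expression(matrix, bl, blfu)
    pv = lb.pvca(matrix, meta)
    print(f"{name:24s} DE: {de.n_significant_bh:5d} "
          f"({100 * de.fraction_significant_bh:5.1f}%)   "
          f"PVCA batch: {100 * pv.proportions['batch']:5.1f}%  "
          f"individual: {100 * pv.proportions['individual']:5.1f}%")


report("uncorrected", expr)
for method in ("deming", "passing_bablok", "lmm", "polynomial", "qspline"):
    corrected, _ = lb.correct(expr, meta, method)
    report(method, corrected)
for method, kw in (("combat", {}), ("combat", {"qn_first": True}),
                   ("ruv", {"k": 5}), ("ruv", {"k": 5, "qn_first": True})):
    corrected, _ = lb.correct(expr, meta, method, probes=probes, **kw)
    label = ("QN+" if kw.get("qn_first") else "") + method
    report(label, corrected)

print("\nRescaling regressions apply one global curve, so the per-probe batch")
print("shift survives them; the per-gene empirical-Bayes adjustment and the")
print("replicate-based factor removal drive the replicate DE count to zero.")
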