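# longbatch

Batch-effect removal and replicate-based evaluation for **two-time-point
longitudinal microarray expression data**.

When a cohort's transcriptome is measured at baseline (BL) and again years
later at follow-up (FU), the biology of interest — longitudinal expression
change — is confounded with everything that changed technically in between:
personnel, reagent lots, chip versions, scanners. The clean way to separate
the two is to re-hybridize stored baseline RNA at follow-up. Each selected
subject then contributes three technical-replicate groups:

| group | RNA extracted | array measured | differences reflect |
|---|---|---|---|
| `BL_rep`   | BL | BL | — |
| `BLFU_rep` | BL | FU | **pure batch effect** vs `BL_rep` |
| `FU_rep`   | FU | FU | 5-year biology vs `BLFU_rep` |

`longbatch` implements the full workflow around this design for users who
need to pick (and defend) a batch-correction strategy: a seeded synthetic
cohort generator with this replicate structure, the QC cascade (SNR and
mean-level array filters, shared-probe intersection, detection calling
against negative controls, expressed-probe filtering, sample mix-up
detection from sex-specific and polymorphism-in-probe signals), seven
correction methods (Deming, Passing-Bablok, linear mixed model, cubic
polynomial, qspline, empirical-Bayes location-scale adjustment / ComBat,
replicate-based RUV — each with optional per-batch quantile normalization),
and the evaluation suite that adjudicates between them (replicate
differential expression, principal variance component analysis, dendrogram
classification, subsampled BL–FU pair proximity, Bland–Altman agreement,
phenotype-association concordance).

The core statistic of the winning method, per gene *g* and batch *i*
(intercept-only ComBat): standardize
*Z = (Y − α̂_g)/σ̂_g*, shrink the batch location/scale estimates
*(γ̂_ig, δ̂²_ig)* toward empirical-Bayes priors, and restore
*Y\* = σ̂_g/δ\*_ig·(Z − γ\*_ig) + α̂_g* — applied after quantile-normalizing
each batch separately. See `docs/methods.md` for every model and numerical
choice.

## Worked example

```python
import longbatch as lb

ds = lb.simulate_dataset(lb.SimulationConfig(seed=1))   # 2,000 probes x 132 samples
meta = ds.meta
bl   = meta.index[meta.replicate_group == "BL_rep"]
blfu = meta.index[meta.replicate_group == "BLFU_rep"]

before = lb.differential_expression(ds.expression, bl, blfu)
corrected, model = lb.correct(ds.expression, meta, "combat", qn_first=True)
after = lb.differential_expression(corrected, bl, blfu)

print(before.n_significant_bh, after.n_significant_bh)
print(lb.pvca(ds.expression, meta).proportions["batch"],
      lb.pvca(corrected, meta).proportions["batch"])
```

prints

```
1997 0
0.8125106922355931 0.002129589616769595
```

— before correction 1,997 of 2,000 probes (99.9%) differ between the two
replicate batches at BH FDR < 0.05 and 81% of retained-PC variance is
attributable to batch; after per-batch quantile normalization + ComBat,
**zero** probes differ between technical replicates and the batch share
drops to 0.2%, while the subject share rises from 19% to 99.6% (biology
preserved). The `examples/` scripts walk through the generator, the QC
cascade, the seven-method comparison (reproducing the pattern that only the
empirical-Bayes and replicate-RUV corrections reach zero replicate DE), and
the biology-preservation checks; each prints and explains its numbers.

A thin CLI mirrors the library for shell pipelines:

```sh
longbatch simulate --out data --seed 1
longbatch qc --expr data/expression.tsv --meta data/meta.tsv \
             --probes data/probes.tsv --min-detected 500 --out qc
longbatch correct --expr qc/expression_qc.tsv --meta qc/meta_qc.tsv \
                  --method combat --qn-first --out corrected
longbatch run --out full_run   # simulate -> qc -> correct -> evaluate
```

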