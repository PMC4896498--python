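"""Evaluation suite: DE counting, PVCA, clustering, agreement, associations."""

import numpy as np
import pandas as pd
import pytest

import longbatch as lb
from longbatch.containers import (
    AGE, BATCH, CHIP, GROUP, PHENOTYPE, SEX, SUBJECT, TIMEPOINT,
)
from longbatch.evaluation import AssociationResult

from oracles import bh_adjusted


def _meta(samples, **cols):
    n = len(samples)
    defaults = {SUBJECT: list(range(n)), TIMEPOINT: ["BL"] * n,
                BATCH: ["BL"] * n, GROUP: ["cohort"] * n, SEX: ["F"] * n,
                AGE: [50.0] * n, PHENOTYPE: [25.0] * n, CHIP: ["c1"] * n}
    defaults.update(cols)
    return pd.DataFrame(defaults, index=pd.Index(samples, name="sample_id"))


class TestDifferentialExpression:
    def test_identical_groups_no_discoveries(self, rng):
        Y = rng.normal(8, 1, (50, 4))
        expr = pd.DataFrame(np.hstack([Y, Y]),
                            index=[f"g{i}" for i in range(50)],
                            columns=[f"s{j}" for j in range(8)])
        de = lb.differential_expression(expr, expr.columns[:4], expr.columns[4:])
        assert de.n_significant_bh == 0
        assert de.n_significant_bonferroni == 0

    def test_bh_adjustment_matches_stepup_example(self, rng):
        # p = (0.001, 0.01, 0.02, 0.9) -> adjusted (0.004, 0.02, 0.0267, 0.9)
        from statsmodels.stats.multitest import multipletests

        p = [0.001, 0.01, 0.02, 0.9]
        _, adj, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, [0.004, 0.02, 4 * 0.02 / 3, 0.9])
        np.testing.assert_allclose(adj, bh_adjusted(p))
        assert (np.array(adj) < 0.05).sum() == 3

    def test_adjusted_never_below_raw_and_counts_bounded(self, small_replicate_ds):
        ds = small_replicate_ds
        m = ds.meta
        bl = m.index[m[GROUP] == "BL_rep"]
        fu = m.index[m[GROUP] == "BLFU_rep"]
        de = lb.differential_expression(ds.expression, bl, fu)
        t = de.table
        assert (t.p_bh >= t.p - 1e-12).all()
        assert (t.p_bonferroni >= t.p - 1e-12).all()
        assert de.n_significant_bh <= de.total_probes
        assert de.n_significant_bonferroni <= de.n_significant_bh

    def test_degenerate_zero_variance_handling(self):
        expr = pd.DataFrame({"a1": [5.0, 1.0], "a2": [5.0, 1.0],
                             "b1": [5.0, 2.0], "b2": [5.0, 2.0]},
                            index=["same", "diff"])
        de = lb.differential_expression(expr, ["a1", "a2"], ["b1", "b2"])
        assert de.table.loc["same", "p"] == 1.0
        assert de.table.loc["diff", "p"] == 0.0


class TestPvca:
    @staticmethod
    def _design_meta(n_subj=10, reps=4):
        # extraction time point held constant so that the measurement batch
        # is not confounded with it
        samples, subj, batch = [], [], []
        for s in range(n_subj):
            for r in range(reps):
                samples.append(f"s{s}_{r}")
                subj.append(s)
                batch.append("BL" if r < reps // 2 else "FU")
        return _meta(samples, **{SUBJECT: subj, BATCH: batch,
                                 TIMEPOINT: ["BL"] * len(samples),
                                 GROUP: ["cohort"] * len(samples)})

    def test_batch_dominated_data(self, rng):
        meta = self._design_meta()
        shift = rng.normal(0, 1, 200)
        is_fu = (meta[BATCH] == "FU").to_numpy().astype(float)
        Y = rng.normal(0, 0.01, (200, len(meta))) + np.outer(shift, is_fu)
        expr = pd.DataFrame(Y, index=[f"g{i}" for i in range(200)],
                            columns=meta.index)
        res = lb.pvca(expr, meta)
        assert res.proportions["batch"] > 0.95

    def test_pure_noise_data(self, rng):
        meta = self._design_meta()
        expr = pd.DataFrame(rng.normal(0, 1, (200, len(meta))),
                            index=[f"g{i}" for i in range(200)],
                            columns=meta.index)
        res = lb.pvca(expr, meta)
        assert res.proportions["residual"] > 0.9

    def test_proportions_sum_to_one_and_bounded(self, small_replicate_ds):
        ds = small_replicate_ds
        res = lb.pvca(ds.expression, ds.meta)
        assert sum(res.proportions.values()) == pytest.approx(1.0, abs=1e-6)
        assert all(0.0 <= v <= 1.0 for v in res.proportions.values())
        assert res.cumulative_variance >= 0.60

    def test_invariant_to_mean_shift_and_probe_order(self, small_replicate_ds):
        ds = small_replicate_ds
        base = lb.pvca(ds.expression, ds.meta)
        shifted = lb.pvca(ds.expression + 5.0, ds.meta)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.expression.index)
        reordered = lb.pvca(ds.expression.loc[perm], ds.meta)
        # exact in exact arithmetic; REML restarts leave small numeric jitter
        for key in base.proportions:
            assert shifted.proportions[key] == pytest.approx(
                base.proportions[key], abs=0.02)
            assert reordered.proportions[key] == pytest.approx(
                base.proportions[key], abs=0.02)


class TestDendrogramClassify:
    def test_well_separated_subjects_all_correct(self, rng):
        profiles = {0: rng.normal(0, 1, 50), 1: rng.normal(10, 1, 50)}
        cols = {}
        meta_rows = []
        for s in (0, 1):
            for r, batch in enumerate(["BL", "FU", "BL", "FU"]):
                cols[f"s{s}_{r}"] = profiles[s] + rng.normal(0, 0.01, 50)
                meta_rows.append((s, batch))
        expr = pd.DataFrame(cols, index=[f"g{i}" for i in range(50)])
        meta = _meta(list(cols), **{SUBJECT: [r[0] for r in meta_rows],
                                    BATCH: [r[1] for r in meta_rows],
                                    TIMEPOINT: [r[1] for r in meta_rows]})
        res = lb.dendrogram_classify(expr, meta)
        assert res.classification == {0: "correct", 1: "correct"}

    def test_batch_dominated_clustering_all_incorrect(self, rng):
        cols = {}
        subj, batch = [], []
        base = rng.normal(8, 0.05, 50)
        shift = rng.normal(0, 3, 50)
        for s in range(4):
            for b in ("BL", "FU"):
                for r in range(2):
                    name = f"s{s}_{b}{r}"
                    cols[name] = base + (shift if b == "FU" else 0) \
                        + rng.normal(0, 0.05, 50)
                    subj.append(s)
                    batch.append(b)
        expr = pd.DataFrame(cols, index=[f"g{i}" for i in range(50)])
        meta = _meta(list(cols), **{SUBJECT: subj, BATCH: batch,
                                    TIMEPOINT: batch})
        res = lb.dendrogram_classify(expr, meta)
        assert all(v == "incorrect" for v in res.classification.values())

    def test_correction_improves_replicate_clustering(self, replicate_ds):
        ds = replicate_ds
        m = ds.meta
        rep = m.index[m[GROUP].isin(["BL_rep", "BLFU_rep"])]
        before = lb.dendrogram_classify(ds.expression[rep], m.loc[rep])
        corrected, _ = lb.correct(ds.expression, ds.meta, "combat", qn_first=True)
        after = lb.dendrogram_classify(corrected[rep], m.loc[rep])

        def score(res):
            return sum(1 for v in res.classification.values()
                       if v in ("correct", "partly_correct"))

        assert score(after) > score(before)


class TestDendrogramNewick:
    def test_round_trips_through_a_tree_parser(self, rng):
        from io import StringIO

        from Bio import Phylo

        expr = pd.DataFrame(rng.normal(8, 1, (30, 6)),
                            index=[f"g{i}" for i in range(30)],
                            columns=[f"s{j}" for j in range(6)])
        nwk = lb.dendrogram_newick(expr)
        tree = Phylo.read(StringIO(nwk), "newick")
        leaves = sorted(t.name for t in tree.get_terminals())
        assert leaves == sorted(expr.columns)
        # root-to-leaf depth equals the top merge height for every leaf
        # (ultrametric by construction)
        depths = tree.depths()
        leaf_depths = {t.name: d for t, d in depths.items() if t.name}
        vals = np.array(list(leaf_depths.values()))
        assert np.allclose(vals, vals[0], atol=1e-6)


class TestPairProximity:
    def test_duplicated_fu_columns_cluster_perfectly(self, rng):
        n = 12
        cols, subj, tp = {}, [], []
        for s in range(n):
            profile = rng.normal(8, 1, 80)
            cols[f"s{s}_BL"] = profile
            cols[f"s{s}_FU"] = profile.copy()
            subj += [s, s]
            tp += ["BL", "FU"]
        expr = pd.DataFrame(cols, index=[f"g{i}" for i in range(80)])
        meta = _meta(list(cols), **{SUBJECT: subj, TIMEPOINT: tp,
                                    BATCH: tp})
        res = lb.pair_proximity_statistic(expr, meta, n_iterations=5,
                                          subset_size=8, seed=1)
        assert res.mean_proportion == pytest.approx(1.0)

    def test_independent_noise_matches_permutation_chance(self, rng):
        n = 30
        cols, subj, tp = {}, [], []
        for s in range(n):
            cols[f"s{s}_BL"] = rng.normal(0, 1, 60)
            cols[f"s{s}_FU"] = rng.normal(0, 1, 60)
            subj += [s, s]
            tp += ["BL", "FU"]
        expr = pd.DataFrame(cols, index=[f"g{i}" for i in range(60)])
        meta = _meta(list(cols), **{SUBJECT: subj, TIMEPOINT: tp, BATCH: tp})
        res = lb.pair_proximity_statistic(expr, meta, n_iterations=30,
                                          subset_size=15, seed=2)
        # permutation oracle: chance rate of sibling pairings under shuffled
        # subject labels on the same data
        chance = []
        for it in range(30):
            perm_meta = meta.copy()
            perm_meta[SUBJECT] = rng.permutation(perm_meta[SUBJECT].to_numpy())
            keep = perm_meta.groupby(SUBJECT)[TIMEPOINT].nunique() == 2
            ok = perm_meta[perm_meta[SUBJECT].isin(keep.index[keep])]
            if (keep).sum() < 15:
                continue
            r = lb.pair_proximity_statistic(expr[ok.index], ok,
                                            n_iterations=3, subset_size=15,
                                            seed=100 + it)
            chance.append(r.mean_proportion)
        assert res.mean_proportion == pytest.approx(np.mean(chance), abs=0.1)

    def test_deterministic_and_column_order_invariant(self, cohort_ds):
        ds = cohort_ds
        a = lb.pair_proximity_statistic(ds.expression, ds.meta,
                                        n_iterations=4, subset_size=20, seed=3)
        b = lb.pair_proximity_statistic(ds.expression, ds.meta,
                                        n_iterations=4, subset_size=20, seed=3)
        rng = np.random.default_rng(1)
        perm = rng.permutation(ds.expression.columns)
        c = lb.pair_proximity_statistic(ds.expression[perm], ds.meta.loc[perm],
                                        n_iterations=4, subset_size=20, seed=3)
        assert a.per_iteration_counts == b.per_iteration_counts
        assert a.per_iteration_counts == c.per_iteration_counts

    def test_flat_mode_is_at_least_as_generous(self, cohort_ds):
        ds = cohort_ds
        corrected, _ = lb.correct(ds.expression, ds.meta, "combat", qn_first=True)
        sib = lb.pair_proximity_statistic(corrected, ds.meta, n_iterations=4,
                                          subset_size=20, seed=5)
        flat = lb.pair_proximity_statistic(corrected, ds.meta, n_iterations=4,
                                           subset_size=20, seed=5, mode="flat")
        assert flat.mean_proportion >= sib.mean_proportion


class TestBlandAltman:
    def test_identical_samples_zero_difference(self, rng):
        expr = pd.DataFrame({"a": rng.normal(8, 1, 40)},
                            index=[f"g{i}" for i in range(40)])
        expr["b"] = expr["a"]
        tab = lb.bland_altman(expr, "a", "b")
        assert (tab["difference"] == 0).all()

    def test_constant_offset(self, rng):
        expr = pd.DataFrame({"a": rng.normal(8, 1, 40)},
                            index=[f"g{i}" for i in range(40)])
        expr["b"] = expr["a"] + 0.5
        tab = lb.bland_altman(expr, "a", "b")
        np.testing.assert_allclose(tab["difference"], -0.5)
        np.testing.assert_allclose(tab["mean"], expr["a"] + 0.25)

    def test_uncorrected_difference_decreases_with_intensity(self, replicate_ds):
        from scipy.stats import spearmanr

        ds = replicate_ds
        m = ds.meta
        subj = m[m[GROUP] == "BL_rep"][SUBJECT].iloc[0]
        a = m.index[(m[SUBJECT] == subj) & (m[GROUP] == "BLFU_rep")][0]
        b = m.index[(m[SUBJECT] == subj) & (m[GROUP] == "BL_rep")][0]
        tab = lb.bland_altman(ds.expression, a, b)
        rho, _ = spearmanr(tab["mean"], tab["difference"])
        assert rho < -0.3


class TestAssociation:
    def test_constant_phenotype_errors(self, rng):
        expr = pd.DataFrame(rng.normal(8, 1, (10, 8)),
                            index=[f"g{i}" for i in range(10)],
                            columns=[f"s{j}" for j in range(8)])
        meta = _meta(expr.columns, **{CHIP: ["c1"] * 4 + ["c2"] * 4})
        with pytest.raises(ValueError, match="constant"):
            lb.phenotype_association(expr, meta)

    def test_null_phenotype_rarely_discovers(self):
        """BH under a complete null: no discoveries in almost every run."""
        clean = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cfg = lb.SimulationConfig(
                n_subjects=100, n_probes=60, n_negative_controls=20,
                phenotype_model=lb.PhenotypeModel(n_associated_probes=0),
                seed=seed)
            ds = lb.simulate_cohort(cfg)
            m = ds.meta
            bl = m.index[m[BATCH] == "BL"]
            meta = m.loc[bl].copy()
            meta[PHENOTYPE] = rng.permutation(meta[PHENOTYPE].to_numpy())
            res = lb.phenotype_association(ds.expression[bl], meta)
            clean += res.n_significant == 0
        assert clean >= 18


class TestConcordance:
    @staticmethod
    def _result(beta, p):
        idx = pd.Index([f"g{i}" for i in range(len(beta))])
        table = pd.DataFrame({"beta": beta, "se": np.full(len(beta), 0.1),
                              "p": p, "q": p}, index=idx)
        return AssociationResult(table=table, n_significant=0)

    def test_identical_results_correlate_perfectly(self, rng):
        beta = rng.normal(0, 1, 50)
        p = rng.uniform(1e-6, 1, 50)
        r_beta, r_logp = lb.association_concordance(self._result(beta, p),
                                                    self._result(beta, p))
        assert r_beta == pytest.approx(1.0)
        assert r_logp == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self, rng):
        beta = rng.normal(0, 1, 50)
        p = rng.uniform(1e-6, 1, 50)
        r_beta, _ = lb.association_concordance(self._result(beta, p),
                                               self._result(-beta, p))
        assert r_beta == pytest.approx(-1.0)

    def test_attenuation_matches_analytic_prediction(self, rng):
        beta = rng.normal(0, 1.0, 4000)
        noise = rng.normal(0, 0.5, 4000)
        p = rng.uniform(1e-6, 1, 4000)
        r_beta, _ = lb.association_concordance(self._result(beta, p),
                                               self._result(beta + noise, p))
        expected = 1.0 / np.sqrt(1 + 0.5 ** 2 / beta.var())
        assert r_beta == pytest.approx(expected, abs=0.02)

    def test_mismatched_probe_sets_error(self, rng):
        a = self._result(rng.normal(size=10), rng.uniform(size=10))
        b = self._result(rng.normal(size=10), rng.uniform(size=10))
        b.table.index = [f"h{i}" for i in range(10)]
        with pytest.raises(ValueError, match="different probe sets"):
            lb.association_concordance(a, b)
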