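"""Replicate-based evaluation of batch-effect removal.

Metrics: per-probe differential expression between the technical-replicate
batches (none should remain after a successful correction), principal
variance component analysis (PVCA) attributing overall variance to batch /
time point / individual / residual, dendrogram classification of replicate
clustering, a subsampled BL-FU pair-proximity statistic, Bland-Altman
agreement tables, and phenotype-association recovery with concordance of
summary statistics before and after correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .containers import AGE, BATCH, CHIP, PHENOTYPE, SEX, SUBJECT, TIMEPOINT

logger = logging.getLogger(__name__)

__all__ = [
    "DEResult", "differential_expression",
    "PVCAResult", "pvca",
    "ClusterEvalResult", "dendrogram_classify", "pair_proximity_statistic",
    "bland_altman",
    "AssociationResult", "phenotype_association", "association_concordance",
]


# ---------------------------------------------------------------------------
# differential expression between replicate batches

@dataclass
class DEResult:
    table: pd.DataFrame  # statistic, p, p_bh, p_bonferroni per probe
    n_significant_bh: int
    n_significant_bonferroni: int
    total_probes: int
    alpha: float = 0.05

    @property
    def fraction_significant_bh(self) -> float:
        return self.n_significant_bh / self.total_probes


def differential_expression(expr: pd.DataFrame, group_a, group_b,
                            alpha: float = 0.05) -> DEResult:
    """Per-probe Welch t-test between two sample sets, BH and Bonferroni.

    Probes with zero variance in both groups get p = 1 when the group means
    agree and p = 0 otherwise (the pooled-test limit).
    """
    a = expr[list(group_a)].to_numpy()
    b = expr[list(group_b)].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # probes whose within-group spread is at floating-point scale relative to
    # their level carry no testable variation: compare the means with the
    # same tolerance instead of a raw t statistic
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    scale = np.maximum(1.0, np.maximum(np.abs(ma), np.abs(mb)))
    tol = 1e-9 * scale
    degenerate = ~np.isfinite(p) | ((a.std(axis=1) <= tol) & (b.std(axis=1) <= tol))
    if degenerate.any():
        equal_means = np.abs(ma - mb) <= tol
        p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
        stat = np.where(degenerate, np.where(equal_means, 0.0, np.inf), stat)
    reject_bh, p_bh, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    reject_bf, p_bf, *_ = multipletests(p, alpha=alpha, method="bonferroni")
    table = pd.DataFrame(
        {"statistic": stat, "p": p, "p_bh": p_bh, "p_bonferroni": p_bf},
        index=expr.index)
    return DEResult(table=table,
                    n_significant_bh=int(reject_bh.sum()),
                    n_significant_bonferroni=int(reject_bf.sum()),
                    total_probes=len(p), alpha=alpha)


# ---------------------------------------------------------------------------
# principal variance component analysis

@dataclass
class PVCAResult:
    n_retained_pcs: int
    cumulative_variance: float
    proportions: dict[str, float]  # batch, timepoint, individual, residual
    per_pc: pd.DataFrame = field(repr=False, default=None)


_PVCA_SOURCES = {"batch": BATCH, "timepoint": TIMEPOINT, "individual": SUBJECT}


def _vc_moments(scores: np.ndarray, factors: dict[str, np.ndarray]) -> dict[str, float]:
    """Method-of-moments variance components (fallback estimator).

    Per factor: between-level mean squares against the pooled within-level
    variance, truncated at zero.
    """
    out = {}
    resid = float(np.var(scores, ddof=1))
    for name, labels in factors.items():
        levels, inverse = np.unique(labels, return_inverse=True)
        if len(levels) < 2:
            out[name] = 0.0
            continue
        means = np.array([scores[inverse == i].mean() for i in range(len(levels))])
        sizes = np.array([(inverse == i).sum() for i in range(len(levels))])
        within = np.concatenate(
            [scores[inverse == i] - means[i] for i in range(len(levels))])
        s2_within = float(np.var(within, ddof=len(levels)) if len(within) > len(levels)
                          else 0.0)
        ms_between = float(np.sum(sizes * (means - scores.mean()) ** 2) / (len(levels) - 1))
        out[name] = max(0.0, (ms_between - s2_within) / sizes.mean())
        resid = min(resid, s2_within)
    out["residual"] = max(resid, 0.0)
    return out


def _vc_reml(scores: np.ndarray, meta: pd.DataFrame,
             max_iter: int = 300, tol: float = 1e-8) -> dict[str, float]:
    """EM-REML for the random-intercepts variance-components model.

    ``score = mu + u_batch + u_timepoint + u_subject + e`` with independent
    components.  EM updates are monotone in the restricted likelihood and
    keep every component non-negative, which makes the boundary cases
    (components that are truly zero) well behaved.  Factors with fewer than
    two levels are unidentifiable next to the intercept and get component 0.
    """
    sd = scores.std()
    if sd == 0:
        raise ValueError("constant PC scores")
    y = scores / sd
    n = len(y)
    Zs: dict[str, np.ndarray] = {}
    for name, col in _PVCA_SOURCES.items():
        levels, inverse = np.unique(meta[col].to_numpy(), return_inverse=True)
        if len(levels) >= 2:
            Z = np.zeros((n, len(levels)))
            Z[np.arange(n), inverse] = 1.0
            Zs[name] = Z
    X = np.ones((n, 1))
    var0 = float(np.var(y, ddof=1))
    sig = {name: var0 / (len(Zs) + 1) for name in Zs}
    sig_e = var0 / (len(Zs) + 1)
    for _ in range(max_iter):
        V = sig_e * np.eye(n)
        for name, Z in Zs.items():
            V += sig[name] * (Z @ Z.T)
        Vinv = np.linalg.inv(V)
        XtVX = X.T @ Vinv @ X
        P = Vinv - Vinv @ X @ np.linalg.solve(XtVX, X.T @ Vinv)
        Py = P @ y
        new = {}
        for name, Z in Zs.items():
            q = Z.shape[1]
            ZtPy = Z.T @ Py
            trZPZ = np.trace(Z.T @ P @ Z)
            new[name] = max(sig[name] + (sig[name] ** 2 / q)
                            * (ZtPy @ ZtPy - trZPZ), 0.0)
        new_e = max(sig_e + (sig_e ** 2 / n) * (Py @ Py - np.trace(P)), 0.0)
        delta = max(abs(new_e - sig_e),
                    *(abs(new[k] - sig[k]) for k in new)) if new else \
            abs(new_e - sig_e)
        sig, sig_e = new, new_e
        if delta < tol:
            break
    comps = {name: sig.get(name, 0.0) for name in _PVCA_SOURCES}
    comps["residual"] = sig_e
    return comps


def pvca(expr: pd.DataFrame, meta: pd.DataFrame,
         variance_threshold: float = 0.60) -> PVCAResult:
    """Eigenvalue-weighted variance-component attribution of principal components.

    PCA is computed on row-centered data (no probe scaling); the smallest set
    of leading PCs reaching ``variance_threshold`` of total variance is
    retained.  Each retained PC's sample scores are decomposed by a
    variance-components model with random intercepts for measurement batch,
    extraction time point and subject (REML, with a method-of-moments
    fallback); per-PC proportions are weighted by the PC's eigenvalue share
    among retained PCs and summed.
    """
    meta = meta.loc[expr.columns]
    X = expr.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s ** 2
    total = ev.sum()
    cum = np.cumsum(ev) / total
    n_retained = int(np.searchsorted(cum, variance_threshold) + 1)
    n_retained = min(n_retained, len(ev))
    scores = vt[:n_retained] * s[:n_retained, None]  # PCs x samples

    factors = {name: meta[col].to_numpy() for name, col in _PVCA_SOURCES.items()}
    weights = ev[:n_retained] / ev[:n_retained].sum()
    sources = list(_PVCA_SOURCES) + ["residual"]
    combined = dict.fromkeys(sources, 0.0)
    rows = []
    for i in range(n_retained):
        try:
            comps = _vc_reml(scores[i], meta)
        except (np.linalg.LinAlgError, ValueError) as err:
            logger.warning("PC%d REML failed (%s); method-of-moments fallback",
                           i + 1, err)
            comps = _vc_moments(scores[i], factors)
        comp_total = sum(comps.values())
        props = {k: (comps.get(k, 0.0) / comp_total if comp_total > 0 else 0.0)
                 for k in sources}
        rows.append({"pc": i + 1, "eigenvalue_share": float(ev[i] / total), **props})
        for k in sources:
            combined[k] += weights[i] * props[k]
    norm = sum(combined.values())
    proportions = {k: v / norm for k, v in combined.items()}
    return PVCAResult(
        n_retained_pcs=n_retained,
        cumulative_variance=float(cum[n_retained - 1]),
        proportions={"batch": proportions["batch"],
                     "timepoint": proportions["timepoint"],
                     "individual": proportions["individual"],
                     "residual": proportions["residual"]},
        per_pc=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# hierarchical clustering of replicates

@dataclass
class ClusterEvalResult:
    per_iteration_counts: list[int]
    per_iteration_proportions: list[float]
    mean_proportion: float
    classification: dict = field(default_factory=dict)  # subject -> label


def _linkage(expr: pd.DataFrame, method: str = "complete"):
    d = pdist(expr.to_numpy().T, metric="euclidean")
    return hierarchy.linkage(d, method=method)


def _node_leafsets(link: np.ndarray, n_leaves: int) -> list[set[int]]:
    sets: dict[int, set[int]] = {i: {i} for i in range(n_leaves)}
    out = []
    for row in range(link.shape[0]):
        a, b = int(link[row, 0]), int(link[row, 1])
        merged = sets[a] | sets[b]
        sets[n_leaves + row] = merged
        out.append(merged)
    return out


def dendrogram_newick(expr: pd.DataFrame,
                      linkage_method: str = "complete") -> str:
    """Newick string of the sample dendrogram (branch lengths = merge heights)."""
    link = _linkage(expr, linkage_method)
    labels = list(expr.columns)
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height):
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{max(parent_height - node.dist, 0.0):.6g}"

    body = walk(tree, tree.dist)
    # the root carries no branch length
    return body.rsplit(":", 1)[0] + ";"


def dendrogram_classify(expr: pd.DataFrame, meta: pd.DataFrame,
                        linkage_method: str = "complete") -> ClusterEvalResult:
    """Classify each subject by how its replicates cluster.

    ``correct``: all of the subject's replicates form a pure subtree;
    ``partly_correct``: some pure subtree holds >= 2 of its replicates drawn
    from both measurement batches; ``incorrect`` otherwise.
    """
    meta = meta.loc[expr.columns]
    link = _linkage(expr, linkage_method)
    leafsets = _node_leafsets(link, expr.shape[1])
    subjects = meta[SUBJECT].to_numpy()
    batches = meta[BATCH].to_numpy()
    classification = {}
    for subject in pd.unique(subjects):
        mine = set(np.flatnonzero(subjects == subject))
        if len(mine) < 2:
            classification[subject] = "correct"
            continue
        label = "incorrect"
        for leaves in leafsets:
            if not leaves <= mine:
                continue
            if leaves == mine:
                label = "correct"
                break
            if len(leaves) >= 2 and len({batches[i] for i in leaves}) == 2:
                label = "partly_correct"
        classification[subject] = label
    n_correct = sum(1 for v in classification.values() if v == "correct")
    prop = n_correct / len(classification)
    return ClusterEvalResult(per_iteration_counts=[n_correct],
                             per_iteration_proportions=[prop],
                             mean_proportion=prop,
                             classification=classification)


def pair_proximity_statistic(expr: pd.DataFrame, meta: pd.DataFrame,
                             n_iterations: int = 22, subset_size: int = 50,
                             seed: int = 0, mode: str = "siblings",
                             linkage_method: str = "complete",
                             ) -> ClusterEvalResult:
    """Subsampled proportion of subjects whose BL and FU columns cluster together.

    Per iteration ``subset_size`` subjects with both time points are drawn
    without replacement, their 2 x subset_size columns hierarchically
    clustered, and the subjects whose two columns merge as immediate
    dendrogram siblings are counted (``mode="flat"`` instead counts pairs
    sharing a flat cluster when the tree is cut into ``subset_size``
    clusters).
    """
    meta = meta.loc[expr.columns]
    by_subject = {}
    for subject, rows in meta.groupby(SUBJECT):
        bl = rows.index[rows[TIMEPOINT] == "BL"]
        fu = rows.index[rows[TIMEPOINT] == "FU"]
        if len(bl) and len(fu):
            by_subject[subject] = (bl[0], fu[0])
    eligible = sorted(by_subject)
    if subset_size > len(eligible):
        raise ValueError("subset_size exceeds subjects with both time points")
    rng = np.random.default_rng(seed)
    counts, props = [], []
    for _ in range(n_iterations):
        chosen = rng.choice(eligible, size=subset_size, replace=False)
        cols, pair_of = [], {}
        for s in chosen:
            bl, fu = by_subject[s]
            pair_of[len(cols)] = len(cols) + 1
            cols.extend([bl, fu])
        sub = expr[cols]
        link = _linkage(sub, linkage_method)
        if mode == "siblings":
            n = len(cols)
            sib = 0
            for row in link:
                a, b = int(row[0]), int(row[1])
                if a < n and b < n and pair_of.get(min(a, b)) == max(a, b):
                    sib += 1
            count = sib
        elif mode == "flat":
            flat = hierarchy.fcluster(link, t=subset_size, criterion="maxclust")
            count = sum(1 for a, b in pair_of.items() if flat[a] == flat[b])
        else:
            raise ValueError("mode must be 'siblings' or 'flat'")
        counts.append(count)
        props.append(count / subset_size)
    return ClusterEvalResult(per_iteration_counts=counts,
                             per_iteration_proportions=props,
                             mean_proportion=float(np.mean(props)))


# ---------------------------------------------------------------------------
# agreement and association

def bland_altman(expr: pd.DataFrame, sample_a: str, sample_b: str) -> pd.DataFrame:
    """Per-probe (mean, difference) table for two samples (a minus b)."""
    a = expr[sample_a]
    b = expr[sample_b]
    return pd.DataFrame({"mean": (a + b) / 2.0, "difference": a - b},
                        index=expr.index)


@dataclass
class AssociationResult:
    table: pd.DataFrame  # beta, se, p, q per probe
    n_significant: int
    alpha: float = 0.05


def phenotype_association(expr: pd.DataFrame, meta: pd.DataFrame,
                          alpha: float = 0.05) -> AssociationResult:
    """Per-probe mixed model: expression ~ sex + age + phenotype + (1 | chip).

    The chip random intercept absorbs shared technical variation; BH
    adjustment is applied over all probes.  Probes whose mixed-model fit is
    singular fall back to fixed-effects OLS (logged).
    """
    meta = meta.loc[expr.columns]
    if meta[PHENOTYPE].nunique() < 2:
        raise ValueError("phenotype is constant; association undefined")
    if meta[CHIP].nunique() < 2:
        raise ValueError("need >= 2 chips for the random intercept")
    exog = pd.DataFrame({
        "const": 1.0,
        "sex": (meta[SEX] == "M").astype(float),
        "age": meta[AGE].astype(float),
        "phenotype": meta[PHENOTYPE].astype(float),
    }, index=meta.index)
    groups = meta[CHIP].to_numpy()
    betas, ses, ps = [], [], []
    n_fallback = 0
    X = exog.to_numpy()
    # small-sample reference: t with the residual degrees of freedom instead
    # of the asymptotic normal Wald p-value
    dof = len(meta) - X.shape[1]
    for probe in expr.index:
        y = expr.loc[probe].to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = MixedLM(y, X, groups=groups).fit(reml=True)
            if not np.all(np.isfinite(fit.bse_fe)):
                raise np.linalg.LinAlgError("singular covariance")
            beta = fit.fe_params[3]
            se = fit.bse_fe[3]
        except (np.linalg.LinAlgError, ValueError):
            n_fallback += 1
            ols = sm.OLS(y, X).fit()
            beta, se = ols.params[3], ols.bse[3]
        betas.append(float(beta))
        ses.append(float(se))
        ps.append(float(2.0 * stats.t.sf(abs(beta / se), dof)))
    if n_fallback:
        logger.warning("%d probes used the fixed-effects fallback", n_fallback)
    reject, q, *_ = multipletests(ps, alpha=alpha, method="fdr_bh")
    table = pd.DataFrame({"beta": betas, "se": ses, "p": ps, "q": q},
                         index=expr.index)
    return AssociationResult(table=table, n_significant=int(reject.sum()),
                             alpha=alpha)


def association_concordance(res_a: AssociationResult, res_b: AssociationResult,
                            ) -> tuple[float, float]:
    """Pearson correlations of effect estimates and of log10 p-values."""
    a, b = res_a.table, res_b.table
    if not a.index.equals(b.index):
        raise ValueError("association results cover different probe sets")
    if len(a) < 3:
        raise ValueError("need at least 3 probes")
    r_beta = float(np.corrcoef(a["beta"], b["beta"])[0, 1])
    r_logp = float(np.corrcoef(np.log10(a["p"]), np.log10(b["p"]))[0, 1])
    return r_beta, r_logp
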