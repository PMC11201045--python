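"""Multi-environment phenotype analysis: BLUEs, PCA, two-stage clustering.

The phenotype pipeline mirrors a classical multi-environment trial (MET)
workflow for variety collections:

1. derived traits from the raw records — anthesis-silking interval
   ASI = DS - DT (days) and relative ear height EPHR = (EH / PH) x 100 (%);
2. per-trait linear mixed model with varieties fixed and trials random,
   fitted by REML; the variety BLUEs are the fixed-effect estimates under
   cell-means coding, valid for unbalanced data;
3. PCA of the standardized BLUEs (correlation matrix), retaining
   components with eigenvalue > 1 but never fewer than two;
4. two-stage clustering: seeded k-means into ``k`` preliminary clusters
   (Euclidean distance on the retained scores), then size-weighted
   average-linkage agglomeration of the preliminary centroids cut into
   ``n_main`` main clusters labelled A, B, ... in dendrogram leaf order.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from ._utils import logger
from .structure import Tree, _linkage_to_tree

TRAITS_RAW = ("DT", "DS", "PH", "EH")
TRAITS_ALL = ("DT", "DS", "ASI", "PH", "EH", "EPHR")


@dataclass
class BLUETable:
    """Variety x trait BLUEs with per-trait variance components."""

    blues: pd.DataFrame
    varcomp: pd.DataFrame  # trait x (trial_var, resid_var)
    standard_errors: pd.DataFrame | None = None
    derived_mode: str = "records"  # "records": derive per record then BLUE
    #                                "blues": derive from BLUE columns


@dataclass
class PhenoPcaResult:
    """PCA of standardized trait BLUEs (correlation-matrix PCA)."""

    loadings: pd.DataFrame  # trait x component
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    scores: pd.DataFrame  # entity x retained component
    n_retained: int


@dataclass
class PreclusterResult:
    labels: pd.Series
    centroids: np.ndarray
    sizes: np.ndarray
    inertia: float
    pseudo_f: float


@dataclass
class ClusterAssignment:
    """Two-stage partition: preliminary subcluster and main cluster."""

    subcluster: pd.Series  # entity -> 1..k
    main_cluster: pd.Series  # entity -> "A".."E"
    tree: Tree = field(repr=False)
    sub_to_main: pd.Series | None = None


def derive_traits(records: pd.DataFrame) -> pd.DataFrame:
    """Augment trial records with ASI = DS - DT and EPHR = (EH/PH) x 100."""
    missing = [t for t in TRAITS_RAW if t not in records.columns]
    if missing:
        raise ValueError(f"records missing trait columns {missing}")
    out = records.copy()
    out["ASI"] = out["DS"] - out["DT"]
    ph = out["PH"].to_numpy(dtype=float)
    zero = ph == 0
    if zero.any():
        logger.warning("%d records with PH = 0: EPHR set missing", int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        out["EPHR"] = np.where(zero, np.nan, out["EH"] / ph * 100.0)
    return out


def estimate_blues(records: pd.DataFrame, trait: str,
                   rep_within_trial: bool = False) -> tuple[pd.Series, dict, pd.Series]:
    """REML mixed-model BLUEs for one trait.

    Model: y = variety (fixed) + trial (random intercept) + residual,
    fitted by REML on all non-missing records; with ``rep_within_trial``
    an additional random replicate-within-trial term is included. Returns
    (blues, variance components, standard errors). Varieties are coded as
    cell means, so each fixed coefficient is directly the variety BLUE
    (estimated marginal mean); in a balanced complete design this reduces
    to the raw variety mean.
    """
    data = records.dropna(subset=[trait]).copy()
    if data["trial"].nunique() < 2:
        raise ValueError("need at least two trials")
    y = data[trait].to_numpy(dtype=float)
    exog = pd.get_dummies(data["landrace"], dtype=float)
    groups = data["trial"].to_numpy()
    if rep_within_trial:
        # replicate-within-trial as an extra variance component
        data["rep"] = data["rep"].astype(str)
        model = sm.MixedLM.from_formula(
            f"{trait} ~ 0 + C(landrace)", data=data, groups="trial",
            re_formula="1", vc_formula={"rep": "0 + C(rep)"})
    else:
        model = sm.MixedLM(y, exog, groups=groups)
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method="bfgs", maxiter=500)
        if not res.converged:
            res = model.fit(reml=True, method="powell", maxiter=2000)
        if not res.converged:
            raise RuntimeError(f"REML did not converge for trait {trait}")
        names = list(exog.columns)
        blues = pd.Series(np.asarray(res.fe_params)[:len(names)], index=names,
                          name=trait)
        se = pd.Series(np.asarray(res.bse_fe)[:len(names)], index=names,
                       name=trait)
    vcomp = {
        "trial_var": max(float(res.cov_re.iloc[0, 0]), 0.0),
        "resid_var": max(float(res.scale), 0.0),
    }
    return blues, vcomp, se


def blue_table(records: pd.DataFrame, derived_mode: str = "records",
               rep_within_trial: bool = False) -> BLUETable:
    """BLUEs for all six traits from raw trial records.

    ``derived_mode="records"`` derives ASI/EPHR per record before fitting
    (the default); ``"blues"`` fits the four raw traits and derives ASI and
    EPHR from the BLUE columns afterwards.
    """
    if derived_mode not in ("records", "blues"):
        raise ValueError("derived_mode must be 'records' or 'blues'")
    traits = TRAITS_ALL if derived_mode == "records" else TRAITS_RAW
    data = derive_traits(records) if derived_mode == "records" else records
    cols, vcs, ses = {}, {}, {}
    for trait in traits:
        b, vc, se = estimate_blues(data, trait, rep_within_trial)
        cols[trait], vcs[trait], ses[trait] = b, vc, se
    blues = pd.DataFrame(cols)
    se_df = pd.DataFrame(ses)
    if derived_mode == "blues":
        blues["ASI"] = blues["DS"] - blues["DT"]
        blues["EPHR"] = blues["EH"] / blues["PH"] * 100.0
        blues = blues[list(TRAITS_ALL)]
    return BLUETable(blues=blues, varcomp=pd.DataFrame(vcs).T,
                     standard_errors=se_df, derived_mode=derived_mode)


def pheno_pca(blues: pd.DataFrame, min_components: int = 2) -> PhenoPcaResult:
    """Correlation-matrix PCA of trait BLUEs.

    Rows with missing values are dropped with a warning; a constant trait
    column is an error. Components with eigenvalue > 1 are retained, but
    never fewer than ``min_components`` (a single retained dimension makes
    the downstream clustering degenerate). Component signs are fixed so the
    largest-magnitude loading is positive.
    """
    df = blues.blues if isinstance(blues, BLUETable) else blues
    complete = df.dropna()
    if len(complete) < len(df):
        logger.warning("dropping %d rows with missing BLUEs",
                       len(df) - len(complete))
    sd = complete.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant trait column(s): {constant}")
    z = (complete - complete.mean()) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] *= -1.0
    n_traits = df.shape[1]
    pct = evals / n_traits * 100.0
    n_keep = max(int((evals > 1.0).sum()), min_components)
    comps = [f"PRIN{k + 1}" for k in range(n_traits)]
    loadings = pd.DataFrame(evecs, index=df.columns, columns=comps)
    scores = pd.DataFrame(z.to_numpy() @ evecs[:, :n_keep],
                          index=complete.index, columns=comps[:n_keep])
    if int((evals > 1.0).sum()) < min_components:
        logger.warning("only %d eigenvalue(s) > 1; retaining %d components",
                       int((evals > 1.0).sum()), n_keep)
    return PhenoPcaResult(loadings=loadings, eigenvalues=evals,
                          percent_variance=pct, scores=scores,
                          n_retained=n_keep)


def explained_variance_percent(eigenvalues, n_traits: int | None = None) -> np.ndarray:
    """Percent variance per component for a correlation-matrix PCA.

    Each eigenvalue is divided by the total variance, which equals the
    number of traits for standardized data (pass ``n_traits`` when the
    eigenvalue list is truncated, as in a published table).
    """
    ev = np.asarray(eigenvalues, dtype=float)
    total = float(n_traits) if n_traits is not None else ev.sum()
    return ev / total * 100.0


def _pseudo_f(x: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    n, k = x.shape[0], centroids.shape[0]
    if k == 1 or k >= n:
        return float("nan")
    grand = x.mean(axis=0)
    ssw = float(((x - centroids[labels]) ** 2).sum())
    ssb = float((np.bincount(labels, minlength=k)[:, None]
                 * (centroids - grand) ** 2).sum())
    return (ssb / (k - 1)) / (ssw / (n - k))


def precluster(scores: pd.DataFrame, k: int = 15, seed: int = 0,
               n_init: int = 100) -> PreclusterResult:
    """Seeded k-means preliminary clustering on Euclidean distance.

    Runs ``n_init`` k-means++ restarts and keeps the best-inertia solution;
    fully deterministic given ``seed``. The pseudo-F statistic of the
    chosen partition is reported as a diagnostic.
    """
    x = scores.to_numpy(dtype=float)
    if k > len(x):
        raise ValueError("k cannot exceed the number of entities")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed,
                algorithm="lloyd").fit(x)
    labels = km.labels_
    sizes = np.bincount(labels, minlength=k)
    return PreclusterResult(
        labels=pd.Series(labels + 1, index=scores.index, name="subcluster"),
        centroids=km.cluster_centers_, sizes=sizes,
        inertia=float(km.inertia_),
        pseudo_f=_pseudo_f(x, labels, km.cluster_centers_),
    )


def pseudo_f_scan(scores: pd.DataFrame, k_range=range(2, 21),
                  seed: int = 0, n_init: int = 10) -> pd.Series:
    """Pseudo-F over a range of k (diagnostic for choosing k)."""
    out = {}
    for k in k_range:
        if k >= len(scores):
            break
        out[k] = precluster(scores, k=k, seed=seed, n_init=n_init).pseudo_f
    return pd.Series(out, name="pseudo_F")


def _weighted_average_linkage(centroids: np.ndarray,
                              sizes: np.ndarray) -> np.ndarray:
    """Average-linkage agglomeration of pre-formed clusters.

    Initial between-cluster distances are Euclidean centroid distances;
    the Lance-Williams update d(i+j, k) = (n_i d_ik + n_j d_jk)/(n_i+n_j)
    then maintains exact average linkage over the underlying members (for
    the centroid initialization this is the standard weighted
    approximation). Returns a scipy-style linkage matrix.
    """
    k = centroids.shape[0]
    d = np.sqrt(((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    n = sizes.astype(float).copy()
    ids = np.arange(k)
    alive = np.ones(k, dtype=bool)
    d = np.pad(d, ((0, k - 1), (0, k - 1)), constant_values=np.inf)
    n = np.concatenate([n, np.zeros(k - 1)])
    ids = np.concatenate([ids, np.zeros(k - 1, dtype=int)])
    alive = np.concatenate([alive, np.zeros(k - 1, dtype=bool)])
    Z = np.zeros((k - 1, 4))
    leaves = np.concatenate([np.ones(k), np.zeros(k - 1)])
    nxt = k
    for step in range(k - 1):
        sub = np.where(alive)[0]
        dd = d[np.ix_(sub, sub)]
        i_loc, j_loc = np.unravel_index(np.argmin(dd), dd.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = sub[i_loc], sub[j_loc]
        h = d[i, j]
        for m in sub:
            if m not in (i, j):
                d[nxt, m] = d[m, nxt] = (n[i] * d[i, m] + n[j] * d[j, m]) / (n[i] + n[j])
        # the count column tracks merged leaves (preliminary clusters);
        # the member counts n[] drive the size-weighted update
        Z[step] = (min(i, j), max(i, j), h, leaves[i] + leaves[j])
        n[nxt] = n[i] + n[j]
        leaves[nxt] = leaves[i] + leaves[j]
        alive[i] = alive[j] = False
        alive[nxt] = True
        nxt += 1
    return Z


def hier_cluster(pre: PreclusterResult, n_main: int = 5,
                 main_labels: str = "ABCDEFGHIJKLMNOPQRSTUVWXYZ",
                 ) -> ClusterAssignment:
    """Average-linkage hierarchy over preliminary clusters, cut into n_main.

    Main clusters are labelled A, B, ... in order of first appearance in
    the dendrogram leaf order.
    """
    k = pre.centroids.shape[0]
    if n_main > k:
        raise ValueError("n_main cannot exceed the number of preliminary clusters")
    Z = _weighted_average_linkage(pre.centroids, pre.sizes)
    cut = hierarchy.fcluster(Z, t=n_main, criterion="maxclust")
    leaf_order = hierarchy.leaves_list(Z)
    seen, mapping = [], {}
    for leaf in leaf_order:
        c = cut[leaf]
        if c not in seen:
            mapping[c] = main_labels[len(seen)]
            seen.append(c)
    sub_to_main = pd.Series({s + 1: mapping[cut[s]] for s in range(k)},
                            name="main_cluster")
    main = pre.labels.map(sub_to_main)
    main.name = "main_cluster"
    tree = Tree(tree=_linkage_to_tree(Z, [f"sub{s + 1}" for s in range(k)]),
                merge_heights=Z[:, 2].copy(), linkage=Z)
    return ClusterAssignment(subcluster=pre.labels, main_cluster=main,
                             tree=tree, sub_to_main=sub_to_main)


def cluster_means(blues: pd.DataFrame, assignment: ClusterAssignment) -> pd.DataFrame:
    """Per-main-cluster and per-subcluster trait means (long summary table)."""
    df = blues.blues if isinstance(blues, BLUETable) else blues
    joined = df.join(assignment.subcluster).join(assignment.main_cluster)
    rows = []
    for main, grp in joined.groupby("main_cluster"):
        rows.append({"cluster": main, "subcluster": "", "N": len(grp),
                     **grp[list(df.columns)].mean().to_dict()})
        for sub, sgrp in grp.groupby("subcluster"):
            rows.append({"cluster": main, "subcluster": int(sub),
                         "N": len(sgrp),
                         **sgrp[list(df.columns)].mean().to_dict()})
    rows.append({"cluster": "Total", "subcluster": "", "N": len(joined),
                 **joined[list(df.columns)].mean().to_dict()})
    return pd.DataFrame(rows)


def summarize_collection(blues: pd.DataFrame,
                         checks: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean, range and quartiles per trait, plus one row per check entry.

    Quartiles use linear interpolation. ``checks`` rows (e.g. hybrid
    controls) are appended individually below the collection summary.
    """
    df = blues.blues if isinstance(blues, BLUETable) else blues
    if df.empty:
        raise ValueError("empty BLUE table")
    stats_rows = {
        "Mean": df.mean(),
        "Minimum": df.min(),
        "Q25": df.quantile(0.25, interpolation="linear"),
        "Median": df.quantile(0.50, interpolation="linear"),
        "Q75": df.quantile(0.75, interpolation="linear"),
        "Maximum": df.max(),
    }
    table = pd.DataFrame(stats_rows).T
    if checks is not None and len(checks):
        cdf = checks.blues if isinstance(checks, BLUETable) else checks
        check_block = pd.concat([pd.DataFrame({"Checks mean": cdf.mean()}).T, cdf])
        table = pd.concat([table, check_block])
    return table
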