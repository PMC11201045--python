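"""Simplex-constrained ancestry assignment by least squares.

Each landrace's allele-frequency vector is regressed on the allele
frequencies of K reference genetic groups; the coefficients are constrained
to be nonnegative and to sum to one and are interpreted as admixture
proportions. The problem

    min_beta ||f - G beta||^2   s.t.  beta >= 0,  sum(beta) = 1

is a convex quadratic program over the probability simplex, solved here with
an exact active-set method: on the current free set the equality-constrained
KKT system is solved directly, variables driven negative are fixed at zero,
and zero-fixed variables with negative multipliers are released until the
KKT conditions hold. For the small K of interest the solve is exact and
deterministic. No intercept is included: frequencies share a common scale
and an intercept would break the simplex interpretation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import logger


@dataclass
class AdmixtureCoefficients:
    """Landrace x group admixture proportions.

    Rows are nonnegative and sum to one (within 1e-8). ``rss`` is the
    residual sum of squares of each landrace's regression and ``n_loci`` the
    number of loci actually used (missing loci are excluded per landrace).
    """

    coef: pd.DataFrame
    rss: pd.Series | None = None
    n_loci: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.coef.to_numpy(dtype=float)
        ok = np.isfinite(vals).all(axis=1)
        if (vals[ok] < -1e-8).any():
            raise ValueError("admixture coefficients must be nonnegative")
        sums = vals[ok].sum(axis=1)
        if ok.any() and np.abs(sums - 1.0).max() > 1e-8:
            raise ValueError("admixture rows must sum to one")

    @property
    def group_labels(self) -> list:
        return list(self.coef.columns)


def _simplex_lstsq(G: np.ndarray, f: np.ndarray,
                   max_iter: int = 200) -> tuple[np.ndarray, float]:
    """Active-set solver for min ||f - G b||^2 on the probability simplex."""
    L, K = G.shape
    GtG = G.T @ G
    Gtf = G.T @ f
    # warn (once per call) on rank deficiency: solution may be non-unique
    if np.linalg.matrix_rank(GtG) < K:
        logger.warning("group-frequency matrix is rank deficient; "
                       "admixture solution may be non-unique")

    free = np.ones(K, dtype=bool)

    def solve_free(idx: np.ndarray) -> tuple[np.ndarray, float]:
        k = idx.sum()
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = GtG[np.ix_(idx, idx)]
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.concatenate([Gtf[idx], [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        return sol[:k], float(sol[k])

    lam = 0.0
    for _ in range(max_iter):
        beta_free, lam = solve_free(free)
        if (beta_free >= -1e-12).all():
            beta = np.zeros(K)
            beta[free] = np.clip(beta_free, 0.0, None)
            # KKT multipliers of the zero-fixed variables
            grad = GtG @ beta - Gtf
            mu = grad + lam
            fixed = ~free
            if fixed.any() and (mu[fixed] < -1e-10).any():
                # release the most violated fixed variable
                cand = np.where(fixed)[0]
                free[cand[np.argmin(mu[cand])]] = True
                continue
            beta /= beta.sum()
            rss = float(np.sum((f - G @ beta) ** 2))
            return beta, rss
        # fix the most negative free variable at zero
        cand = np.where(free)[0]
        free[cand[np.argmin(beta_free)]] = False
        if not free.any():  # pragma: no cover - cannot happen with sum-to-one
            raise RuntimeError("active-set solver emptied the free set")
    raise RuntimeError("active-set solver failed to converge")


def fit_admixture(f, group_freqs) -> tuple[np.ndarray, float]:
    """Admixture coefficients of one landrace.

    ``f`` is the landrace's frequency vector over L loci, ``group_freqs``
    the K x L group matrix (a GroupModel, DataFrame, or array). Loci where
    f is missing are excluded pairwise. Returns (beta, rss).
    """
    G = _as_group_matrix(group_freqs)
    f = np.asarray(f, dtype=float)
    if f.ndim != 1 or f.shape[0] != G.shape[1]:
        raise ValueError("frequency vector length must match group loci")
    keep = np.isfinite(f) & np.isfinite(G).all(axis=0)
    K = G.shape[0]
    if keep.sum() < K:
        raise ValueError(f"need at least K={K} observed loci, got {keep.sum()}")
    return _simplex_lstsq(G[:, keep].T, f[keep])


def _as_group_matrix(group_freqs) -> np.ndarray:
    if hasattr(group_freqs, "group_freqs"):  # GroupModel
        group_freqs = group_freqs.group_freqs
    if isinstance(group_freqs, pd.DataFrame):
        return group_freqs.to_numpy(dtype=float)
    return np.asarray(group_freqs, dtype=float)


def _group_labels(group_freqs, K: int) -> list:
    if hasattr(group_freqs, "group_freqs"):
        group_freqs = group_freqs.group_freqs
    if isinstance(group_freqs, pd.DataFrame):
        return list(group_freqs.index)
    return list(range(1, K + 1))


def fit_panel(panel, group_freqs) -> AdmixtureCoefficients:
    """Row-wise admixture regression over a whole panel.

    ``panel`` is a PanelFrequencies (or a landrace x locus DataFrame).
    Landraces whose regression fails (too few observed loci) are flagged
    with NaN coefficients rather than aborting the panel.
    """
    freq = panel.freq if hasattr(panel, "freq") else panel
    gdf = group_freqs.group_freqs if hasattr(group_freqs, "group_freqs") else group_freqs
    if isinstance(gdf, pd.DataFrame):
        # align loci by label; every panel locus must be present in the groups
        missing = freq.columns.difference(gdf.columns)
        if len(missing):
            raise ValueError(f"group frequencies lack loci {list(missing[:5])}...")
        gdf = gdf[freq.columns]
    G = _as_group_matrix(gdf)
    K = G.shape[0]
    labels = _group_labels(group_freqs, K)
    coefs = np.full((len(freq), K), np.nan)
    rss = np.full(len(freq), np.nan)
    nloc = np.zeros(len(freq), dtype=int)
    for i, (name, row) in enumerate(freq.iterrows()):
        try:
            beta, r = fit_admixture(row.to_numpy(dtype=float), G)
        except ValueError as exc:
            logger.warning("landrace %s: admixture fit skipped (%s)", name, exc)
            continue
        coefs[i] = beta
        rss[i] = r
        nloc[i] = int(np.isfinite(row.to_numpy(dtype=float)).sum())
    coef_df = pd.DataFrame(coefs, index=freq.index, columns=labels)
    return AdmixtureCoefficients(
        coef=coef_df,
        rss=pd.Series(rss, index=freq.index, name="rss"),
        n_loci=pd.Series(nloc, index=freq.index, name="n_loci"),
    )
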