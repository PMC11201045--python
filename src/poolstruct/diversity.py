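"""Diversity and differentiation statistics for pooled allele frequencies.

All statistics operate on a landrace x locus matrix of B-allele frequencies
(biallelic SNPs). Within-landrace summaries (allele number A, minor allele
frequency MAF, expected heterozygosity H_s = 2p(1-p), Nei's gene diversity)
average across loci; group/panel summaries use the unweighted per-locus mean
frequency across landraces. No small-sample correction is applied: with
pools of n diploid plants the unbiased-heterozygosity factor is 2n/(2n-1),
a deliberate, quantified omission (see ``unbiased_correction_factor``).

Distances: modified Roger's distance (MRD), a Euclidean-type distance on
frequency vectors, and a Nei-style pairwise Fst as a ratio of locus sums.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from ._utils import check_unit_interval, logger

VALID_METRICS = ("MRD", "FST", "EUCLIDEAN")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with zero diagonal."""

    values: pd.DataFrame
    metric: str = "MRD"

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(v - v.T), initial=0.0)
        if asym > 1e-12:
            raise ValueError(f"distance matrix asymmetric by {asym:g}")
        if np.abs(np.diag(v)).max(initial=0.0) != 0.0:
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.nanmin(v, initial=0.0) < 0:
            raise ValueError("distances must be nonnegative")

    @property
    def labels(self) -> list:
        return list(self.values.index)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def unbiased_correction_factor(n_individuals: int) -> float:
    """Factor 2n/(2n-1) by which the unbiased H exceeds the plug-in H.

    With pools of n = 15 diploid plants (30 gametes) the factor is 30/29,
    i.e. a 3.4% increase — small enough that the plug-in estimator is used
    throughout this module.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    return 2 * n_individuals / (2 * n_individuals - 1)


def locus_heterozygosity(p) -> np.ndarray:
    """Nei gene diversity per locus, H_l = 2 p (1 - p). No bias correction."""
    p = np.asarray(p, dtype=float)
    check_unit_interval(p, "allele frequencies")
    return 2.0 * p * (1.0 - p)


def _freq_matrix(panel) -> pd.DataFrame:
    return panel.freq if hasattr(panel, "freq") else panel


def landrace_summary(panel) -> pd.DataFrame:
    """Per-landrace diversity: A, MAF, H_s, each mean +/- SD across loci.

    A counts alleles per locus within the pool: 1 when the frequency is
    exactly 0 or 1, else 2. Landraces with no observed locus are excluded
    with a warning.
    """
    freq = _freq_matrix(panel)
    vals = freq.to_numpy(dtype=float)
    check_unit_interval(vals, "frequencies")
    obs = np.isfinite(vals)
    keep = obs.any(axis=1)
    if not keep.all():
        dropped = list(freq.index[~keep])
        logger.warning("excluding all-missing landraces: %s", dropped)
    vals, obs = vals[keep], obs[keep]

    a = np.where((vals == 0.0) | (vals == 1.0), 1.0, 2.0)
    maf = np.minimum(vals, 1.0 - vals)
    het = 2.0 * vals * (1.0 - vals)
    out = {}
    for name, m in (("A", a), ("MAF", maf), ("Hs", het)):
        masked = np.ma.masked_array(m, mask=~obs)
        out[f"{name}_mean"] = masked.mean(axis=1).filled(np.nan)
        out[f"{name}_sd"] = masked.std(axis=1, ddof=1).filled(np.nan)
    out["n_loci"] = obs.sum(axis=1)
    return pd.DataFrame(out, index=freq.index[keep])


def panel_summary(panel, subset=None) -> pd.Series:
    """Group/panel-level diversity from per-locus mean frequencies.

    The per-locus mean frequency p-bar (unweighted over landraces, missing
    excluded per locus) drives H_t(l) = 2 p-bar (1 - p-bar) and the
    group-level A and MAF. ``n_monomorphic`` counts loci at which every
    member landrace is fixed for the same allele.
    """
    freq = _freq_matrix(panel)
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("subset must be non-empty")
        freq = freq.loc[list(subset)]
    vals = freq.to_numpy(dtype=float)
    obs = np.isfinite(vals)
    masked = np.ma.masked_array(vals, mask=~obs)
    pbar = masked.mean(axis=0)
    ht_l = 2.0 * pbar * (1.0 - pbar)
    a_l = np.ma.where((pbar == 0.0) | (pbar == 1.0), 1.0, 2.0)
    maf_l = np.ma.minimum(pbar, 1.0 - pbar)
    all_zero = ((vals == 0.0) | ~obs).all(axis=0) & obs.any(axis=0)
    all_one = ((vals == 1.0) | ~obs).all(axis=0) & obs.any(axis=0)
    def _f(x):
        x = np.ma.filled(np.ma.asarray(x), np.nan)
        return float(x)

    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), \
            _warnings.catch_warnings():
        # single-locus panels have no SD (ddof=1); report NaN quietly
        _warnings.simplefilter("ignore", RuntimeWarning)
        return pd.Series({
            "n_landraces": freq.shape[0],
            "n_monomorphic": int(all_zero.sum() + all_one.sum()),
            "A_mean": _f(a_l.mean()), "A_sd": _f(a_l.std(ddof=1)),
            "MAF_mean": _f(maf_l.mean()), "MAF_sd": _f(maf_l.std(ddof=1)),
            "Ht_mean": _f(ht_l.mean()), "Ht_sd": _f(ht_l.std(ddof=1)),
        })


def gst(panel, subset=None) -> float:
    """Nei's G_st = (H_t - mean H_s) / H_t over landraces.

    H_t and mean H_s are averaged across loci; loci with H_t(l) = 0 are
    excluded from both averages. Returns NaN (with a warning) when every
    locus is fixed for the same allele.
    """
    freq = _freq_matrix(panel)
    if subset is not None:
        freq = freq.loc[list(subset)]
    if freq.shape[0] < 2:
        raise ValueError("G_st needs at least two landraces")
    vals = freq.to_numpy(dtype=float)
    obs = np.isfinite(vals)
    masked = np.ma.masked_array(vals, mask=~obs)
    pbar = masked.mean(axis=0)
    ht_l = np.asarray(2.0 * pbar * (1.0 - pbar))
    hs_l = np.asarray((2.0 * masked * (1.0 - masked)).mean(axis=0))
    keep = np.isfinite(ht_l) & (ht_l > 0)
    if not keep.any():
        logger.warning("all loci fixed for the same allele; G_st undefined")
        return float("nan")
    ht = float(np.mean(ht_l[keep]))
    hs = float(np.mean(hs_l[keep]))
    return (ht - hs) / ht


def mrd_matrix(panel, subset=None) -> DistanceMatrix:
    """Modified Roger's distance between all landrace pairs.

    MRD(i,j) = sqrt( (1/(2L)) sum_l sum_{alleles} (p_il - p_jl)^2 )
             = sqrt( (1/L) sum_l (p_il - p_jl)^2 )   for biallelic loci,
    with L the loci observed in both landraces (pairwise-complete).
    """
    freq = _freq_matrix(panel)
    if subset is not None:
        freq = freq.loc[list(subset)]
    if freq.shape[0] < 2:
        raise ValueError("need at least two landraces")
    vals = freq.to_numpy(dtype=float)
    if np.isfinite(vals).all():
        g = vals @ vals.T
        sq = np.diag(g)
        d2 = (sq[:, None] + sq[None, :] - 2.0 * g) / vals.shape[1]
        d = np.sqrt(np.clip(d2, 0.0, None))
    else:
        # nan_euclidean scales the partial sum by L / n_present; rescale to
        # the pairwise-complete mean squared difference
        with np.errstate(invalid="ignore"):
            d = nan_euclidean_distances(vals) / np.sqrt(vals.shape[1])
        if np.isnan(d[~np.eye(len(d), dtype=bool)]).any():
            logger.warning("landrace pairs with zero shared loci: MRD missing")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    df = pd.DataFrame(d, index=freq.index, columns=freq.index)
    return DistanceMatrix(df, metric="MRD")


def pairwise_fst(freqs, grouping=None) -> DistanceMatrix:
    """Pairwise Nei-style Fst between entities from their frequency vectors.

    For entities u, v: per locus H_t(l) = 2 p-bar (1 - p-bar) with
    p-bar = (p_u + p_v)/2 and H_w(l) the mean of the two within diversities;
    Fst(u,v) = (sum H_t - sum H_w) / sum H_t (ratio of locus sums). When
    ``grouping`` maps landraces to groups, entity vectors are the unweighted
    group mean frequencies.
    """
    freq = _freq_matrix(freqs)
    if grouping is not None:
        grouping = pd.Series(grouping)
        freq = freq.groupby(grouping.reindex(freq.index)).mean()
    if freq.shape[0] < 2:
        raise ValueError("need at least two entities")
    labels = freq.index
    vals = freq.to_numpy(dtype=float)
    n = vals.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pu, pv = vals[i], vals[j]
            keep = np.isfinite(pu) & np.isfinite(pv)
            pu, pv = pu[keep], pv[keep]
            pbar = (pu + pv) / 2.0
            ht = 2.0 * pbar * (1.0 - pbar)
            hw = (2.0 * pu * (1.0 - pu) + 2.0 * pv * (1.0 - pv)) / 2.0
            denom = ht.sum()
            if denom == 0:
                logger.warning("Fst undefined for pair (%s, %s)", labels[i], labels[j])
                out[i, j] = out[j, i] = np.nan
            else:
                out[i, j] = out[j, i] = (denom - hw.sum()) / denom
    df = pd.DataFrame(out, index=labels, columns=labels)
    return DistanceMatrix(df, metric="FST")


def group_table(panel, admix, threshold: float = 0.6) -> pd.DataFrame:
    """Per-group diversity summary restricted to highly assigned landraces.

    A landrace belongs to a group when its membership exceeds ``threshold``.
    Each row carries group size, monomorphic-SNP count, group- and
    within-level A and MAF, H_t, H_s, G_st and mean MRD between members.
    Empty groups yield a row with size 0 and missing statistics.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    coef = admix.coef if hasattr(admix, "coef") else admix
    freq = _freq_matrix(panel)
    rows = {}
    for group in coef.columns:
        members = coef.index[coef[group] > threshold]
        members = [m for m in members if m in freq.index]
        if not members:
            rows[group] = pd.Series({"size": 0}, dtype=float)
            continue
        sub = freq.loc[members]
        pl = panel_summary(sub)
        within = landrace_summary(sub)
        row = {
            "size": len(members),
            "n_monomorphic": pl["n_monomorphic"],
            "A_group_mean": pl["A_mean"], "A_group_sd": pl["A_sd"],
            "A_within_mean": within["A_mean"].mean(),
            "A_within_sd": within["A_mean"].std(ddof=1),
            "MAF_group_mean": pl["MAF_mean"], "MAF_group_sd": pl["MAF_sd"],
            "MAF_within_mean": within["MAF_mean"].mean(),
            "MAF_within_sd": within["MAF_mean"].std(ddof=1),
            "Ht_mean": pl["Ht_mean"], "Ht_sd": pl["Ht_sd"],
            "Hs_mean": within["Hs_mean"].mean(),
            "Hs_sd": within["Hs_mean"].std(ddof=1),
        }
        if len(members) >= 2:
            row["Gst"] = gst(sub)
            d = mrd_matrix(sub).to_numpy()
            iu = np.triu_indices(len(members), k=1)
            row["MRD_mean"] = float(np.nanmean(d[iu]))
            row["MRD_sd"] = float(np.nanstd(d[iu], ddof=1)) if len(iu[0]) > 1 else np.nan
        rows[group] = pd.Series(row, dtype=float)
    table = pd.DataFrame(rows).T
    table.index.name = "group"
    return table
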