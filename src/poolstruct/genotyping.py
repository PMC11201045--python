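"""Pooled-DNA allele-frequency calling from SNP-array fluorescence.

Each landrace is genotyped as a single DNA pool of plants, so a SNP yields a
population allele frequency rather than an individual genotype. Calling is a
two-step procedure driven by the fluorescence intensity ratio (FIR) of the
two allele channels:

1. test each landrace x SNP entry for monomorphism against the homozygous
   fluorescence clusters of controlled (known-frequency) pools;
2. for entries declared polymorphic, predict the B-allele frequency with a
   binomial GLM (logit link) calibrated on the controlled pools.

Monomorphic entries are set to exactly 0 or 1, which makes the procedure
conservative for loci at or near fixation: a truly fixed pool that is not
rejected carries zero estimation error.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._utils import LOGIT_EPS, check_unit_interval, inv_logit, logger, logit


class CalibrationError(ValueError):
    """Raised when the controlled-pool table cannot support a calibration."""


@dataclass
class CalibrationModel:
    """Fitted FIR -> frequency link plus homozygous-cluster statistics.

    The link operates on the logit scale: logit(f) = a + b * logit(FIR).
    (mu_A, sd_A) and (mu_B, sd_B) are the mean/SD of the FIR over controlled
    pools fixed for allele A (known frequency 0) and allele B (frequency 1);
    they parameterize the one-sided monomorphism test of size ``alpha``.
    """

    a: float
    b: float
    mu_A: float
    sd_A: float
    mu_B: float
    sd_B: float
    alpha: float = 0.05
    validation_mae: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (self.sd_A > 0 and self.sd_B > 0):
            raise CalibrationError("homozygous-cluster SDs must be positive")
        if not self.mu_A < self.mu_B:
            raise CalibrationError("mu_A must be below mu_B")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PanelFrequencies:
    """Landrace x locus matrix of B-allele frequencies in [0, 1].

    ``freq`` holds NaN for missing entries. ``polymorphic`` (same shape,
    nullable boolean) marks entries that passed the polymorphism test;
    monomorphic non-missing entries are exactly 0 or 1.
    """

    freq: pd.DataFrame
    polymorphic: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        check_unit_interval(self.freq.to_numpy(dtype=float), "frequencies")
        if self.polymorphic is not None:
            if not self.freq.index.equals(self.polymorphic.index) or not (
                self.freq.columns.equals(self.polymorphic.columns)
            ):
                raise ValueError("freq and polymorphic must share labels")
            mono = (self.polymorphic == False).to_numpy()  # noqa: E712
            vals = self.freq.to_numpy(dtype=float)
            bad = mono & np.isfinite(vals) & (vals != 0.0) & (vals != 1.0)
            if bad.any():
                raise ValueError("monomorphic entries must be exactly 0 or 1")

    @property
    def landraces(self) -> list:
        return list(self.freq.index)

    @property
    def loci(self) -> list:
        return list(self.freq.columns)

    @property
    def missing(self) -> pd.DataFrame:
        return self.freq.isna()

    def subset(self, landraces) -> "PanelFrequencies":
        poly = None if self.polymorphic is None else self.polymorphic.loc[landraces]
        return PanelFrequencies(self.freq.loc[landraces], poly)


def compute_fir(fluo: pd.DataFrame) -> pd.DataFrame:
    """FIR matrix (landrace x locus) from a long fluorescence table.

    ``fluo`` columns: landrace, snp, intensity_A, intensity_B. FIR is the
    B-channel share, I_B / (I_A + I_B). Entries with zero total intensity
    are flagged missing (NaN) with a logged warning; missing propagates.
    """
    required = {"landrace", "snp", "intensity_A", "intensity_B"}
    if not required.issubset(fluo.columns):
        raise ValueError(f"fluorescence table needs columns {sorted(required)}")
    ia = fluo["intensity_A"].to_numpy(dtype=float)
    ib = fluo["intensity_B"].to_numpy(dtype=float)
    if np.nanmin(ia, initial=0.0) < 0 or np.nanmin(ib, initial=0.0) < 0:
        raise ValueError("intensities must be nonnegative")
    total = ia + ib
    with np.errstate(invalid="ignore", divide="ignore"):
        fir = np.where(total > 0, ib / total, np.nan)
    n_zero = int((total == 0).sum())
    if n_zero:
        logger.warning("%d entries with zero total intensity set missing", n_zero)
    out = fluo[["landrace", "snp"]].copy()
    out["fir"] = fir
    wide = out.pivot(index="landrace", columns="snp", values="fir")
    # preserve the order of first appearance (pivot sorts lexicographically)
    wide = wide.reindex(index=out["landrace"].unique(),
                        columns=out["snp"].unique())
    return wide


def _calibration_fir(cal: pd.DataFrame) -> pd.Series:
    return cal["intensity_B"] / (cal["intensity_A"] + cal["intensity_B"])


def fit_calibration(cal: pd.DataFrame, alpha: float = 0.05,
                    n_plants: int = 15) -> CalibrationModel:
    """Fit the FIR -> frequency GLM and homozygous-cluster statistics.

    ``cal`` columns: snp, series (1 or 2), known_freq, intensity_A,
    intensity_B. Cluster statistics use all rows with known frequency 0
    (allele A fixed) or 1 (allele B fixed). The GLM — binomial family,
    logit link, response = known frequency weighted by 2*n_plants gametes,
    covariate = logit(FIR) — is trained on the interior rows of series 1;
    series 2 interior rows are held out and their mean absolute prediction
    error is logged and stored on the model.
    """
    required = {"snp", "series", "known_freq", "intensity_A", "intensity_B"}
    if not required.issubset(cal.columns):
        raise CalibrationError(f"calibration table needs columns {sorted(required)}")
    check_unit_interval(cal["known_freq"], "known_freq")
    fir = _calibration_fir(cal)

    fixed_a = fir[cal["known_freq"] == 0.0]
    fixed_b = fir[cal["known_freq"] == 1.0]
    if fixed_a.empty or fixed_b.empty:
        raise CalibrationError(
            "calibration requires rows with known_freq = 0 and known_freq = 1"
        )
    mu_a, sd_a = float(fixed_a.mean()), float(fixed_a.std(ddof=1))
    mu_b, sd_b = float(fixed_b.mean()), float(fixed_b.std(ddof=1))
    if not (sd_a > 0 and sd_b > 0):
        raise CalibrationError("degenerate homozygous cluster (zero SD)")

    interior = (cal["known_freq"] > 0) & (cal["known_freq"] < 1)
    train = interior & (cal["series"] == 1)
    if cal.loc[train, "known_freq"].nunique() < 2:
        raise CalibrationError("need >= 2 distinct interior frequencies in series 1")

    x = logit(fir[train].to_numpy())
    y = cal.loc[train, "known_freq"].to_numpy(dtype=float)
    exog = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect-fit binomial warnings on exact data
        res = sm.GLM(y, exog, family=sm.families.Binomial(),
                     freq_weights=np.full(y.shape, 2.0 * n_plants)).fit()
    a, b = float(res.params[0]), float(res.params[1])

    model = CalibrationModel(a=a, b=b, mu_A=mu_a, sd_A=sd_a,
                             mu_B=mu_b, sd_B=sd_b, alpha=alpha)
    holdout = interior & (cal["series"] == 2)
    if holdout.any():
        pred = inv_logit(a + b * logit(fir[holdout].to_numpy()))
        mae = float(np.mean(np.abs(pred - cal.loc[holdout, "known_freq"].to_numpy())))
        model.validation_mae = mae
        logger.info("calibration held-out MAE on series 2: %.4f", mae)
    return model


def test_polymorphism(fir: pd.DataFrame, model: CalibrationModel) -> pd.DataFrame:
    """One-sided z-test of monomorphism per landrace x SNP entry.

    The nearer homozygous cluster is chosen by |FIR - mu_c|; the entry is
    declared polymorphic iff the FIR deviates from that cluster mean toward
    the interior by more than z_{1-alpha} * sd_c. Deviations away from the
    interior never reject, so a truly monomorphic pool is rejected with
    probability alpha. Returns a nullable-boolean frame; missing propagates.
    """
    vals = fir.to_numpy(dtype=float)
    z = stats.norm.ppf(1.0 - model.alpha)
    nearer_a = np.abs(vals - model.mu_A) <= np.abs(vals - model.mu_B)
    dev = np.where(nearer_a, vals - model.mu_A, model.mu_B - vals)
    sd = np.where(nearer_a, model.sd_A, model.sd_B)
    poly = dev > z * sd
    out = pd.DataFrame(poly, index=fir.index, columns=fir.columns).astype("boolean")
    out = out.mask(~np.isfinite(vals))
    return out


def predict_frequencies(fir: pd.DataFrame, poly: pd.DataFrame,
                        model: CalibrationModel) -> PanelFrequencies:
    """B-allele frequencies from FIR given the polymorphism calls.

    Polymorphic entries get invlogit(a + b * logit(FIR)) (FIR clipped away
    from the boundary), clipped to [0, 1]; monomorphic entries get exactly 0
    or 1 according to the nearer homozygous cluster.
    """
    if not (fir.index.equals(poly.index) and fir.columns.equals(poly.columns)):
        raise ValueError("fir and poly must be conformable")
    vals = fir.to_numpy(dtype=float)
    fhat = np.clip(inv_logit(model.a + model.b * logit(vals, LOGIT_EPS)), 0.0, 1.0)
    nearer_a = np.abs(vals - model.mu_A) <= np.abs(vals - model.mu_B)
    mono_val = np.where(nearer_a, 0.0, 1.0)
    is_poly = poly.to_numpy(dtype=object)
    freq = np.where(is_poly == True, fhat, mono_val)  # noqa: E712
    freq = np.where(np.isfinite(vals), freq, np.nan)
    freq_df = pd.DataFrame(freq.astype(float), index=fir.index, columns=fir.columns)
    return PanelFrequencies(freq_df, poly)


def call_frequencies(fluo: pd.DataFrame, cal: pd.DataFrame,
                     alpha: float = 0.05, n_plants: int = 15) -> PanelFrequencies:
    """Full two-step pipeline: FIR -> monomorphism test -> frequency call."""
    fir = compute_fir(fluo)
    model = fit_calibration(cal, alpha=alpha, n_plants=n_plants)
    poly = test_polymorphism(fir, model)
    return predict_frequencies(fir, poly, model)
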