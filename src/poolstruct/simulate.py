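"""Synthetic landrace panels with realistic population structure.

Pooled-genotyping studies of genebank collections are routinely under data
embargo, so every downstream stage of this package is exercised on
simulated panels built to the statistical blueprint such studies share:

* K ancestral genetic groups whose allele frequencies drift from a shared
  ancestral frequency under the Balding-Nichols model (a Beta distribution
  whose dispersion parameter is the target Fst per group);
* landraces as admixtures of those groups — most with one dominant ancestry
  (membership >= 0.75), the rest deliberately "admixed" (no membership
  reaching 0.6, mirroring the downstream assignment rule by construction);
* pools of ``n_plants`` diploid plants, so observed pool frequencies are
  binomial counts over 2 * n_plants gametes (multiples of 1/30 at the
  default pool size of 15);
* two-channel array fluorescence whose B-channel share (FIR) follows a
  logit-linear link to the true frequency with truncated Gaussian noise,
  plus a controlled-pool calibration table in two series;
* multi-environment trial records (days to tasseling/silking, plant and ear
  height) with group-level means, landrace deviations, random trial effects
  and residual noise, each landrace grown in 2-9 locations.

Defaults are sized for desk-scale runs (L = 2500 loci, K = 9 groups,
120 landraces) while keeping the structural constants of the emulated
study: 15-plant pools, a 0.6 assignment threshold, an admixed fraction of
0.44, and 2-9 trial locations per landrace.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import check_unit_interval, inv_logit, logit, rng_from_seed
from .ancestry import AdmixtureCoefficients
from .genotyping import PanelFrequencies

#: desk-scale defaults (real panels run to tens of thousands of SNPs and
#: several hundred pools; these sizes keep test runs fast)
DEFAULT_L = 2500
DEFAULT_K = 9
DEFAULT_N_LANDRACES = 120
DEFAULT_N_PLANTS = 15
DEFAULT_FRAC_ADMIXED = 0.44
DEFAULT_DRIFT = 0.01
DEFAULT_NOISE_SD = 0.02
DEFAULT_LINK = (0.0, 1.0)
DEFAULT_MU_A = 0.02
DEFAULT_MU_B = 0.98


@dataclass
class GroupModel:
    """Ancestral-group allele frequencies (groups x loci)."""

    group_freqs: pd.DataFrame
    ancestral_freqs: np.ndarray | None = None
    fst_per_group: np.ndarray | None = None

    def __post_init__(self) -> None:
        check_unit_interval(self.group_freqs.to_numpy(), "group frequencies")
        if self.group_freqs.shape[0] < 2:
            raise ValueError("need at least two groups")

    @property
    def group_labels(self) -> list:
        return list(self.group_freqs.index)

    @property
    def n_groups(self) -> int:
        return self.group_freqs.shape[0]

    @property
    def n_loci(self) -> int:
        return self.group_freqs.shape[1]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated panel: admixture rows and pool frequencies."""

    true_admixture: AdmixtureCoefficients
    true_pool_freqs: PanelFrequencies
    latent_freqs: pd.DataFrame = field(repr=False)
    drift_coefficient: float = DEFAULT_DRIFT
    n_plants: int = DEFAULT_N_PLANTS
    seed: int = 0

    @property
    def landraces(self) -> list:
        return list(self.true_pool_freqs.freq.index)


@dataclass
class TrialDesign:
    """Layout of a multi-environment trial series.

    ``assignment`` maps each landrace to 2-9 trial locations; the standard
    deviations may be scalars or per-trait mappings for (DT, DS, PH, EH).
    """

    locations: list
    reps_per_location: int
    assignment: dict
    trait_means: pd.DataFrame  # group x (DT, DS, PH, EH)
    env_effect_sd: dict | float
    residual_sd: dict | float
    landrace_sd: dict | float
    check_means: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for lr, locs in self.assignment.items():
            if len(locs) < 2:
                raise ValueError(f"landrace {lr} assigned to fewer than 2 locations")
        for sd in (self.env_effect_sd, self.residual_sd, self.landrace_sd):
            vals = list(sd.values()) if isinstance(sd, dict) else [sd]
            if any(v < 0 for v in vals):
                raise ValueError("standard deviations must be nonnegative")


def _balding_nichols(rng, p_anc: np.ndarray, fst: float) -> np.ndarray:
    """Draw drifted frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F) per locus."""
    scale = (1.0 - fst) / fst
    interior = (p_anc > 0) & (p_anc < 1)
    out = p_anc.copy()
    if interior.any():
        out[interior] = rng.beta(p_anc[interior] * scale,
                                 (1.0 - p_anc[interior]) * scale)
    return out


def generate_group_frequencies(L: int = DEFAULT_L, K: int = DEFAULT_K,
                               fst=0.2, seed: int = 0) -> GroupModel:
    """Ancestral groups under the Balding-Nichols structure model.

    Ancestral frequencies are Uniform(0.05, 0.95) per locus; each group
    drifts independently with its own Fst-like dispersion parameter.
    """
    if L < 1 or K < 2:
        raise ValueError("need L >= 1 loci and K >= 2 groups")
    fst = np.broadcast_to(np.asarray(fst, dtype=float), (K,)).copy()
    if not np.isfinite(fst).all() or (fst <= 0).any() or (fst >= 1).any():
        raise ValueError("each fst must lie in (0, 1)")
    rng = rng_from_seed(seed)
    p_anc = rng.uniform(0.05, 0.95, size=L)
    groups = np.vstack([_balding_nichols(rng, p_anc, f) for f in fst])
    labels = [f"K{k + 1}" for k in range(K)]
    loci = [f"snp{l + 1}" for l in range(L)]
    return GroupModel(pd.DataFrame(groups, index=labels, columns=loci),
                      ancestral_freqs=p_anc, fst_per_group=fst)


def generate_landraces(gm: GroupModel, n_landraces: int = DEFAULT_N_LANDRACES,
                       frac_admixed: float = DEFAULT_FRAC_ADMIXED,
                       drift: float = DEFAULT_DRIFT,
                       n_plants: int = DEFAULT_N_PLANTS,
                       seed: int = 0) -> SyntheticTruth:
    """Simulate landrace pools as admixtures of the ancestral groups.

    Assigned landraces get one dominant ancestry component >= 0.75 (groups
    cycled); admixed landraces get flat-Dirichlet rows resampled until no
    component reaches 0.6. The latent landrace frequency is the admixture
    mixture of group frequencies, drifted within-landrace by Balding-
    Nichols with parameter ``drift``; the observed pool frequency is a
    binomial gamete count over 2 * n_plants.
    """
    if not 0 <= frac_admixed <= 1:
        raise ValueError("frac_admixed must lie in [0, 1]")
    if not 0 <= drift < 1:
        raise ValueError("drift must lie in [0, 1)")
    K = gm.n_groups
    if n_landraces < K:
        raise ValueError("need at least one landrace per group")
    rng = rng_from_seed(seed)
    n_admixed = int(round(frac_admixed * n_landraces))
    n_assigned = n_landraces - n_admixed

    alphas = np.zeros((n_landraces, K))
    for i in range(n_assigned):
        k = i % K
        w = rng.uniform(0.75, 1.0)
        rest = rng.dirichlet(np.ones(K - 1)) * (1.0 - w)
        alphas[i, k] = w
        alphas[i, np.arange(K) != k] = rest
    for i in range(n_assigned, n_landraces):
        while True:
            row = rng.dirichlet(np.ones(K))
            if row.max() < 0.6:
                alphas[i] = row
                break

    G = gm.group_freqs.to_numpy()
    latent = alphas @ G
    if drift > 0:
        latent = np.vstack([_balding_nichols(rng, latent[i], drift)
                            for i in range(n_landraces)])
    counts = rng.binomial(2 * n_plants, latent)
    pool = counts / (2.0 * n_plants)

    idx = [f"LR{i + 1:04d}" for i in range(n_landraces)]
    admix = AdmixtureCoefficients(
        pd.DataFrame(alphas, index=idx, columns=gm.group_labels))
    panel = PanelFrequencies(
        pd.DataFrame(pool, index=idx, columns=gm.group_freqs.columns))
    return SyntheticTruth(true_admixture=admix, true_pool_freqs=panel,
                          latent_freqs=pd.DataFrame(
                              latent, index=idx, columns=gm.group_freqs.columns),
                          drift_coefficient=drift, n_plants=n_plants,
                          seed=int(seed) if np.isscalar(seed) else 0)


def _fir_mean(f: np.ndarray, a: float, b: float,
              mu_a: float, mu_b: float) -> np.ndarray:
    """Latent FIR mean: logit-linear link for interior f, cluster means at 0/1."""
    mean = inv_logit(a + b * logit(f))
    mean = np.where(f == 0.0, mu_a, mean)
    mean = np.where(f == 1.0, mu_b, mean)
    return mean


def _truncnorm_unit(rng, mean: np.ndarray, sd: float) -> np.ndarray:
    lo = (0.0 - mean) / sd
    hi = (1.0 - mean) / sd
    u = rng.uniform(size=mean.shape)
    return stats.truncnorm.ppf(u, lo, hi, loc=mean, scale=sd)


def _intensities(rng, fir: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    total = rng.uniform(800.0, 1200.0, size=fir.shape)
    return total * (1.0 - fir), total * fir


def generate_fluorescence(truth: SyntheticTruth,
                          link_params: tuple[float, float] = DEFAULT_LINK,
                          noise_sd: float = DEFAULT_NOISE_SD,
                          n_calibration_snps: int = 1000,
                          seed: int = 0,
                          mu_A: float = DEFAULT_MU_A,
                          mu_B: float = DEFAULT_MU_B,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-channel fluorescence for the panel plus a controlled-pool table.

    Observed FIR = truncated-Normal(link(f), noise_sd) on [0, 1]; channel
    intensities are emitted so that I_B / (I_A + I_B) reproduces the FIR
    exactly. The calibration table holds ``n_calibration_snps`` controlled
    pools with known frequencies cycling over the gamete grid
    {0, 1/2n, ..., 1}, split into two series (train / validation).
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if n_calibration_snps < 10:
        raise ValueError("need at least 10 calibration SNPs")
    a, b = link_params
    rng = rng_from_seed(seed)
    freq = truth.true_pool_freqs.freq
    f = freq.to_numpy()
    fir = _truncnorm_unit(rng, _fir_mean(f, a, b, mu_A, mu_B), noise_sd)
    ia, ib = _intensities(rng, fir)
    fluo = pd.DataFrame({
        "landrace": np.repeat(freq.index, freq.shape[1]),
        "snp": np.tile(freq.columns, freq.shape[0]),
        "intensity_A": ia.ravel(),
        "intensity_B": ib.ravel(),
    })

    grid = np.arange(2 * truth.n_plants + 1) / (2.0 * truth.n_plants)
    known = grid[np.arange(n_calibration_snps) % len(grid)]
    series = np.where(np.arange(n_calibration_snps) % 2 == 0, 1, 2)
    cal_fir = _truncnorm_unit(rng, _fir_mean(known, a, b, mu_A, mu_B), noise_sd)
    ca, cb = _intensities(rng, cal_fir)
    cal = pd.DataFrame({
        "snp": [f"cal{i + 1}" for i in range(n_calibration_snps)],
        "series": series,
        "known_freq": known,
        "intensity_A": ca,
        "intensity_B": cb,
    })
    return fluo, cal


def default_trial_design(truth: SyntheticTruth, n_locations: int = 8,
                         reps_per_location: int = 2, seed: int = 0,
                         n_checks: int = 5) -> TrialDesign:
    """A realistic unbalanced layout: each landrace in 2-9 of the locations.

    Group trait means ladder across maturity: days to tasseling 60-85 d,
    silking 2-3 d later, plant height 120-210 cm with ears at ~45% of plant
    height. Checks (hybrid controls) are grown at every location.
    """
    rng = rng_from_seed(seed)
    K = truth.true_admixture.coef.shape[1]
    locations = [f"T{j + 1:02d}" for j in range(n_locations)]
    assignment = {}
    for lr in truth.landraces:
        n_loc = int(rng.integers(2, min(9, n_locations) + 1))
        assignment[lr] = sorted(rng.choice(locations, size=n_loc, replace=False))
    dt = np.linspace(60.0, 85.0, K)
    ph = np.linspace(120.0, 210.0, K)
    trait_means = pd.DataFrame({
        "DT": dt, "DS": dt + np.linspace(2.0, 3.0, K),
        "PH": ph, "EH": 0.45 * ph,
    }, index=truth.true_admixture.coef.columns)
    check_dt = np.linspace(68.0, 85.0, n_checks)
    check_means = pd.DataFrame({
        "DT": check_dt, "DS": check_dt + 0.4,
        "PH": np.full(n_checks, 205.0), "EH": np.full(n_checks, 92.0),
    }, index=[f"CHK{i + 1}" for i in range(n_checks)])
    return TrialDesign(
        locations=locations, reps_per_location=reps_per_location,
        assignment=assignment, trait_means=trait_means,
        env_effect_sd={"DT": 2.5, "DS": 2.5, "PH": 8.0, "EH": 5.0},
        residual_sd={"DT": 1.5, "DS": 1.5, "PH": 6.0, "EH": 4.0},
        landrace_sd={"DT": 3.0, "DS": 3.0, "PH": 10.0, "EH": 6.0},
        check_means=check_means,
    )


TRAITS_RAW = ("DT", "DS", "PH", "EH")


def _sd(spec, trait: str) -> float:
    return float(spec[trait]) if isinstance(spec, dict) else float(spec)


def true_landrace_means(truth: SyntheticTruth, design: TrialDesign,
                        seed: int = 0) -> pd.DataFrame:
    """Deterministic per-landrace true trait means implied by a design.

    Mean = admixture-weighted group mean + landrace deviation (seeded by
    ``seed``, the same stream generate_trials uses first).
    """
    rng = rng_from_seed(seed)
    alphas = truth.true_admixture.coef.to_numpy()
    base = alphas @ design.trait_means.to_numpy()
    means = pd.DataFrame(base, index=truth.landraces,
                         columns=design.trait_means.columns)
    for trait in TRAITS_RAW:
        means[trait] += rng.normal(0.0, _sd(design.landrace_sd, trait),
                                   size=len(means))
    # silking never precedes tasseling in expectation
    means["DS"] = np.maximum(means["DS"], means["DT"])
    means["EH"] = np.clip(means["EH"], 1.0, means["PH"] - 1.0)
    return means


def generate_trials(truth: SyntheticTruth, design: TrialDesign,
                    seed: int = 0) -> pd.DataFrame:
    """Long-format multi-environment trial records.

    Each observation = landrace true mean + random trial effect + residual.
    Columns: landrace, trial, rep, DT, DS, PH, EH, is_check.
    """
    rng = rng_from_seed(seed)
    means = true_landrace_means(truth, design, seed=rng)
    trial_eff = {
        trait: {loc: rng.normal(0.0, _sd(design.env_effect_sd, trait))
                for loc in design.locations}
        for trait in TRAITS_RAW
    }
    entries = [(lr, loc) for lr in truth.landraces
               for loc in design.assignment[lr]]
    if design.check_means is not None:
        entries += [(chk, loc) for chk in design.check_means.index
                    for loc in design.locations]
    rows = []
    for lr, loc in entries:
        is_check = design.check_means is not None and lr in design.check_means.index
        mu = design.check_means.loc[lr] if is_check else means.loc[lr]
        for rep in range(1, design.reps_per_location + 1):
            rec = {"landrace": lr, "trial": loc, "rep": rep,
                   "is_check": is_check}
            for trait in TRAITS_RAW:
                rec[trait] = (mu[trait] + trial_eff[trait][loc]
                              + rng.normal(0.0, _sd(design.residual_sd, trait)))
            rows.append(rec)
    records = pd.DataFrame(rows)
    records["EH"] = np.clip(records["EH"], 0.0, records["PH"])
    return records[["landrace", "trial", "rep", "DT", "DS", "PH", "EH", "is_check"]]
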