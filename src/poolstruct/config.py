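"""Pipeline configuration and orchestration.

``PipelineConfig`` collects every stage parameter (defaults are the
analysis constants used throughout: monomorphism test size 0.05, group
membership threshold 0.6, 5 simulated individuals at 2500 loci, 15
preliminary clusters cut into 5 main clusters) together with explicit
per-stage seeds, and can round-trip through YAML. ``run_pipeline`` executes
the two pipelines — genotype (fluorescence -> frequencies -> diversity /
structure / ancestry) and phenotype (trials -> BLUEs -> PCA -> clusters) —
on a synthetic panel, writing every output under one directory and a JSON
manifest recording stage parameters, seeds, and content hashes.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import ancestry, diversity, genotyping, io, phenotype, simulate, structure
from ._utils import logger


def _default_seeds() -> dict:
    return {"groups": 11, "landraces": 12, "fluorescence": 13,
            "trials": 14, "genotypes": 15, "precluster": 16}


@dataclass
class PipelineConfig:
    """All stage parameters of the synthetic end-to-end pipeline."""

    # genotype pipeline
    n_loci: int = simulate.DEFAULT_L
    n_groups: int = simulate.DEFAULT_K
    n_landraces: int = simulate.DEFAULT_N_LANDRACES
    n_plants: int = simulate.DEFAULT_N_PLANTS
    frac_admixed: float = simulate.DEFAULT_FRAC_ADMIXED
    drift: float = simulate.DEFAULT_DRIFT
    group_fst: float = 0.2
    noise_sd: float = simulate.DEFAULT_NOISE_SD
    n_calibration_snps: int = 1000
    alpha: float = 0.05
    membership_threshold: float = 0.6
    n_sim_individuals: int = 5
    n_sim_loci: int = 2500
    # phenotype pipeline
    k_preliminary: int = 15
    n_main_clusters: int = 5
    seeds: dict = field(default_factory=_default_seeds)
    out_dir: str = "poolstruct_out"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.membership_threshold <= 1:
            raise ValueError("membership_threshold must be in (0, 1]")
        for stage in _default_seeds():
            if stage not in self.seeds:
                raise ValueError(f"missing seed for stage {stage!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Derive all stage seeds deterministically from one master seed."""
        seeds = {stage: (seed * 1000003 + i) % (2**31 - 1)
                 for i, stage in enumerate(sorted(_default_seeds()))}
        return dataclasses.replace(self, seeds=seeds)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic pipeline; returns the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.seeds
    outputs: dict[str, Path] = {}

    # --- synthetic truth -------------------------------------------------
    gm = simulate.generate_group_frequencies(
        config.n_loci, config.n_groups, fst=config.group_fst,
        seed=seeds["groups"])
    truth = simulate.generate_landraces(
        gm, config.n_landraces, frac_admixed=config.frac_admixed,
        drift=config.drift, n_plants=config.n_plants,
        seed=seeds["landraces"])
    fluo, cal = simulate.generate_fluorescence(
        truth, noise_sd=config.noise_sd,
        n_calibration_snps=config.n_calibration_snps,
        seed=seeds["fluorescence"])
    fluo.to_csv(out / "fluorescence.csv", index=False,
                float_format=io.FLOAT_FMT)
    cal.to_csv(out / "calibration.csv", index=False, float_format=io.FLOAT_FMT)
    io.write_admixture(truth.true_admixture, out / "true_admixture.csv")
    outputs |= {"fluorescence": out / "fluorescence.csv",
                "calibration": out / "calibration.csv",
                "true_admixture": out / "true_admixture.csv"}

    # --- genotype pipeline ----------------------------------------------
    panel = genotyping.call_frequencies(fluo, cal, alpha=config.alpha,
                                        n_plants=config.n_plants)
    io.write_frequency_matrix(panel, out / "frequencies.csv",
                              out / "polymorphic_mask.csv")
    outputs |= {"frequencies": out / "frequencies.csv",
                "polymorphic_mask": out / "polymorphic_mask.csv"}

    diversity.landrace_summary(panel).to_csv(
        out / "diversity_landraces.csv", float_format=io.FLOAT_FMT)
    mrd = diversity.mrd_matrix(panel)
    io.write_distance_matrix(mrd, out / "mrd.csv")
    outputs |= {"diversity": out / "diversity_landraces.csv",
                "mrd": out / "mrd.csv"}

    assignment = structure.assign_groups(
        truth.true_admixture, threshold=config.membership_threshold)
    logger.info("assignment threshold %.2f: %d assigned / %d admixed",
                config.membership_threshold,
                int((assignment["group"] != structure.ADMIXED_LABEL).sum()),
                int((assignment["group"] == structure.ADMIXED_LABEL).sum()))
    assignment.to_csv(out / "assignment.csv")
    group_freqs = structure.estimate_group_frequencies(panel, assignment)
    group_freqs.group_freqs.to_csv(out / "group_frequencies.csv",
                                   float_format=io.FLOAT_FMT)
    fst = diversity.pairwise_fst(group_freqs.group_freqs)
    io.write_distance_matrix(fst, out / "group_fst.csv")
    table = diversity.group_table(panel, truth.true_admixture,
                                  threshold=config.membership_threshold)
    table.to_csv(out / "group_table.csv", float_format=io.FLOAT_FMT)
    outputs |= {"assignment": out / "assignment.csv",
                "group_frequencies": out / "group_frequencies.csv",
                "group_fst": out / "group_fst.csv",
                "group_table": out / "group_table.csv"}

    admix_hat = ancestry.fit_panel(panel, group_freqs)
    io.write_admixture(admix_hat, out / "ancestry.csv")
    outputs["ancestry"] = out / "ancestry.csv"

    coords = structure.pcoa(mrd)
    coords.coordinates.iloc[:, :10].to_csv(out / "pcoa.csv",
                                           float_format=io.FLOAT_FMT)
    io.write_newick(structure.ward_tree(mrd), out / "ward.nwk")
    genos = structure.simulate_individuals(
        panel, n_ind=config.n_sim_individuals,
        n_loci=min(config.n_sim_loci, config.n_loci), seed=seeds["genotypes"])
    structure.write_ped_map(genos, str(out / "simulated_genotypes"))
    outputs |= {"pcoa": out / "pcoa.csv", "ward": out / "ward.nwk",
                "ped": out / "simulated_genotypes.ped",
                "map": out / "simulated_genotypes.map"}

    # --- phenotype pipeline ----------------------------------------------
    design = simulate.default_trial_design(truth, seed=seeds["trials"])
    records = simulate.generate_trials(truth, design, seed=seeds["trials"])
    io.write_trial_records(records, out / "trials.csv")
    blues = phenotype.blue_table(records[~records["is_check"]])
    checks = records[records["is_check"]]
    blues.blues.to_csv(out / "blues.csv", float_format=io.FLOAT_FMT)
    pca = phenotype.pheno_pca(blues)
    pca.loadings.assign(eigenvalue=pca.eigenvalues,
                        pct_variance=pca.percent_variance).to_csv(
        out / "pheno_pca.csv", float_format=io.FLOAT_FMT)
    pre = phenotype.precluster(pca.scores, k=config.k_preliminary,
                               seed=seeds["precluster"])
    clusters = phenotype.hier_cluster(pre, n_main=config.n_main_clusters)
    cluster_df = clusters.subcluster.to_frame().join(clusters.main_cluster)
    cluster_df.to_csv(out / "clusters.csv")
    phenotype.cluster_means(blues, clusters).to_csv(
        out / "cluster_means.csv", index=False, float_format=io.FLOAT_FMT)
    io.write_newick(clusters.tree, out / "pheno_dendrogram.nwk")
    if len(checks):
        check_means = checks.groupby("landrace")[
            ["DT", "DS", "PH", "EH"]].mean()
        check_means["ASI"] = check_means["DS"] - check_means["DT"]
        check_means["EPHR"] = check_means["EH"] / check_means["PH"] * 100.0
        summary = phenotype.summarize_collection(
            blues, check_means[list(phenotype.TRAITS_ALL)])
    else:
        summary = phenotype.summarize_collection(blues)
    summary.to_csv(out / "collection_summary.csv", float_format=io.FLOAT_FMT)
    outputs |= {"trials": out / "trials.csv", "blues": out / "blues.csv",
                "pheno_pca": out / "pheno_pca.csv",
                "clusters": out / "clusters.csv",
                "cluster_means": out / "cluster_means.csv",
                "pheno_dendrogram": out / "pheno_dendrogram.nwk",
                "collection_summary": out / "collection_summary.csv"}

    manifest = {
        "config": dataclasses.asdict(config),
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                    for name, p in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
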