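# poolstruct

Genotypic and phenotypic diversity analysis for crop landrace collections
genotyped as DNA pools.

Landraces — locally adapted, genetically heterogeneous traditional crop
populations — are often genotyped economically by pooling DNA from a sample
of plants (here 15 plants, i.e. 30 gametes, per accession) and hybridizing
the pool to a SNP array. Each SNP then yields a *population allele
frequency* rather than an individual genotype, and the whole downstream
analysis has to work on frequencies. `poolstruct` implements that analysis
end to end:

**Genotype pipeline**

1. **Frequency calling** — from the two allele channels' fluorescence the
   intensity ratio FIR = I_B / (I_A + I_B) is computed per landrace × SNP.
   A one-sided z-test against the homozygous clusters of controlled
   (known-frequency) calibration pools decides monomorphic vs polymorphic
   at test size α (default 5%); polymorphic entries are predicted with a
   binomial GLM, logit(f) = a + b·logit(FIR), calibrated on the controlled
   pools (series 1 trains, series 2 validates). Monomorphic entries are set
   to exactly 0 or 1, making the caller conservative near fixation.
2. **Diversity statistics** — per landrace the allele number A, minor
   allele frequency MAF and expected heterozygosity H_s = 2p(1−p) averaged
   over loci; per group/panel H_t from locus mean frequencies, Nei's
   G_st = (H_t − H̄_s)/H_t, the number of monomorphic SNPs, and group
   summary tables restricted to landraces with membership > 0.6.
3. **Distances and structure** — modified Roger's distance
   MRD(i,j) = sqrt(Σ_l (p_il − p_jl)² / L), pairwise Nei-style F_ST,
   principal coordinate analysis, Ward (D2) and neighbor-joining trees,
   plus the plumbing for external model-based ancestry software:
   Hardy–Weinberg genotype simulation (5 individuals × 2500 SNPs per
   landrace), PED/MAP export and Q-matrix import.
4. **Ancestry regression** — each landrace's frequency vector is regressed
   on K reference group frequency vectors under the constraints β ≥ 0,
   Σβ = 1 (an exact active-set quadratic program); the coefficients are the
   admixture proportions, and a landrace with no membership above 0.6 is
   labelled *admixed*.

**Phenotype pipeline**

5. **BLUEs** — multi-environment trial records (days to tasseling DT,
   days to silking DS, plant height PH, ear height EH; derived
   ASI = DS − DT and EPHR = (EH/PH)×100) are analysed per trait with a
   REML linear mixed model, varieties fixed and trials random, valid for
   unbalanced designs (each accession grown in 2–9 locations).
6. **PCA and two-stage clustering** — correlation-matrix PCA of the
   standardized BLUEs (components with eigenvalue > 1 retained, minimum
   two), then k-means into 15 preliminary clusters and size-weighted
   average-linkage agglomeration cut into 5 main clusters A–E.

Because pooled-genotyping studies of genebank material are frequently
under data embargo, the package ships a first-class synthetic generator
(`poolstruct.simulate`) that reproduces the statistical structure of such a
study — Balding–Nichols group differentiation, admixed landraces, binomial
pool sampling, logit-linked fluorescence noise, and unbalanced
multi-location trials — so every stage is testable without any download.

## Worked example

```python
from poolstruct import simulate, genotyping, diversity, structure, ancestry

gm = simulate.generate_group_frequencies(L=2000, K=4, fst=0.2, seed=1)
truth = simulate.generate_landraces(gm, n_landraces=40, frac_admixed=0.3,
                                    drift=0.01, n_plants=15, seed=2)
fluo, cal = simulate.generate_fluorescence(truth, seed=3)

panel = genotyping.call_frequencies(fluo, cal, alpha=0.05)
mae = (panel.freq - truth.true_pool_freqs.freq).abs().mean().mean()
print(f"frequency-call MAE vs truth: {mae:.4f}")

summary = diversity.landrace_summary(panel)
print(f"mean within-landrace Hs: {summary['Hs_mean'].mean():.3f}")
print(f"Gst across the panel:    {diversity.gst(panel):.3f}")

assignment = structure.assign_groups(truth.true_admixture, threshold=0.6)
groups = structure.estimate_group_frequencies(panel, assignment)
admix = ancestry.fit_panel(panel, groups)
err = (admix.coef - truth.true_admixture.coef).abs().mean().mean()
print(f"ancestry-regression MAE: {err:.4f}")
```

prints

```
frequency-call MAE vs truth: 0.0169
mean within-landrace Hs: 0.303
Gst across the panel:    0.124
ancestry-regression MAE: 0.0387
```

i.e. the called allele frequencies sit within ~1.7% of the true pool
frequencies, the panel shows the expected within-pool diversity and
between-landrace differentiation for four groups at this drift level, and
the constrained regression recovers the true admixture proportions to
within ~4 percentage points per coefficient.

The same stages are available from the shell:

```bash
poolstruct run --seed 1 --out-dir out/          # full synthetic pipeline
poolstruct call-frequencies --fluo fluo.csv --calibration cal.csv \
    --alpha 0.05 --out freq.csv
poolstruct distance --panel freq.csv --metric mrd --out mrd.csv
poolstruct tree --distances mrd.csv --method nj --out tree.nwk
poolstruct ancestry --panel freq.csv --groups groups.csv --out admix.csv
poolstruct blue --trials trials.csv --out blues.csv
```

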