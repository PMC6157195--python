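# methgene

Gene-based association tests for methylation-moderated SNP effects on a
quantitative trait, with a permutation significance engine and a synthetic
family-cohort generator for power and type-I-error studies.

## The problem

In cohorts with both genotype and DNA-methylation data, a SNP's effect on a
trait can be moderated by the methylation level of a nearby CpG site.
Testing every SNP–CpG pair individually carries a heavy multiple-testing
burden and ignores gene structure.  `methgene` implements a two-stage,
gene-based alternative for family samples:

1. **Stage 1** — the trait (change in log triglycerides,
   *y* = ln TG<sub>follow-up</sub> − ln TG<sub>baseline</sub>, with duplicate
   visit measurements ln-transformed before averaging) is fitted by REML as

   *y* = *Xβ* + *g* + *e*,  cov(*g*) = 2Φσ²<sub>g</sub>,  cov(*e*) = σ²<sub>e</sub>*I*,

   where Φ is the pedigree kinship matrix.  The per-individual residuals
   *r<sub>i</sub>* = *ŷ<sub>i</sub>* − *y<sub>i</sub>* carry forward.

2. **Stage 2** — for each SNP–CpG pair *j* (each QC-passing SNP paired to
   its nearest, or a designated, CpG site) the residuals are regressed on

   *r* = β<sub>S</sub> SNP<sub>j</sub> + β<sub>C</sub> CPG<sub>j</sub> + β<sub>SC</sub> SNP<sub>j</sub>·CPG<sub>j</sub>,

   and the overall-model F test yields a p-value *p<sub>j</sub>*.

The *m* p-values of a gene are combined into a single statistic *G* by six
methods: Σ ln *p* (Fisher/burden style), Σ −(ln *p*)² (variance-components
style), min *p*, and three **threshold statistics** *p*T(*T*) =
Σ<sub>p<sub>j</sub>≤T</sub> −(ln(*p<sub>j</sub>*/*T*))² for
*T* ∈ {0.01, 0.05, 0.10}, which zero out every pair that is not
individually significant at *T*.  Significance is assessed by permuting the
stage-1 residuals (B = 1000 by default) with the **same shuffles reused for
every pair**, preserving the correlation structure across SNPs and CpGs
within a gene; empirical p-values use the add-one estimator
(1 + #{*G*<sub>perm</sub> ≤ *G*<sub>obs</sub>})/(B + 1).  A Bonferroni
single-marker rule (min *p* < 0.05/*m*) is the comparator.

Because the original family cohort is access-restricted, the
`synthetic` module generates structurally matched cohorts — nuclear-family
pedigrees (~670 individuals), gene-dropped genotypes, beta-distributed
methylation, seven covariates, and a change-score phenotype whose causal
terms β·SNP·(1 − CPG) are calibrated analytically to target per-SNP
heritabilities (0.125 … 0.001).

## Worked example

```python
from methgene.harness import ExperimentConfig, build_set_catalogue, run_experiment

catalogue = build_set_catalogue(seed=0)   # 5 major genes + CAUSAL5/UNION/NOISE sets
config = ExperimentConfig(
    catalogue=catalogue,
    n_replicates=20,
    b_permutations=500,
    master_seed=1,
)
table = run_experiment(config)
sets = table[table.category == "synthetic_set"]
print(
    sets.pivot_table(index="gene_id", columns="method",
                     values="rejection_proportion")
    [["sum_ln_p", "sum_neg_sq_ln_p", "min_p", "pt_0.01", "single_marker"]]
    .round(2)
    .to_string()
)
```

prints

```
method   sum_ln_p  sum_neg_sq_ln_p  min_p  pt_0.01  single_marker
gene_id
CAUSAL5       1.0             1.00    1.0      1.0            1.0
NOISE2        0.4             0.95    1.0      1.0            1.0
NOISE5        0.9             1.00    1.0      1.0            1.0
UNION2        0.5             1.00    1.0      1.0            1.0
UNION5        0.9             1.00    1.0      1.0            1.0
```

Each entry is the fraction of 20 replicate cohorts in which the named
variant set was declared significant at α = 0.05.  The all-causal positive
control (CAUSAL5: five pairs with heritabilities 0.125–0.025) is detected by
every method.  Once a set is dominated by noncausal pairs (NOISE5: 288
pairs, 5 causal; NOISE2: 92 pairs, 2 causal), the averaging combiner
Σ ln *p* loses power while min *p* and the threshold statistics — designed
to suppress noise pairs — keep it.

A command-line interface mirrors the pipeline stages
(`methgene simulate | qc | pair | stage1 | experiment | report`); run
`methgene --help` for options.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its deliberate simplifications, and the numerical choices in
detail.
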