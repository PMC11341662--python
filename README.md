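# hybridgs

Genomic prediction and trial analysis for **factorial hybrid breeding
programmes** with two heterotic parent groups (e.g. flint × dent maize).
The package covers the full loop of a reciprocal hybrid-selection cycle:

1. **Simulate** a two-cycle doubled-haploid (DH) breeding scheme with a known
   genetic ground truth (QTL effects, general and specific combining
   abilities, multi-trial phenotypes with partial replication and repeated
   controls).
2. **Analyse** the field trials: quality control of marker data, hybrid
   least-squares means across trials, and REML decomposition of the hybrid
   genetic variance into general combining ability of each parent group
   (GCAf, GCAd), specific combining ability (SCA), their trial interactions,
   and per-trial residuals.
3. **Predict** untested hybrids with a family of mixed models — pedigree
   BLUP, GCA/SCA genomic BLUP with VanRaden and gamete-origin kernels, and
   genotypic models with additive, dominance and additive×additive kernels —
   and compare them by cross-validation scenarios that mirror how a breeder
   would actually use them (within a factorial, across overlapping
   factorials, and into the next cycle).
4. **Optimise** the training set for a fixed phenotyping budget by
   maximising the expected reliability (CDmean) of hybrid contrasts.

## Why SCA matters

In a hybrid programme, the value of a cross `flint_i × dent_j` splits into
what each parent contributes on average (GCA) and what is specific to the
pair (SCA). If SCA is a small share of the hybrid variance, cheap models
that only learn parental GCAs — or even topcross testers — predict new
hybrids well, and the factorial can be sparse. The package's
`decompose_variance` and `percent_sca` quantify that share from routine
multi-trial data, and the simulator lets you verify the whole estimation
chain against a known truth.

## Worked example

Simulate a small two-cycle scheme, decompose the cycle-0 factorial, and
cross-validate two prediction models on the hybrid ls-means:

```python
from hybridgs import simcross as sc, mm, evalx

# 1. simulate a small two-cycle breeding scheme with known ground truth
scheme = sc.simulate_two_cycle_scheme(
    genome=sc.GenomeSpec.uniform(5, 1.0, 40),
    lines_per_group_g0=60, hybrids_per_line_g0=1.5,
    n_trials_g0=4, n_trials_g1=4, n_qtl=40,
    n_selected=12, n_intragroup_crosses=10,
    lines_per_group_g1=40, hybrids_per_line_g1=1.5, n_g0s_hybrids=12,
    seed=7,
)

# 2. decompose the cycle-0 factorial into GCA/SCA variance components
table, summary = mm.decompose_variance(scheme.g0_plots, scheme.g0_design)
print(table.round(3).to_string(index=False))
g = summary["G0R"]
print(f"%SCA = {g['pct_sca']:.1f}   H2 = {g['H2']:.2f}")

# 3. cross-validate a GCA prediction model on the hybrid ls-means
mids = scheme.genome.marker_ids
lsm = mm.ls_means(scheme.g0_plots)["ls_mean"]
cv = evalx.run_scenario1(
    lsm, scheme.g0_design, ["GCA", "GCA_SCA"], reps=10, seed=1,
    flint_geno=scheme.flint_g0.to_genotype_matrix(mids),
    dent_geno=scheme.dent_g0.to_genotype_matrix(mids),
)
print(cv.groupby("model")["ability"].mean().round(3).to_string())
```

Output:

```text
generation       component  estimate
       G0R            GCAf     0.407
       G0R            GCAd     0.171
       G0R             SCA     0.409
       G0R          GCAfxE     0.229
       G0R          GCAdxE     0.100
       G0R           SCAxE     0.000
           residual:trial0     0.272
           residual:trial1     0.801
           residual:trial2     0.452
           residual:trial3     0.478
%SCA = 41.4   H2 = 0.84
model
GCA        0.602
GCA_SCA    0.602
```

(At this deliberately small scale the SCA share is large and noisy; adding
the SCA kernel does not change predictive ability because SCA is poorly
estimable from 90 hybrids.)

## Command line

Every analysis step is also a `hybridgs` subcommand operating on
tab-separated files, so a whole study is reproducible from a shell script:

```bash
hybridgs simulate --lines-per-group 24 --markers-per-chrom 10 \
    --n-chromosomes 2 --n-qtl 10 --seed 5 --out sim/
hybridgs qc       --flint sim/flint_geno.tsv --dent sim/dent_geno.tsv --out qc/
hybridgs lsmeans  --plots sim/g0_plots.tsv --out lsmeans.tsv
hybridgs decompose --plots sim/g0_plots.tsv --design sim/g0_design.tsv --out dec/
hybridgs predict  --model GCA --lsmeans lsmeans.tsv --design sim/g0_design.tsv \
    --flint sim/flint_geno.tsv --dent sim/dent_geno.tsv \
    --trs trs.txt --ps ps.txt --out pred.tsv
hybridgs kinship  --kind gmodel --flint sim/flint_geno.tsv \
    --dent sim/dent_geno.tsv --design sim/g0_design.tsv --out kin/
hybridgs optimize --strategy cdmean1 --kinship kin/K_G_A.tsv \
    --pool pool.txt --size 5 --seed 3 --out trs.tsv
hybridgs pipeline --config config.yaml --out run/   # end-to-end, manifest.json
```

`hybridgs pipeline` writes a `manifest.json` with the seed, the resolved
configuration and a SHA-256 of every output file; re-running the same
configuration reproduces every file bit-for-bit.

## Model codes

`PBLUP`, `GCA`, `GCA_SCA`, `GCA:A`, `GCA:AD`, `GCA:A(AAdf)`, `GCA:AD(AAdf)`,
`GCA:AD(AAf)(AAd)(AAdf)`, `G:A`, `G:AD`, `G:A(AA)`, `G:AD(AA)` — see
[docs/methods.md](docs/methods.md) for the kernels behind each code and the
structural identities among them (e.g. `GCA` and `GCA:A` are the same model).

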