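# voxgene

From risk-gene SNPs through grey-matter "hot clusters" to patient
subtypes: a tested, reusable multi-scale imaging-genetics pipeline.

Psychiatric disorders such as schizophrenia link genetic variation to
brain structure and, through it, to clinical symptoms.  `voxgene`
implements one complete analytical chain for a case–control structural
MRI study:

1. **Association screen** — for every SNP *s* and grey-matter-volume
   (GMV) voxel *v*, fit
   `GMV_v = β₀ + β₁·g_s + β₂·age + β₃·sex + β₄·edu + ε`
   by OLS and select candidate genes whose minimum SNP × voxel p falls
   below 1 × 10⁻⁶ (after standard genotype QC: subject call rate ≥ 97%,
   marker missingness ≤ 5%, MAF > 0.05, Hardy–Weinberg exact P > 10⁻⁶).
2. **Co-expression validation** — in brain developmental expression
   stratified into 4 regions × 3 stages, build |Pearson r| > 0.8
   networks and test the candidates' *interconnectedness* (the sum of
   edge weights among them) against 10 000 random same-size gene sets.
3. **Hot clusters (HCs)** — weight each voxel by its number of
   significantly associated SNPs, correct the counts for linkage
   disequilibrium (Li–Ji effective number of tests per chromosome),
   smooth with an isotropic Gaussian kernel (FWHM 8 mm), threshold, and
   extract connected components ranked by peak weight, annotated with
   genes and atlas regions.
4. **Subtyping** — cluster patients on their mean HC GMV profiles with
   K-means under the correlation distance d = 1 − r, choose the number
   of groups K ∈ 2..10 by maximizing the mean in-group proportion (IGP),
   and characterize groups on the PANSS subscales (P, N, G, TT,
   PN = P − N) with label-permutation tests plus per-HC Wilcoxon
   rank-sum tests (Bonferroni over the HC family).

Because cohort data of this kind is rarely shareable, the package ships
a synthetic-study generator (`voxgene.simulate`) that plants recoverable
ground truth — LD-blocked genotypes, voxel-sphere SNP effects, stratum-
specific co-expression modules, patient subgroups with GMV and symptom
shifts — so the entire pipeline is testable end to end.  See
`docs/methods.md` for the model details and design choices.

## Worked example

Run the default synthetic study (145 subjects, 200 genes × 5 SNPs,
24³ voxel grid at 1.5 mm, four planted causal genes at β = 1 per allele)
end to end:

```python
from voxgene.pipeline import PipelineConfig, PipelineRun

run = PipelineRun(PipelineConfig(out_dir="demo_run", seed=1))
run.run()

truth = run.state["truth"]
print("planted genes:", sorted(truth.causal_gene_ids))
print("candidates:   ", sorted(run.state["candidate_genes"]))
print("hot clusters: ", [(c.name, c.size, sorted(c.associated_genes))
                         for c in run.state["clusters"]])
```

which prints

```
planted genes: ['G0010', 'G0050', 'G0120', 'G0180']
candidates:    ['G0010', 'G0019', 'G0022', 'G0050', 'G0051', 'G0061',
                'G0079', 'G0081', 'G0110', 'G0117', 'G0120', 'G0145',
                'G0159', 'G0180', 'G0199']
hot clusters:  [('HC1', 203, ['G0180']), ('HC2', 203, ['G0010']),
                ('HC3', 203, ['G0120']), ('HC4', 203, ['G0050'])]
```

All four planted genes are recovered (the extra candidates are the
expected chance exceedances of a fixed 10⁻⁶ screen over ~1.4 × 10⁷
tests; their isolated voxels do not survive smoothing, so exactly four
hot clusters emerge, each annotated with its planted gene and matching
its truth sphere with Dice ≈ 0.94).  The co-expression stage finds the
candidate set significantly interconnected in the stratum carrying the
planted module (p ≈ 0.003) and not in the merged network (p = 1.0).

The same stages are available from the shell:

```bash
voxgene simulate --out study/ --seed 1
voxgene associate --genotypes study/genotypes.raw.tsv \
    --gmv-manifest study/gmv/gmv_manifest.tsv \
    --covariates study/covariates.tsv --out assoc/
voxgene run --out full_run/ --seed 1      # whole pipeline
```

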