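# famvar

Family-based rare-variant prioritization for multiplex disease cohorts.

`famvar` implements, as a tested and reusable pipeline, the analysis chain
used to prioritize rare damaging coding variants in families with a complex
disease:

- **QC** — per-genotype quality filters (GQ, allele balance, alt depth),
  per-variant filters (call rate, Hardy–Weinberg, VQSR tranche bounds), sex
  verification from X homozygosity, kinship-coefficient relationship
  classification with an expected-kinship pedigree oracle, and a PCA
  ancestry ellipsoid with Mahalanobis proximal-control ranking.
- **Annotation filters** — damaging-variant classification (high-impact
  consequences, or missense with a damaging CAROL call and CADD ≥ 20),
  minor-allele orientation, control-AF resolution over reference panels,
  and AF tiering (very rare < 0.005 / rare < 0.05 / common > 0.05).
- **Linkage support** — genetic-map interpolation, LD pruning, 0.3 cM
  linkage-map SNP selection by heterozygosity, pedigree trimming, LOD ≥ 1.5
  locus selection, and the contributing-family shared-variant filter
  (multipoint linkage statistics themselves are consumed as input).
- **Family prioritization** — large-family (≥ 4 sequenced affecteds)
  selection, the ≥ 75 % affected-carrier sharing rule, the ≤ 1/3
  unaffected-carrier segregation rule, and exact conditional transmission
  probabilities under a single-heterozygous-carrier-founder model.
- **Gene dropping** — vectorized Mendelian forward simulation over the
  whole cohort producing null AF distributions, empirical
  `(k+1)/(n+1)` enrichment p-values, and a normal-approximation power
  calculation.
- **Replication statistics** — two-sided Fisher allele tests,
  simulation-based power and the smallest odds ratio achieving target
  power, Spearman-correlation-informed effective dataset counting with a
  Bonferroni threshold, the CMC gene-burden test (two AF bins, logistic
  LLR with PC covariates), and rank-sum AF comparisons.
- **Synthetic data** — a seeded generator for complete study corpora
  (pedigrees, VCF with quality fields, annotation tables, toy LOD tables,
  replication counts, and a truth file), so every stage runs end-to-end
  with no external data.

## CLI

```sh
# generate a synthetic corpus with planted signals
famvar simulate --out corpus/ --seed 7

# run the full analysis (both strategies, gene dropping, correction)
famvar run-all --indir corpus/ --outdir run/ --seed 7 --sims 100000

# single stages compose through TSV files
famvar qc --indir corpus/ --out qc.tsv
famvar famprior --indir corpus/ --out famprior.tsv --scope IBD
famvar genedrop --indir corpus/ --variant 5_71000000_C_T \
    --exclude-family F1 --sims 100000 --seed 7
famvar correct --n-linkage 11 --n-rare 413   # -> alpha = 3.97e-05
```

`run-all` writes per-stage TSV reports plus `funnel.json` with the
per-stage variant counts and the derived significance threshold.

## Layout

- `src/famvar/model.py`, `io.py` — domain types and file formats
  (extended PED, VCF v4.2 via cyvcf2, TSV tables)
- `src/famvar/qc.py`, `annotate.py`, `linkage.py`, `familyprior.py`,
  `genedrop.py`, `replication.py` — analysis stages
- `src/famvar/simulate.py`, `presets.py` — synthetic corpora
- `src/famvar/pipeline.py`, `cli.py` — orchestration and the `famvar` CLI
- `tests/` — unit, property and acceptance suites
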