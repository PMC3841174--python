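# coosig

Cell-of-origin expression signature toolkit for ovarian carcinoma
transcriptomics. The pipeline derives a fallopian-tube-vs-ovary (FNE vs
OCE) differential-expression signature from a paired two-patient
cell-line design, scores tumor expression profiles with ±1 gene weights,
stratifies tumors into FT-like and OV-like subgroups with a two-component
Gaussian mixture, and tests the stratification against clinical covariates
and survival, with a permuted-signature null control.

## Components

| Module | Purpose |
| --- | --- |
| `coosig.simulate` | Synthetic paired cell-line designs and tumor cohorts with the statistical structure the analysis assumes (scaled-inverse-chi-square gene variances, intra-patient correlation, mixture-separated scores, class-linked covariates and exponential survival) |
| `coosig.io` | TSV and GEO Series Matrix readers/writers, clinical tables with configurable ordinal encodings |
| `coosig.normalize` | Generalized-log (glog) variance-stabilizing normalization with per-array affine calibration; quantile normalization |
| `coosig.diffexp` | Consensus intra-patient correlation, per-gene GLS paired contrasts, empirical-Bayes moderated t (d0/s0² by digamma/trigamma moment matching), Benjamini–Hochberg FDR |
| `coosig.signature` | Top-k-per-direction signature selection with gene-symbol uniqueness, ±1-weighted scoring, random signatures |
| `coosig.mixture` | Two-component 1-D Gaussian mixture by EM with seeded restarts; shared/separate variance selected by BIC |
| `coosig.clinstats` | Tie-corrected Mann–Whitney (no continuity correction), Fisher's exact (2×2 exact, 2×K enumeration/Monte-Carlo), proportional-odds ordinal association, Welch t, log-rank, Cox PH (Efron ties), Kaplan–Meier export, permuted-signature null |
| `coosig.pipeline` / `coosig.cli` | Flat key=value configured end-to-end runs with deterministic outputs and a run log |

## CLI

Each stage is a verb; `all` runs the configured pipeline end to end:

```bash
coosig simulate --kind cell-lines --seed 1 --outdir data/
coosig diffexp data/cell_matrix.tsv --design data/cell_design.tsv \
    --annotation data/annotation.tsv --out de.tsv
coosig signature de.tsv --k-per-direction 5 --out sig.tsv
coosig simulate --kind cohort --seed 2 --signature-path sig.tsv --outdir cohort/
coosig score cohort/tumor_matrix.tsv --signature sig.tsv --out scores.tsv
coosig classify scores.tsv --out classes.tsv
coosig associate classes.tsv --clinical cohort/clinical.tsv --out assoc.tsv
coosig survival classes.tsv --clinical cohort/clinical.tsv --out km.tsv
coosig permute cohort/tumor_matrix.tsv --clinical cohort/clinical.tsv \
    --annotation cohort/annotation.tsv --n-permutations 1000 --out null.tsv
```

End-to-end from a config file:

```bash
printf 'k_per_direction=5\nseed=1\n' > run.cfg
coosig all --config run.cfg --outdir results/run1
```

All outputs are TSV plus a `run_log.txt` capturing the version, config
hash, and every tunable; identical config + seed gives byte-identical
outputs.

## Notes

- Scoring requires normalized (log-scale) input; signature probesets
  missing from a platform are dropped from the sum and reported
  (`n_used`, dropped ids), never imputed.
- The consensus correlation is a trimmed mean of atanh per-gene
  within-block correlations, clamped to (−0.99, 0.99).
- Mixture labels use the posterior ≥ 0.5 rule; the FT-like component is
  the one with the larger mean.
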