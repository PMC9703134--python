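# methdrift

Passage-associated DNA-methylation drift analysis for organoid culture
cohorts.

Patient-derived intestinal organoids are kept in culture for months and
repeatedly dissociated and reseeded ("passaged").  Methylation arrays show
that while most CpGs stay put, a minority drift with culture duration —
and that drift can confound any study that compares organoid lines
profiled at different passages.  `methdrift` is for epigenomics analysts
who have a beta-value matrix (CpGs × samples, β ∈ [0, 1]) and a sample
sheet with passage numbers, and who want to quantify and localise that
drift.

## The model

For each CpG *j* with beta values *β<sub>ij</sub>* over samples *i* at
passages *p<sub>i</sub>*:

- **Trend** — OLS fit *β<sub>ij</sub> = α<sub>j</sub> + b<sub>j</sub>
  p<sub>i</sub> + ε<sub>ij</sub>* (optionally with fixed-effect donor
  covariates); two-sided t-test on *b<sub>j</sub>*.
- **Spread** — Breusch–Pagan test on the residuals: regress
  *ε̂<sub>ij</sub>²* on *p<sub>i</sub>*, refer *LM = n·R²* to χ²(1).
- **Effect size** — Δβ<sub>j</sub> = mean β over high-passage samples
  (5–16) minus mean β over low-passage samples (1–4).

After Benjamini–Hochberg adjustment across all tested CpGs, each CpG gets
non-exclusive flags:

| class | rule |
|---|---|
| hypomethylated | directional q < 0.05 and Δβ < −0.15 |
| hypermethylated | directional q < 0.05 and Δβ > +0.15 |
| heteroskedastic | Breusch–Pagan q < 0.05 |

Drift classes are then tested for genomic-feature enrichment by resampling:
observed feature counts vs 1000 random same-size probe lists drawn from a
*feasibility-corrected* background (a CpG with baseline β < 0.15 can never
lose 0.15, so it is excluded from the background for the loss direction;
symmetrically for gains), with fold change, SE across samplings, and
plus-one empirical p-values.  The same resampling scheme drives the
colon-cancer DMR concordance table and the replication-origin distance
permutation test.

A synthetic-cohort generator (bimodal baselines, donor random effects,
gut-segment effects, and the three planted drift archetypes) makes the
whole pipeline runnable and testable without any array download.

## Worked example

```python
import methdrift as md

cfg = md.SimulationConfig(n_cpgs=5000, n_samples=80, n_donors=46, seed=0)
beta, sheet, truth = md.generate_cohort(cfg)
res = md.PassageDriftModel(beta, sheet).fit()
print(res.summary())
```

```
Passage drift classification
============================================
CpGs tested:              5000
Samples:                  80
Low/high passage groups:  (1, 4) / (5, 16)
alpha (BH-FDR):           0.05
|delta-beta| threshold:   0.15 (group)
Donor covariate:          False
--------------------------------------------
hypo:           109  ( 2.18%)
hyper:           39  ( 0.78%)
hetero:         307  ( 6.14%)
stable:        4595  (91.90%)
```

The generator planted 2.2% hypo-, 0.8% hypermethylated and 5.2%
heteroskedastic CpGs; the fit recovers 2.18%, 0.78% and 6.14%.  Scoring
against the ground truth (`res.score_against(truth)`) gives sensitivities
of 0.99 / 0.98 / 0.96 per class with zero false directional calls.  The
`hetero` excess over the planted fraction is real signal: a directional
CpG whose trajectory flattens near the beta bounds is also genuinely
heteroskedastic, and flags are non-exclusive.

The same analysis end to end, from a shell:

```sh
methdrift run-all -c config.yaml --seed 0 -o out/
```

writes the beta matrix, classification table, PCA scree/associations,
regulatory and cDMR enrichment tables, origin-distance tests, and
`report.json` under `out/`.

## Layout

- `methdrift.simulate` — synthetic cohorts and genomic tracks with ground truth
- `methdrift.io` — TSV/BED readers and writers, `IntervalTrack`
- `methdrift.qc` — probe filtering rules, beta↔M-value transforms
- `methdrift.decomposition` — PCA and PC–covariate association
- `methdrift.drift` — `PassageDriftModel` / `PassageDriftResults`, BH-FDR,
  Breusch–Pagan, cross-cohort concordance
- `methdrift.enrichment` — resampling enrichment, feasibility backgrounds,
  cDMR concordance, origin-distance tests, CpG→gene assignment
- `methdrift.pipeline` / `methdrift.cli` — config-driven orchestration

See `docs/methods.md` for the statistical details and design choices.
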