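# Methods

## Scope and data model

`methdrift` analyses passage-associated drift of DNA methylation in
long-term organoid cultures profiled on methylation arrays.  Its input is
a beta-value matrix (CpGs × samples, β = methylated / (methylated +
unmethylated) signal, in [0, 1]), a sample sheet (donor, passage, gut
segment, age, sex, cohort), a probe annotation (coordinates and QC flags)
and BED interval tracks.  Everything upstream of the beta matrix — IDAT
parsing, normalization, batch correction — is out of scope; users bring a
preprocessed matrix, or use the synthetic generator.

All genomic coordinates are 0-based half-open (BED convention); probe
positions are single-base points.  A probe at an interval's start
coordinate is inside it; at the end coordinate it is not.

## Probe filtering

Probes are removed if they sit on a sex chromosome, assay a polymorphic
CpG, can cross-hybridize, or (when a detection-p matrix is supplied) fail
detection (p > 0.05) in more than 1% of samples.  The retained set is the
complement of the union of rules and is therefore order-independent; the
per-rule counts in the report attribute each removed probe to the first
rule it triggers, in the order listed above.  The "more than 1%" reading
is the default because the inclusive alternative removes probes failing in
exactly 1% of samples, which is the more aggressive and less common
convention; a flag (`strict_fraction=False`) switches to ≥.

## Per-CpG drift statistics

For each CpG, ordinary least squares of β on passage (passage treated as
continuous), optionally with fixed-effect donor indicator covariates.
Betas are modelled on the β scale, not M-values, so the slope and Δβ share
units (fraction per passage / fraction).  The passage coefficient's
two-sided t-test gives the directional p-value.

Heteroskedasticity is tested with the studentized Breusch–Pagan statistic:
squared residuals from the mean model are regressed on passage alone (even
when donors are in the mean model), and LM = n·R² of that auxiliary fit is
referred to χ² with 1 degree of freedom.  The studentized form is robust
to non-normal residuals; on bounded beta-scale data it is mildly
conservative at n = 40 (empirical size ≈ 0.042 on logit-normal nulls,
≈ 0.050 on Gaussian nulls at the same size — both measured by the test
suite and acceptance script).

Δβ is the high-passage-group mean minus the low-passage-group mean
(defaults: passages 1–4 vs 5–16).  This group-contrast definition is the
default because it is assumption-free; `delta_beta_mode="model"` instead
uses slope × observed passage span, which is larger for the same planted
effect because the group means average over the interior of the trajectory.

Degenerate CpGs (constant β) are assigned slope 0 and p = 1 rather than
NA, keeping the BH-FDR universe fixed at all tested CpGs.  CpGs with
missing betas are refit on their complete samples; CpGs with fewer than 3
complete samples or fewer than 2 distinct passages get NA statistics,
which propagate through BH as NA q-values.

Classification at α = 0.05 (BH-FDR) and |Δβ| > 0.15: hypo (loss), hyper
(gain), heteroskedastic.  Flags are non-exclusive — a CpG can carry a
trend and growing spread simultaneously, and class counts are per test —
with a primary display label by precedence directional > heteroskedastic >
stable.

## Variance decomposition

PCA treats samples as observations and CpGs as variables, with CpG-wise
mean-centering and no scaling, computed by SVD on β values.  Variance
fractions come from the full decomposition (they sum to 1); the sign of
each component is fixed by orienting its loading vector so the
largest-magnitude element is positive.  Components are associated with
covariates by Spearman correlation (continuous; average ranks on ties) or
one-way ANOVA (categorical); single-level covariates are reported NA, and
missing covariate values are dropped pairwise.

## Resampling enrichment

Enrichment of a target CpG set in a feature is measured against the
array's own probe distribution: `n_samplings` (default 1000) lists of size
|target| are drawn uniformly without replacement from a background
universe; per feature the observed count is compared with the sampled
counts.  Fold change is observed / sampled mean; its SE is the SD across
samplings of observed/sampled-count (zero sampled counts yield NA unless a
+0.5 continuity option is enabled); empirical p-values use the plus-one
correction (1 + #extreme) / (1 + n), so they are never zero and enrichment
and depletion p's overlap by at least 1/(n+1).  BH adjustment runs across
features within a result.

For directional classes the background is feasibility-corrected: with
threshold t, baseline β < t is excluded for the loss direction and
1 − β < t for the gain direction, because such probes cannot reach the
threshold and would dilute the null.  The exclusion predicate is written
exactly as the definition (achievable change ≥ t) so boundary baselines
are retained.  "Baseline" is the mean β over the cohort's lowest-passage
sample(s), which generalizes a passage-1 reference to cohorts that start
later.  The heteroskedastic class keeps the full tested universe — no Δβ
constraint applies to it.

The colon-cancer DMR concordance runs this enrichment for each drift class
against each cDMR direction label and flags the same-direction cells
(loss-with-loss, gain-with-gain).  The replication-origin analysis assigns
each probe its minimum absolute distance to any origin-peak boundary
(interior probes measure to the nearest edge by default; a `zero_inside`
flag sets them to 0) and compares the target's mean distance with means of
random same-size draws, reporting both one-sided plus-one p-values.  Ties
between sampled and observed means count as extreme, with a 1e-9 relative
tolerance absorbing summation-order noise.

CpG→gene assignment maps each probe to the gene of the nearest transcript
(distance 0 inside; ties broken by smaller transcript start, then lexical
gene id), supporting the fraction-of-genes-with-a-drift-CpG statistic.

## Synthetic cohorts

The generator emulates an array study of organoids sampled longitudinally
over passages 1–16.  Defaults are the study conditions: 80 samples from 46
donors, planted class fractions 2.2% hypo / 0.8% hyper / 5.2%
heteroskedastic, and a full-range directional effect of 0.25 β units.

- **Baselines** come from a bimodal mixture (Beta(2,18), Beta(6,6),
  Beta(18,2) with weights 0.38/0.12/0.50), matching the bimodal array β
  distribution.  Directional CpGs are rejection-sampled into the feasible
  range (baseline ≥ effect + 0.05 for losses, ≤ 1 − effect − 0.05 for
  gains).  Heteroskedastic CpGs are drawn from 0.25–0.75: a bounded,
  trend-free fan-out is only realizable at intermediate methylation, which
  is also where variably methylated CpGs sit on real arrays.
- **Trajectories**: directional CpGs move linearly in β with passage,
  reaching the configured effect at the last passage (clipped to
  [0.02, 0.98]).  Donor random intercepts (SD 0.15), a gut-segment shift
  (±0.5 on 10% of CpGs) and residual noise (SD 0.2) are applied on the
  natural-logit scale and inverse-transformed, so all β stay in (0, 1).
  These SDs correspond to β-scale noise of roughly 0.01–0.05 depending on
  baseline, typical of arrays.
- **Heteroskedastic noise** grows linearly: SD = 0.2 + 0.10·(passage − 1)
  on the logit scale, i.e. a fan from ≈ ±0.03 to ≈ ±0.3 β units at
  mid-range baselines over 15 passages.  The spread-growth magnitude is a
  free parameter of the study design; 0.10 reproduces the wide late-passage
  fans seen at representative drift CpGs.  Because logit-normal noise is
  mean-shifting on the β scale away from 0.5, the generator solves (Newton
  on a 21-node Gauss–Hermite quadrature) for the logit location that keeps
  the β-scale expectation flat — without this, growing spread masquerades
  as a trend and corrupts the directional classes.
- **Harvest design**: donors are observed longitudinally, alternating
  between an early window (passages 1–4) and a late window (10–16), with
  passages assigned by balanced cycling through each window, as a harvest
  protocol with planned time points would.  Under this design the planted
  full-range effect of 0.25 yields a realized group-contrast Δβ of ≈ 0.175.
  Uniform passage sampling would push that to ≈ 0.13 — below the 0.15 call
  threshold — so the sampling design, not the per-CpG test, is what makes
  a 0.25 effect detectable; real cohorts that harvest across the full
  range accordingly need larger effects or model-based Δβ.
- **Tracks**: regulatory intervals (six categories) and cDMRs are laid out
  mutually non-overlapping on two synthetic chromosomes so per-category
  background fractions are exact; an enrichment plan places probes of a
  chosen class inside a category at a specified fold over background.
  Origin peaks and transcripts are placed independently.

What the generator does **not** emulate: probe-level mean–variance
coupling beyond the logit transform, spatial correlation along the genome,
array batch effects, detection failures (beyond an optional missing-value
rate), age- or sex-dependent methylation, and cell-composition shifts.
Passing tests therefore demonstrate correctness of the statistics and
recovery under idealized drift, not robustness to those real-data
artifacts.

## Numerical choices

- Residual variance below 1e-24 is treated as exactly zero (degenerate
  fits); slopes below 1e-12 in such fits report p = 1.
- BH-FDR is step-up with a stable mergesort, capped at 1, NA-propagating.
- The mass fit is one shared design matrix and a single matrix product per
  cohort; per-CpG fallbacks run only for rows with missing values and are
  exactly consistent with the vectorized path (tested).
- All randomness flows through `numpy.random.Generator`; a pipeline run
  derives per-stage generators from one master seed via `SeedSequence`,
  making full runs byte-identical for a fixed config.

## Limitations

- Donor repeated measures are handled by fixed-effect covariates, not
  mixed models; with donors confounded against passage the design is
  rejected rather than regularized.
- The Breusch–Pagan auxiliary regression uses passage only; variance
  driven by other covariates will surface as heteroskedasticity.
- Resampling enrichment treats probes as exchangeable within the
  background; it corrects for the array's feature distribution but not for
  probe-level covariates such as CpG density.
- The nearest-transcript scan is exact but quadratic per chromosome chunk;
  at array scale (~1e6 probes × ~1e3 synthetic transcripts) this is fine,
  but a genome-wide transcript set would warrant an interval-sweep
  implementation.
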