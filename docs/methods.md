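# Methods

## Scope and data model

`oabnet` analyses cohorts of OABSS questionnaires measured at five fixed
timepoints (T0, T6, T12, T18, T24 — months since treatment). A cohort
is complete-case by construction: every patient has all five
measurements. Two CSV dialects are accepted: item-level
(`T0-Q1 … T24-Q4`, with totals derived) and totals-only
(`T0-OABSS … T24-OABSS`). Totals-only input supports clustering,
embedding, trajectory-mode networks and total-score summaries, but not
item-level networks or item-level change summaries.

## Synthetic cohort generator

The generator exists because the underlying clinical data is not
public; it produces cohorts with the statistical structure the analysis
assumes, so that parameter-recovery and invariant tests are meaningful.

Per patient *i* in cluster *k*, item *c*, timepoint *t*:

    latent = baseline_means[c] + separation · cluster_offsets[k,c]
             + b_ic + trajectory_deltas[k,t,c] + eps_ict

with `b_ic ~ N(0, baseline_sd[c])` drawn once per patient and
`eps_ict ~ N(0, noise_sd[c])` independent per timepoint. Scores are
rounded half-away-from-zero and clipped to the item bounds
(Q1 0–2, Q2 0–3, Q3 0–5, Q4 0–5); `discretize=False` skips this for
distribution-level checks. All units are OABSS points.

Design notes:

* **Patient-level effect `b_ic`.** Without it, the change score
  t − baseline would carry two independent noise draws and its SD could
  not be pushed down to realistic questionnaire values (items change in
  only a few patients). It also acts as a dither: latent baselines
  spread smoothly over the integer grid, which makes rounding
  essentially unbiased in the mean.
* **Determinism.** One `numpy` Generator seeded from `config.seed`
  drives all draws in a fixed order; identical configs give
  byte-identical tables.

### `table1_calibrated` preset

Emulates the published 101-patient cohort summary (mean ± SD change
from baseline per item and follow-up). Calibration:

* `noise_sd[c]` = (mean printed change-SD for item c) / √2, so the
  *latent* change SD matches the printed dispersion. Rounding then
  inflates the observed change SD by roughly +1/12 variance per
  timepoint (most visible for the narrow-range Q1, whose observed
  change SD ≈ 0.4 vs printed 0.14); items are generated independently,
  so the observed *total* change SD (≈1.6) sits below the printed 2.03,
  which reflects positive inter-item correlation in real patients.
  Both distortions are accepted and documented rather than compensated.
* Mean changes are calibrated *exactly* through the discretisation:
  under the model, the population mean of a discretised item with
  latent mean μ and spread s is g(μ) = Σ_{j=1..hi} (1 − Φ((j−0.5−μ)/s)).
  The latent shift d for each (item, follow-up) solves
  g(baseline + d) − g(baseline) = printed mean change by bisection, so
  the generator's population mean change equals the printed value to
  numerical precision, and an n=101 draw scatters around it with
  SE ≈ SD/√101.
* Baseline levels are not published. The preset uses means
  (1.2, 2.0, 3.0, 3.0) — total ≈ 9.2, "moderate" severity, plausible
  for a treated OAB cohort of women ≥60 — and between-patient SDs
  (0.45, 0.6, 0.9, 0.8), placing the mass far enough from the score
  bounds that clipping corrections stay well under 0.1 points.
* Cluster structure does not enter the published table, so the preset
  sets `separation = 0` (labels 34/47/20 are still emitted).

### `study_sizes` preset

Emulates the reported cluster structure: 101 patients in three groups
of 34/47/20 with qualitatively distinct courses — severe-stable
(total ≈ 12 throughout), steadily improving (10 → 2), and initially
mild but worsening after T6 (3 → 2 → 6 → 9 → 12). The trajectory
means were chosen to be roughly equidistant *after per-timepoint
standardization* (the clustering default): near-equidistant centroids
are what make the SSE second difference peak at the true k, whereas a
chain-like geometry biases the elbow toward k = 2. Within-cluster
spreads (noise_sd 0.15–0.2, baseline_sd 0.2–0.25 points) keep the
planted groups separated by many within-group SDs, so elbow selection
returns k = 3 and K-means recovers memberships exactly for essentially
every seed (300/300 in the regression sweep run while fixing the
geometry). Per-cluster trajectory shapes are package choices — only
the sizes and the qualitative narrative are anchored.

## Preprocessing

Standardization z-scores each timepoint column with the population SD
(divisor n), matching the conventional scaler; it is idempotent, and a
constant column maps to zeros with a warning rather than failing, so
degenerate synthetic configurations can still flow through the
pipeline. Clustering and PCA consume standardized input by default;
`standardize=False` reproduces the raw-score variant (both appear in
practice and neither is asserted as canonical).

## Clustering

Euclidean distances; Ward linkage (SciPy) exposed as the merge tree,
with cut labels available for comparison; K-means (scikit-learn,
k-means++, `n_init=10`, default seed 42) produces the final labels.
The elbow is the interior k maximizing J(k−1) − 2J(k) + J(k+1) over a
contiguous candidate range (default 1–8); ties take the smaller k.
Labels are canonicalized by descending cluster size (ties: lowest
member index) because K-means label permutation is arbitrary and
downstream reports need stable identities; any colour/cluster-id
mapping is presentation configuration.

## Embedding

PCA via eigendecomposition of the covariance of the (centered) input;
the first two components are returned with a fixed sign convention
(largest-magnitude loading positive). Total variance across all five
components is retained for conservation checks. Rank-deficient input
yields a zero-variance second component with a warning.

## Similarity networks

`r_min` (default 0.7) is an explicit inclusion threshold: the method
needs *some* threshold to produce non-complete graphs, no canonical
value exists, and 0.7 is the conventional "strong correlation" cut.
Edges require r > r_min strictly (exact ties excluded, for
determinism). Non-positive correlations never form edges — the length
formula (1/r − 1)×1000 is undefined or negative there — and pairs
involving a constant score vector are excluded and logged.

Two correlation bases are supported because "per-timepoint graphs from
correlations across time" is ambiguous: `components_at_t` (default)
correlates the two patients' four item scores at the timepoint, giving
genuinely time-varying graphs; `trajectory_up_to_t` correlates
total-score trajectories up to t (T0 falls back to the component basis
with a warning). Pearson on 4-point integer vectors is coarse — values
cluster near ±1 — which is why edge counts, not exact r values, carry
the signal; outputs always record the mode and r_min used.

## Network metrics

Average degree centrality of cluster C counts **all** incident edges
and divides by |V|−1 (how connected C is to the whole cohort); edge
density uses only the induced subgraph (internal cohesion; 0 for
singleton clusters). The two are deliberately distinct measures and
both are reported per (cluster, timepoint). Eigenvector centrality is
computed by power iteration on A + I (shared eigenvectors with A;
avoids bipartite oscillation), tolerance 1e-10, ≤1000 iterations, on
the largest connected component with zeros elsewhere; it is exposed as
machinery but is not part of the headline trajectory.

## Change summaries

Change = score(t) − score(T0) per patient; mean with sample SD (n−1),
the convention for cohort summary tables (the generator's population-SD
calibration accounts for this). Total mean change equals the sum of
item mean changes exactly, by linearity. Severity bands are reported
as published — mild <5, moderate 6–11, severe ≥12 — which leaves a
total of exactly 5 unassigned; it is labelled "unclassified" rather
than silently binned.

## Pipeline and reproducibility

`run_pipeline` chains input → preprocess → clustering → embedding →
networks → dynamics → summary, writes all CSV/GraphML/plot artifacts
plus a JSON manifest (config echo, seed, versions, timestamps, output
list, completion flag), and wraps stage failures with the stage name.
A single root seed drives cohort generation and K-means, so repeated
runs are hash-identical on every CSV. The CLI exposes each stage as a
subcommand plus `run-all`; flags override YAML config values.

Default problem sizes (n=101 cohorts, k-range 1–8, 10 K-means restarts,
100-instance oracle sweeps with n ≤ 12, 20-seed recovery sweeps) keep a
full test-and-reproduction cycle in the tens of seconds on one CPU.

## Limitations

* The generator draws items independently within a timepoint and uses
  Gaussian noise; real OABSS items are positively correlated and
  skewed near their bounds. Passing recovery tests therefore shows the
  pipeline recovers structure *of the kind assumed*, not that the
  clinical conclusions hold for real cohorts.
* No dropout/censoring (complete-case design) and no covariates.
* The elbow rule, like all cluster-count heuristics, is only reliable
  when the planted/true structure is well separated; the second
  difference can prefer k = 2 for chain-like cluster geometries.
* Published figure layouts are presentation, not inference, and are
  not reproduced; graphs are emitted as data (GraphML/edge lists).
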