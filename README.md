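# oabnet

Dynamic network analysis of longitudinal overactive-bladder (OAB)
symptom scores.

Chronic conditions like OAB are monitored with repeated questionnaires —
here the four-item OAB symptom score (OABSS: Q1 daytime frequency 0–2,
Q2 nighttime frequency 0–3, Q3 urgency 0–5, Q4 urgency incontinence
0–5; total 0–15) collected at baseline and 6, 12, 18 and 24 months
after treatment. Average cohort statistics hide the fact that patients
respond in qualitatively different ways. `oabnet` is for
biostatisticians and clinical researchers who want to (1) stratify a
cohort into response subgroups from the score trajectories themselves
and (2) watch how the *relationships between patients* — who resembles
whom — rearrange over the follow-up period.

## Method

Given a patients × timepoints table of OABSS measurements:

1. **Trajectory clustering.** Total scores are z-scored per timepoint;
   pairwise Euclidean distances feed Ward's hierarchical clustering, and
   the cluster count k is chosen from the K-means objective
   J(k) = Σᵢ Σ_{x∈Cᵢ} ‖x − μᵢ‖² by the elbow rule, formalized as the
   interior k maximizing the discrete second difference
   J(k−1) − 2J(k) + J(k+1). K-means (k-means++, best of 10 restarts)
   produces the final labels, relabelled by descending cluster size.
2. **Embedding.** Two-component PCA of the same matrix for
   visualization, with a deterministic sign convention.
3. **Patient similarity networks.** One graph per timepoint: nodes are
   patients, and an edge joins pairs whose score vectors have Pearson
   correlation r > r_min (default 0.7), with edge length
   **(1/r − 1) × 1000** — 0 for perfectly aligned profiles, unbounded
   as r → 0⁺. Non-positive and undefined correlations never form edges.
4. **Network dynamics.** For each cluster C and timepoint t:
   average degree centrality (1/|C|) Σ_{v∈C} deg(v,t)/(|V|−1) (degrees
   count all incident edges) and edge density of the induced subgraph,
   |E(C)| / (|C|(|C|−1)/2). Adjacency/Laplacian matrices (L = D − A)
   and power-iteration eigenvector centrality (Ax = λx) are provided
   for further structural analysis.
5. **Change summaries.** Mean ± SD change from baseline per item and
   total at each follow-up (improvement is negative).

The clinical dataset behind the published analysis is not deposited, so
the package ships a synthetic cohort generator with planted response
clusters and a preset calibrated to the published change-from-baseline
table; every stage is tested against brute-force oracles and structural
invariants on top of that generator.

## Worked example

```python
from oabnet import (study_sizes_preset, generate_cohort, extract_totals,
                    standardize, fit_trajectory_clusters)

cohort = generate_cohort(study_sizes_preset(seed=42))   # 101 patients, 3 planted groups
model = fit_trajectory_clusters(standardize(extract_totals(cohort)), seed=42)
print(model.k, model.sizes.tolist())
```

```
3 [47, 34, 20]
```

The elbow picks k = 3 (the SSE curve drops 505 → 206 → 28 and then
flattens) and K-means recovers the three planted response groups
exactly; sizes are reported largest-first. Running
`python examples/04_centrality_trajectories.py` then prints, for
example, an average degree centrality falling from 0.81 at T0 to 0.09
at T24 for the steadily improving cluster — as its members' symptom
profiles diverge from the still-severe rest of the cohort, it
disconnects from the network — while the late-worsening cluster's
centrality rises after T6 as it converges onto the severe profile.
The `examples/` scripts cover each capability end to end; the `oabnet`
CLI (`oabnet run-all --preset study_sizes --seed 42 --outdir run/`)
writes the full artifact set (cohort, clusters, SSE curve, embedding,
five GraphML networks, metric trajectories, change table, manifest).

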