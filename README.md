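# kinectome

Whole-body movement networks from motion-capture gait data.

Clinical gait analysis usually reduces a walking body to a handful of
summary parameters (step length, cadence, joint angles), discarding the
coordination *between* body segments. This package instead treats the body
as a network — the **kinectome**: nodes are reflective markers on bone
landmarks (21 by default, covering head, trunk, arms, pelvis, legs, and
feet), and edges are Pearson correlations between the markers'
acceleration or jerk time series over a gait cycle, computed separately
along the mediolateral (ML), anteroposterior (AP), and vertical (V) lab
axes. Each ~2 s trial therefore yields six 21 × 21 networks
(2 kinematic quantities × 3 axes), each with 210 unique edges.

It is aimed at movement scientists and clinical gait labs who want
network-level descriptions of locomotion — in particular of Parkinson's
disease, where trunk rigidity and asymmetry reshape whole-body
coordination.

## What it computes

Given per-subject test/retest trials (C3D or delimited text) plus a
subject table, the package runs four analysis families:

- **Group structure** — element-wise mean and SD of the kinectomes per
  group, compared by label-shuffling permutation tests
  (Bonferroni-corrected; 0.05/6 ≈ 0.0083 over the six network types).
- **Modularity** — communities of each network by seeded Louvain
  optimization of Newman's Q,
  `Q = (1/2m) Σᵢⱼ [Aᵢⱼ − kᵢkⱼ/2m] δ(cᵢ,cⱼ)`,
  stabilized by consensus clustering (100 iterations), summarized in
  allegiance matrices (probability that two markers share a community
  across subjects).
- **Fingerprinting** — the identifiability matrix correlates every
  subject's test edge vector with every retest vector; I-self (diagonal),
  I-others (off-diagonal), I-diff = I-self − I-others, and the
  identification rate IR = fraction of subjects whose self-similarity
  beats all their cross-subject similarities.
- **Edge selection & clinical topology** — per-edge test-retest
  reliability via the one-way intraclass correlation
  `ICC = (MSA − MSW) / (MSA + (k−1)·MSW)`, IR curves over ICC-ranked edge
  subsets with random-edge null bands, markers flagged when the edges that
  drive identification hinge on them above chance, the flagged marker's
  weighted degree `sᵢ = Σⱼ |wᵢⱼ|` compared between groups, and an OLS
  model (degree + age + education + gender, VIFs, 5-fold CV) predicting
  the clinical motor score.

No public dataset accompanies the method, so `kinectome.synth` generates
synthetic cohorts with the statistical structure the analyses assume:
harmonic gait templates with planted community structure, stable
subject signatures across trials, and a parkinsonian mode with asymmetry,
trunk–limb hypercoupling centred on the T10 marker, inflated AP
variability, and a motor score derived from the planted coupling. See
`docs/methods.md` for the model and its limits.

## Worked example

```python
import kinectome as kc

# two synthetic cohorts: healthy controls and a parkinsonian group
hc_spec = kc.CohortSpec(n_subjects=23, mode="healthy", seed=1)
pd_spec = kc.CohortSpec(n_subjects=23, mode="parkinsonian", seed=101)
hc = kc.validate_session(*kc.generate_cohort(hc_spec))
pd_trials, pd_subjects = kc.generate_cohort(pd_spec)
pd = kc.validate_session(pd_trials, pd_subjects)

# fingerprint the healthy cohort from AP jerk kinectomes
test = [kc.vectorize(kc.build_kinectome(kc.axis_series(t, "jerk", "AP")))
        for t, _ in hc.values()]
retest = [kc.vectorize(kc.build_kinectome(kc.axis_series(r, "jerk", "AP")))
          for _, r in hc.values()]
scores = kc.fingerprint_scores(kc.identifiability_matrix(test, retest))
print(f"IR = {scores.ir * 100:.1f}%, I-diff = {scores.idiff * 100:.1f}%")

# T10 weighted degree from ML acceleration, per group
deg = lambda pairs: [
    kc.weighted_degree(kc.build_kinectome(
        kc.axis_series(t, "acceleration", "ML")))["T10"]
    for t, _ in pairs.values()
]
res = kc.permutation_compare(deg(hc), deg(pd), n_perm=10000, seed=0)
print(f"T10 degree HC vs PD: |Δ| = {res.observed_stat:.2f}, "
      f"p = {res.p_value:.4f}")
```

Output:

```
IR = 100.0%, I-diff = 5.9%
T10 degree HC vs PD: |Δ| = 2.05, p = 0.0001
```

Every healthy subject is re-identified from a single ~2 s retest recording
(IR 100%: each subject's self-similarity exceeds all 44 of their
cross-subject similarities), and the parkinsonian group's trunk marker is
substantially more strongly coupled to the rest of the body along the
mediolateral axis — the planted disease effect (about +2 in weighted
degree, permutation p ≈ 1e-4).

The same study runs end to end from the command line:

```bash
kinectome simulate --n-subjects 23 --mode parkinsonian --seed 1 --output cohort/
kinectome run-all --config study.json
```

`run-all` writes per-stage artifacts (kinectomes, allegiance matrices, IR
curves, predictions) plus `report.json` / `report.txt` to the configured
output directory; `build`, `modularity`, `fingerprint`, `edges`,
`topology`, and `predict` run the chain up to that stage.

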