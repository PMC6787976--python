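# lobarflow

Quantitative lobar CT analysis for paired inspiration/expiration scans.

Idiopathic pulmonary fibrosis (IPF) changes both the *structure* of lung
tissue (denser, scarred parenchyma) and its *function* (how much air each
lobe moves during a breath). Both changes are visible in a pair of
breath-hold CT scans — one at full inspiration ("expanded"), one at full
expiration ("contracted") — given a lobe segmentation. lobarflow turns such
a pair, plus a lobe label map, into:

* **HU histogram statistics** per region: mean, median, skewness and
  kurtosis of the Hounsfield-unit distribution (population moments,
  non-excess kurtosis). Fibrosis raises the mean and flattens the air peak,
  lowering skewness and kurtosis.
* **Lobar mechanics** over the four analysed lobes *i* ∈ {RU, RL, LL, LU}
  (RU includes the right middle lobe):
  - volume fraction `V_i = v_i / Σ_j v_j`,
  - lobar flow `Q_i = (v_e,i − v_c,i) / Σ_j (v_e,j − v_c,j)` — the share of
    the breath moved by lobe *i*,
  - lobar strain `S_i = (v_e,i − v_c,i) / v_e,i`.
* **A healthy-reference discriminant score.** For a per-lobe quantity X,
  a subject's distance from a healthy cohort with per-lobe mean `X̄_i^h`
  and SD `σ_i^h` is

  `score(X) = (1/4) Σ_i |X_i − X̄_i^h| / σ_i^h`

  (the field calls this an RMSD; written out it is the mean absolute
  standardized deviation — a quadratic variant is available). Robustness to
  the reference cohort's composition is assessed by leave-one-out
  validation. Applied to the lobar flow Q, this score is the package's
  headline discriminant between fibrotic and healthy lungs.
* **Cohort statistics**: Welch t-tests from summary statistics, Bonferroni
  family-wise correction, Kolmogorov–Smirnov normality screening, the
  GAP (gender–age–physiology) index, and percent-difference derivations
  between group means.
* **Synthetic data**: paired CT phantoms (ellipsoidal lobes, air/tissue/
  fibrosis HU mixtures, per-lobe air-content conservation between states)
  and tabular cohorts with configurable group structure, so the entire
  pipeline is testable without patient data.

Volumes and label maps are exchanged as NIfTI (via nibabel); label
convention: 0 background, 1 RU, 2 RL, 3 LL, 4 LU.

## Worked example

`examples/02_lobar_mechanics.py` builds one paired phantom at healthy
group-mean volumes (5.56 L expanded, 2.46 L contracted) and measures it
back through the pipeline:

```
lung volume: expanded 5.56 L, contracted 2.46 L
lobe   v_e (L)   v_c (L)   V_exp       Q       S
  RU     1.334     0.652   0.240   0.220   0.511
  RL     1.557     0.627   0.280   0.300   0.597
  LL     1.390     0.553   0.250   0.270   0.602
  LU     1.279     0.628   0.230   0.210   0.509
sum of Q: 1.000000
```

The measured flow split (22/30/27/21%) matches the generator's target
exactly — in a healthy lung the lower lobes carry the largest share of the
breath — and Q sums to 1 by construction.

`examples/03_flow_discriminant.py` simulates a 13-healthy / 9-fibrotic
tabular cohort and scores everyone against the healthy reference:

```
 healthy: flow score 0.79 ± 0.23 (range 0.31–1.09; mean leave-one-out SD 0.059)
     ipf: flow score 2.78 ± 1.09 (range 1.60–5.19; mean leave-one-out SD 0.106)
```

Fibrotic subjects shift flow toward the right upper lobe, landing several
healthy-cohort standard deviations away from the reference profile; the
small leave-one-out SDs show the score is robust to which healthy subject
anchors the reference.

The other examples cover histogram statistics on healthy vs fibrotic
phantoms, GAP scoring (including the missing-DLCO branch), and the full
pipeline driver. A thin CLI mirrors the library
(`lobarflow segment|hist|mechanics|rmsd|compare|gap|simulate|run`).

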