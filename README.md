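# mmconn — multimodal brain connectome analysis

`mmconn` is a tested pipeline for multimodal connectomics of the kind used
in clinical neuroimaging studies of ALS and other network-level
neurodegenerative diseases. It builds three kinds of brain network on a
shared 104-node parcellation (Desikan–Killiany cortex + subcortical and
cerebellar nodes), analyses them at fixed edge density, quantifies how
strongly structure predicts function, and relates network metrics to
clinical scores:

* **Structural covariance networks (SCN)** — cross-subject correlations of
  regional morphometry after adjusting for age, sex and total intracranial
  volume, Fisher z-transformed; group inference by label permutation.
* **Diffusion (DTI) connectomes** — streamline-count matrices normalized by
  ROI size, w_ij = c_ij / ((v_i + v_j)/2).
* **Functional connectivity (FC)** — ROI-to-ROI Pearson correlations of
  rest and task fMRI series, Fisher z-transformed; task runs are first
  residualized against HRF-convolved block regressors so they represent
  intrinsic (background) connectivity.
* **Graph metrics at fixed density** — every network is thresholded to its
  top-5% strongest edges (K = round(ρ·N(N−1)/2) = 268 at N = 104, mean
  nodal degree 5.154) before computing global efficiency, clustering,
  characteristic path length L, Louvain modularity Q, assortativity r,
  small-worldness σ = (C/C_rand)/(L/L_rand) and the normalized rich-club
  coefficient φ against degree-preserving (Maslov–Sneppen) null models,
  plus nodal degree, strength and betweenness.
* **Structure–function coupling** — the Pearson correlation of two
  matrices' edge vectors over all 5356 unique node pairs; couplings are
  compared with Fisher's z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).
* **Clinical statistics** — Shapiro-gated Welch-t / Mann–Whitney group
  comparisons with Cohen's d or rank-biserial effect sizes,
  Benjamini–Hochberg FDR, and Spearman correlations between network
  metrics and clinical measures (grip strength, ALSFRS-R).

Because raw MRI data for such studies are rarely public, the package is
driven by a first-class **synthetic cohort generator** that plants known
ground truth — a two-group cohort with realistic demographics, modular
hemispherically-symmetric connectomes with a plantable interhemispheric
motor deficit δ, time series coupled to structure at a tunable ρ_sf, and
clinical scores tied to a network metric at a planted Spearman ρ — so
every downstream stage is testable by parameter recovery.

## Worked example

```python
import numpy as np
from mmconn import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=0))
print(report.recovery)
```

prints (seed 0, default study conditions — 15 patients / 14 controls,
300/600 volumes, top-5% thresholding, 100 nulls, 1000 permutations):

```
{'planted_rho_sf': 0.25, 'recovered_rho_sf_mean': 0.2387,
 'planted_delta': 0.15, 'interhemispheric_motor_diff': -5.43,
 'interhemispheric_motor_p': 0.00032,
 'planted_clinical_rho': -0.7, 'recovered_clinical_rho': -0.625}
```

(values abbreviated to 3–4 digits). That is: the planted
structure–function coupling (0.25) comes back as 0.239 from the measured
rest-FC matrices, the planted interhemispheric motor-deficit direction is
detected (patient − control strength difference negative, Mann–Whitney
p ≈ 3e-4), and the planted clinical Spearman (−0.70) is recovered as
−0.625 at n = 15 (small-sample noise; at n = 200 it recovers within
±0.05). `report` also carries the demographic, SCN, DTI,
FC, topology, coupling, clinical and nodal tables as DataFrames;
`run_pipeline(cfg, outdir=...)` writes them as TSV alongside connectogram
edge lists.

The same stages are exposed as numbered analysis drivers:

```bash
python analysis/01_simulate.py          # cohort, morphometry, matrices
python analysis/02_build_scn.py         # covariance networks + permutation test
python analysis/03_network_metrics.py   # fixed-density metric tables
python analysis/04_coupling.py          # cross-modal coupling + Fisher z
python analysis/05_clinical.py          # demographic + clinical tables
```

each writing its tables under `results/` (bulky per-subject matrices go to
`scratch/`), and as a thin CLI (`mmconn generate|build-scn|build-fc|
normalize-dti|metrics|couple|couple-compare|clinical|run`).

A packaged per-subject clinical fixture (ages, grip strengths, ALSFRS-R
for 15 patients and 14 controls) ships with the package; its group
summaries — patient age 64.7 ± 6.5 vs control 63.7 ± 3.9 (t-test p =
0.61), dominant grip 15.2 ± 6.6 vs 32.2 ± 1.8 kg — are reproduced by
`mmconn.pipeline.demographic_table`.

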