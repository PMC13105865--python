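# crossomics

Graph-regularized cross-omics attention networks for molecular subtype
classification.

## The problem

Intrinsic molecular subtypes (Luminal A/B, HER2-enriched, Basal-like,
Normal-like) drive treatment stratification in breast cancer, and each subtype
leaves traces across several molecular layers at once: transcription, promoter
methylation, and miRNA regulation.  Most multi-omics classifiers either
concatenate features or align patients by similarity; neither represents the
*mechanistic* relations between molecular entities.  `crossomics` instead
builds a fixed heterogeneous graph whose nodes are genes, promoter-associated
CpG clusters and miRNAs, and whose edges encode biological priors:

* a CpG cluster — probes within 500 bp of one another, mean beta value,
  clusters with ≥ 2 probes — links to a gene when it falls in the strand-aware
  promoter window (2,000 bp upstream to 500 bp downstream of each annotated
  TSS);
* a miRNA links to each predicted target with cumulative weighted context++
  score ≤ −0.2.

Per patient, each node carries one standardized measurement.  A relation-aware
graph network propagates evidence across these edges

    h_v ← σ( W₀ h_v + Σ_r Σ_{u ∈ N_r(v)} 1/|N_r(v)| · W_r h_u ),

attention pools each node type into a modality vector, a second masked
attention fuses the present modalities, and a softmax head yields subtype
probabilities.  Training minimizes cross-entropy plus a Laplacian smoothness
penalty along cross-omics edges, λ_gr Σ_(u,v)∈E w_uv ‖h_u − h_v‖², plus weight
decay.  Around the model sit the analyses a deployment-oriented study needs:
repeated stratified cross-validation with strictly fold-safe preprocessing,
calibration (ECE / Brier / NLL), the variance-corrected repeated-CV t-test,
missing-modality robustness, selective prediction with validation-chosen
abstention thresholds, site-held-out evaluation, and gradient-based
attribution (saliency, integrated gradients, differentiable edge gates) with
subtype-specific explanatory subnetwork extraction.

A built-in generator produces synthetic annotation tables and cohorts with
subtype signal planted *along cross-omics edges* (anchor-gene overexpression
coupled to promoter hypomethylation and miRNA regulation), so the entire
pipeline is testable without any external download.  It is for method
development and verification, not a substitute for real cohorts.

## Worked example

Simulate a cohort, rebuild the graph from the emitted annotation tables, and
run a cross-validated training from the shell:

```bash
crossomics simulate --seed 7 --out demo
crossomics build-graph --genes demo/genes.tsv --probes demo/probes.tsv \
    --targets demo/targets.tsv --out demo/graph2
crossomics train --graph demo/graph --data demo --seed 7 \
    --repeats 1 --folds 5 --config demo_model.yaml --out demo/run
crossomics evaluate --oof demo/run/oof_predictions.tsv --out demo/eval
```

with `demo_model.yaml` containing `hidden_dim: 16`.  Output:

```
simulated cohort: 300 patients, 145 nodes, 145 edges -> demo
graph: {'gene': 60, 'cpg': 60, 'mirna': 25} nodes, {'g-c': 55, 'm->g': 90} edges -> demo/graph2
OOF accuracy: 0.853 -> demo/run
accuracy=0.853 macro_f1=0.815 ece=0.044 -> demo/eval
```

Reading the numbers: the simulated 300-patient cohort spans five subtypes with
realistic class imbalance and 20% borderline patients; `0.853` is the
out-of-fold accuracy over one repeat of stratified five-fold CV — every
patient is predicted by a model that never saw it, including standardization
statistics.  `macro_f1` weighs the rare Normal-like-analogue class as much as
the dominant Luminal-A-analogue; `ece` is the expected calibration error over
15 confidence bins (0 = perfectly calibrated probabilities).  The same
library calls are available in Python (`crossomics.simulate`,
`crossomics.training.cross_validate`, `crossomics.evaluation`), and
`crossomics explain` / `crossomics robustness` emit attribution tables,
explanatory subnetworks, missing-modality reports and coverage–risk curves
from the same inputs.

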