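# qsmart

Explainable prediction of protein kinase inhibitor (PKI) response in
cancer cell lines from drug substructures and multi-omics cell-line
features, with statistically screened interaction terms.

Most high-accuracy drug-response predictors are black boxes: they ingest
expression profiles and compound structures and emit a log-IC50, but they
cannot say *which* drug substructure interacting with *which* mutated
kinase residue drives the prediction. `qsmart` takes the opposite route:
it moves the interaction structure out of the model and into the design
matrix, where every term is a named, testable quantity — at the price of
having to screen and select those terms carefully.

## The model

The response of cell line *j* to drug *i* (log-IC50) is modelled as

```
IC50 = β₀ + Σᵢ β₁ᵢ Dᵢ + Σⱼ β₂ⱼ Cⱼ + Σᵢₖ β₃ᵢₖ Dᵢ·Mₖ
          + Σₚ β₄ₚ PPIₚ + Σ_q β₅_q RECx_q + Σᵣ β₆ᵣ PWYxᵣ + Σₛ β₇ₛ GOxₛ + ε
```

where `Dᵢ` are drug features (fingerprint bits, descriptors, and the
assay-source batch covariate `From_Sanger`), `Cⱼ` are cell-line features
at seven levels (residue, motif, domain, gene, family, pathway/GO,
sample), `Mₖ ⊆ Cⱼ` are the residue-level mutation features (per
reference-PKA position: mutation count and the charge / polarity /
hydrophobicity / ASA / volume / energy deltas plus the BLOSUM62 score of
the substitution), and the product terms are:

* **drug × mutation** — fingerprint bit × residue feature, e.g.
  `PKA_187_CHA_X_Fingerprint_805` (only residues mapped onto the
  reference protein kinase A structure interact with drugs);
* **PPI** — expression(A) × expression(B) for STRING edges with combined
  score > 700 touching at least one kinase;
* **reaction / pathway / GO pairs** — products of mutation-count
  features within one namespace, excluding ancestor-related pairs.

Every candidate term is tested individually by a nested-model F-test,
adjusted by Benjamini–Hochberg, and kept at FDR < 0.05 with ≥ 30 non-zero
values. The design is then reduced by stepwise VIF screening
(VIFᵢ = 1/(1−R²ᵢ) ≤ 5, drug features visited in substructure-complexity
order) and Lasso selection with the BIC, `BIC = k·ln(n) − 2·ln(L̂)`,
scored on the least-squares refit of each path support. The selected
features feed either the explainable linear view or feed-forward TanH
networks whose hidden widths follow the geometric pyramid rule
(⌈N^½⌉; ⌈N^⅔⌉,⌈N^⅓⌉; N,⌈N^½⌉), trained with an L1 weight penalty,
10-fold cross-validation, early stopping, and an architecture/iteration
escalation schedule that stops at mean CV R² ≥ 0.8.

Because cell-line-scale pharmacogenomic corpora cannot ship with a
package, `qsmart` includes a first-class synthetic generator
(`qsmart.simulate`) that emulates every input table with planted main
effects, planted interactions of each class, an assay-source batch
effect, a collinear fingerprint block, and Gaussian noise at SNR ≈ 10 —
so the full pipeline is exercisable and its recovery measurable.

## Worked example

```python
from qsmart import (PipelineConfig, SimulationSpec, simulate_bundle,
                    run_pipeline, perturb_effect, ppi_edge_impacts)

config = PipelineConfig(seed=1)
bundle = simulate_bundle(SimulationSpec(seed=1))
result = run_pipeline(config, bundle, train_networks=True)

model = result["models"]["lung_nsclc"]
report = result["reports"]["lung_nsclc"]
design = result["designs"]["lung_nsclc"]
print(f"selected features: {len(model.feature_names)}")
print(f"10-fold CV R^2 (network): {model.network['cv_r2']:.3f}")
print(f"in-sample R^2: {report.r2:.3f}  RMSE: {report.rmse:.3f}")
print(f"mean multi-threshold AUC: {report.mean_auc:.3f}")

eff = perturb_effect(model, "From_Sanger", design)
print(f"From_Sanger unit effect on predicted log-IC50: {eff.delta:+.3f}")
print(ppi_edge_impacts(model, design).to_string(index=False))
```

prints

```
selected features: 10
10-fold CV R^2 (network): 0.908
in-sample R^2: 0.912  RMSE: 0.748
mean multi-threshold AUC: 0.955
From_Sanger unit effect on predicted log-IC50: -0.530
gene_a gene_b    delta sign_class
 GEN03  KIN07 0.993906   positive
```

Reading the output: the 2000 simulated responses form one cancer group
(lung NSCLC histologies); selection kept 10 features including all
planted effects; the single-layer pyramid network explains ~91% of the
held-out variance (the generator's SNR of 10 caps attainable R² at
0.909); classification of "sensitive" at thresholds −4…0 averages AUC
0.955. The unit-perturbation readout recovers the planted batch effect
(−0.5) and the planted PPI coefficient (+1.0) to within the noise.

The same run is available from the shell:

```sh
qsmart simulate --seed 1 --out bundle/
qsmart run --bundle bundle/ --out out/
qsmart explain --model out/model_lung_nsclc.json --bundle bundle/
```

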