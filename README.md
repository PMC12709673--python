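# kbinding — k-binding analysis of TCR CDR3 cross-reactivity

A single T-cell receptor (TCR) can recognize many peptide–MHC (pMHC)
targets. Given a universe U of seven related 9-mer peptides presented by
HLA-A*02:01 and a library of TCR variants randomizing six CDR3 positions
(a99, a100, a101 on the alpha chain; b98, b99, b100 on beta) over a
19-letter alphabet (19^6 ≈ 4.7 × 10^7 variants), a variant is **S-binding**
if it binds exactly the subset S ⊆ U and **k-binding** if k = |S|. This
package implements the full analysis around that definition:

* a **panning simulator** generating multi-round MACS selection read counts
  with a known ground-truth binding landscape (shared alpha-chain motif,
  strict position-importance hierarchy);
* **binder calling** (presence in round 3 of both replicates), k-binding
  stratification, an exact one-sided binomial test for excess
  cross-reactivity, and S-class sequence logos (position frequency matrices
  with information content IC_p = log2(20) − H_p);
* a **multi-label MLP classifier** (two 500-unit ReLU layers, 7 sigmoid
  outputs, Adam, 10 epochs) trained over BLOSUM50 / VHSE8 / one-hot
  embeddings with k-stratum weighted sampling, w_k = sqrt(n0 / n_k);
* **cross-validated evaluation** (10-fold × 2 seeds; F1 and average
  precision, overall / per stratum / per target) with the associated
  statistics (Kruskal–Wallis + ε², Dunn/FDR, Mann–Whitney, Wilcoxon, sign
  test) and logistic / label-permutation baselines;
* **residue-masking importance**: retrain with each residue or chain
  deleted, rank positions by ΔF1, and correlate with an external table of
  interface-energy changes (ΔI_sc) by Spearman rank correlation.

See `docs/methods.md` for the model, parameter choices and known limits.

## Worked example

The numbered scripts under `analysis/` run the pipeline end to end at desk
scale (2 × 10^4 variants, sequencing depth 3 × 10^5):

```
python analysis/01_simulate_panning.py      --outdir results --seed 11
python analysis/02_call_binders_stratify.py --outdir results
python analysis/03_logos.py                 --outdir results
python analysis/04_train_evaluate.py        --outdir results --seed 0
python analysis/05_baselines.py             --outdir results --seed 0
python analysis/06_mask_importance.py       --outdir results --seed 0
python analysis/07_energy_correlation.py    --outdir results
```

Selected output (seed 11 / 0):

```
Tax replicate 1 across rounds 0-3:
  unique variants: [20000, 18605, 4352, 875]
  top-100 read share: [0.009, 0.217, 0.84, 0.99]
k-binding strata: {0: 18020, 1: 385, 2: 211, 3: 198, 4: 262, 5: 272, 6: 338, 7: 314}
multi-binding (k>=2): observed 1595, expected under independence 1133,
  one-sided binomial p = 6.4e-41
mean alpha-position information: 1-binding 1.00 bits, 2-binding 2.51 bits
BLOSUM50: F1 = 0.789, AUPRC = 0.873 (20 fold cells)
residue ranking (most important first): a99 > a101 > b98 > a100 > b100 > b99
alpha vs beta chain, one-sided Wilcoxon p = 5.54e-06
Spearman(mean_delta_f1, Delta I_sc): rho = -0.98, p = 3.31e-05
```

Reading it: panning enriches (diversity collapses, the top-100 share rises
to ~1); presence-based calls over seven targets yield a k-stratified
universe whose multi-binding count far exceeds the independent-binding
null; cross-reactive (2-binding) classes carry more information at the
shared alpha motif than target-specific classes; BLOSUM50-embedded models
predict binding well out of fold; masked retraining recovers the
generator's position hierarchy with the alpha chain dominating; and the
importance ranking correlates strongly (negatively, as it should: larger
deterioration ↔ larger destabilization) with the interface-energy table.
The same stages are scriptable via the `kbinding` CLI (`kbinding run-all
--config cfg.yaml`) or the `kbinding.pipeline_cli.run_pipeline` API.

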