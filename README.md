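# rtamhc

Prediction of peptide binding affinity to **class II MHC** by a
regularized thermodynamic average, for immunologists and method
developers working on CD4+ T-cell epitope discovery.

Class II MHC molecules present peptides of 12–25 residues in an
open-ended groove; only a 9-residue core contacts the binding pockets,
and a given peptide can bind in any of its L − 8 *registers*. `rtamhc`
scores register M of a peptide with a position-specific energy matrix
β ∈ R^{9×20} (kcal/mol),

    ΔG_M = Σ_i β[i, seq[M+i]],

and predicts the apparent total affinity as the Boltzmann-weighted
average over all registers,

    ΔG = Σ_M f_M ΔG_M,     f_M = exp(ΔG_M/kT) / Σ_{M'} exp(ΔG_{M'}/kT),

with kT = 0.586 kcal/mol at room temperature, so suboptimal binding
registers contribute to the score instead of being discarded. The matrix
is fit to IC50-derived free energies ΔG_exp = −kT ln(IC50 [M]) by
minimizing mean squared error under the lasso-style constraint
Σ|β_ij| ≤ t (split nonnegative variables, constant starts 1 and 2, local
SLSQP solves over a descending t schedule, inner-validation model
selection). The predicted binding core is the register with the
largest-magnitude term in the Boltzmann sum.

The package also provides:

- a **similarity-aware cross-validation splitter**: peptides sharing an
  exact 9-mer are joined in a graph; connected components stay whole,
  oversized components are split at approximate sparsest cuts found by
  sweeping the Fiedler vector of the component Laplacian, and groups are
  dealt greedily onto folds — minimizing train/test sequence overlap;
- an **evaluation harness** (ROC AUC at a 500 nM binder threshold, RMSE,
  Pearson r; pooled and per-fold) with a deliberate leakage control;
- a **synthetic-data generator** with known sparse ground truth and a
  truth sidecar, for end-to-end recovery experiments;
- structural register annotations for 18 peptide–MHC X-ray complexes,
  usable to score register predictions of any trained matrix.

The main entry points are sklearn-style estimators — `RTARegressor`
(fit/predict, `coef_`, `fit_path_`) and `SimilarityKFold` (a CV splitter
that composes with `sklearn.model_selection`) — plus a thin `rtamhc` CLI.

## Worked example

Simulate an IEDB-style binding table, build minimally-overlapping folds,
train, and predict:

```
$ rtamhc simulate scratch/binding.tsv scratch/truth.tsv --n-peptides 400 --seed 7
wrote 400 records to scratch/binding.tsv (truth: scratch/truth.tsv)

$ rtamhc cvsplit scratch/binding.tsv scratch/folds.tsv --k-folds 5
fold sizes: [80, 80, 79, 79, 79]; splits performed: 0; cross-fold shared-9mer pairs: 0 (0% of cross-fold pairs)

$ rtamhc train scratch/binding.tsv scratch/matrix.tsv --fit-log scratch/fitlog.tsv --seed 1
selected t=30.17 start=1 train_mse=1.0190 val_mse=1.9022 nonzero=42

$ rtamhc predict scratch/matrix.tsv scratch/binding.tsv scratch/pred.tsv
wrote 397 predictions to scratch/pred.tsv

$ head -2 scratch/pred.tsv
peptide_id	sequence	predicted_dG_kcal_mol	predicted_IC50_nM	core_offset	core_sequence	ratio_top	ratio_second
HFYEHPSPVAINKIIADMLYFT	HFYEHPSPVAINKIIADMLYFT	4.68312	338269	3	EHPSPVAIN	0.545388	0.421066
```

Reading the output: the splitter achieved perfect separation (no 9-mer
shared across folds, no component needed splitting). The sweep selected
an L1 budget of ~30 kcal/mol keeping 42 of 180 coefficients nonzero;
training MSE ≈ 1.02 (kcal/mol)² matches the simulated noise of
σ = 1 kcal/mol. For the first peptide the model predicts a weak binder
(ΔG ≈ 4.7 kcal/mol, IC50 ≈ 0.3 mM) whose core 9-mer starts at 0-based
offset 3; the leading Boltzmann term carries only ~55% of the sum
(`ratio_top`), i.e. suboptimal registers matter for this peptide. The
same workflow runs from Python via `RTARegressor` /
`SimilarityKFold` / `run_cross_validation`.

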