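# Methods

## The model

Class II MHC molecules have an open binding groove: a peptide of length
L ≥ 9 can place any of its L − 8 consecutive 9-mers (the *core*, residues
P1..P9) into the groove, and which window is bound — the *register* — is
not known in advance. `rtamhc` scores a peptide with a position-specific
energy matrix β ∈ R^{9×20} (kcal/mol) under three assumptions:

1. **Additivity.** Pocket contributions are independent, so the affinity
   of register M is the sum of nine entries,
   ΔG_M = Σ_i β[i, seq[M+i]].
2. **Thermodynamic averaging.** All registers are populated according to
   Boltzmann statistics. The fraction bound in register M is
   f_M = exp(ΔG_M/kT) / Σ_{M'} exp(ΔG_{M'}/kT), and the apparent total
   affinity is the weighted average ΔG = Σ_M f_M ΔG_M. Suboptimal
   registers therefore contribute; the common "best window only"
   approximation is recovered exactly in the kT → 0 limit and is exposed
   as `max_register_affinity`. An alternative log-sum-exp (apparent
   dissociation constant) form, kT·ln Σ_M exp(ΔG_M/kT), is available via
   `model_form="logsumexp"` for sensitivity analysis; all defaults use
   the weighted average.
3. **Regularization.** β (180 free parameters) is fit under the lasso-style
   budget Σ_ij |β_ij| ≤ t, which drives coefficients exactly to zero as t
   shrinks.

Experimental affinities come from competition-assay IC50 values through
ΔG_exp = −kT ln(IC50 [molar]) (the K_i ≈ IC50 regime of the Cheng–Prusoff
relation; the exact K_i = IC50/(1 + [L]/K_d) form is provided but not used
by default). With this sign convention larger ΔG means stronger binding:
500 nM corresponds to ΔG ≈ 8.5 kcal/mol, 1 nM to ≈ 12.1 kcal/mol. Files
carry IC50 in nM (the IEDB convention); conversion to molar happens
internally.

The predicted binding register is the offset M_max of the
largest-magnitude term T_M = ΔG_M·exp(ΔG_M/kT) in the Boltzmann sum, with
ties broken toward the smaller offset; offsets are 0-based (the index of
the P1 residue; a 1-based "residues M+1..M+9" description maps to the
same window). The per-peptide diagnostics |T_(1)/Σ T_M| and
|T_(2)/T_(1)| quantify how much suboptimal registers matter; both are
reported per peptide and as empirical distributions over a dataset.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| kT | 0.586 | kcal/mol | R·T at ≈295 K; overridable everywhere |
| t grid | 12 values, 0.05·t_OLS … 2·t_OLS | kcal/mol | geometric; t_OLS is the L1 norm of an unconstrained least-squares fit on best-register cores (best register picked by a first-pass uniform-weight linear fit), bracketing the restrictive and loose regimes |
| start values | 1, 2 | — | every component of β⁺ and β⁻ starts at the same constant; both starts run for every t; no random multistart |
| validation fraction | 0.2 | — | seeded inner split used to pick the (t, start) run |
| solver | SLSQP | — | 360 nonnegative split variables, one linear constraint; ftol 1e-6, ≤2000 iterations |
| binder threshold | 500 | nM | AUC label; configurable |

**Model selection.** Training MSE alone would always favour the loosest
budget, so the winning (t, start) run is the one with the lowest MSE on
the seeded inner-validation split; exact ties resolve to the smaller t
(the more parsimonious model) and then the smaller start. Every feasible
solve competes, including runs that stopped at the iteration cap: on
noiseless data the loose-budget solves approach a perfect fit slowly and
would otherwise be discarded while being the best models; runs that
violate their budget are excluded, and a solve is only reported
`converged` when the solver succeeded *and* the budget holds. Folds are
selected per training set (per fold in cross-validation), not once
globally.

**Thresholded records** ("IC50 > 50000") are converted at the bound,
flagged, used for training and for binder/non-binder labels, and excluded
from RMSE/Pearson, where bound values would distort the statistics.
Duplicate (peptide, allele) measurements are median-aggregated before
conversion. Non-canonical residues (B, J, O, U, X, Z, lowercase) are
rejected with a logged warning, never silently dropped. No hydrophobicity
restriction is imposed on the P1 pocket.

## Identifiability (gauge freedom)

Every core window selects exactly one entry per matrix row, so adding a
constant c_i to row i with Σ_i c_i = 0 changes no register energy
difference and no prediction at all — an 8-dimensional exact gauge
freedom. Predictions, register calls and cross-validated metrics are
unaffected, but recovered matrices are only comparable to a ground truth
after gauge fixing (e.g. row-demeaning) unless the L1 budget is tight
enough to pin the solution to the sparse representative: at t = Σ|β*| the
minimal-L1 point is the sparse truth itself, and the tests recover it to
numerical precision. Matrix files therefore store one representative,
not a canonical form.

## Similarity-aware cross-validation

Random splits leak information because datasets contain families of
near-identical peptides. Two peptides are *similar* when they share an
exact 9-mer; similar peptides must not straddle a train/test boundary.
The splitter:

1. builds the shared-9-mer graph (via a 9-mer → peptide inverted index;
   identical to the all-pairs definition);
2. takes connected components as indivisible groups;
3. splits any group larger than one fold's share (⌈N/k⌉) at an
   approximate sparsest cut — nodes ordered by the Fiedler vector of the
   component Laplacian (dense symmetric eigendecomposition to 2000 nodes,
   shift-invert Lanczos above, sign fixed for determinism), all |V|−1
   prefix cuts scored by sp(S) = cut edges / min(|S|, |S̄|), minimum kept,
   ties preferring the more balanced cut then the smaller threshold —
   recursively until every group fits;
4. deals groups greedily, largest first, onto the currently smallest fold.

Every edge removed by a cut is a pair of similar peptides that can end up
in different folds, so the overlap report equals the removed-edge count
whenever the cut sides land in different folds (they are the largest
groups, so the greedy dealer separates them). The sweep cut is an
approximation to an NP-hard problem: on structured fixtures (paths,
cycles, clique-bridge graphs) it attains the exhaustive optimum, and the
property suite checks it never reports a sparsity below the true optimum.
k = N (leave-one-out) is allowed but logged as a caution, since overlap
between training and test sets then becomes unavoidable.

## Synthetic data

The generator emulates IEDB-style competition-assay tables: peptide
lengths uniform on 12–25, a sparse ground-truth matrix (default 20
nonzero entries, standard-normal values scaled by 5 kcal/mol), observed
ΔG = model ΔG + N(0, σ²) with σ = 1 kcal/mol by default, and IC50 written
in nM. The 5 kcal/mol scale was chosen so that simulated IC50 values span
the range of real competition assays — strongest binders around 1 nM and
a substantial weak tail beyond 50 µM — giving both classes at the 500 nM
binder threshold. A `family_fraction` (default 0.3) of peptides are built
by keeping a ≥9-residue window of a seed peptide and re-randomising its
flanks, guaranteeing shared 9-mers and exercising the splitter.

Each dataset carries a truth sidecar with the noise-free affinity and the
register the generating model itself assigns, computed by a deliberately
naive direct enumeration (independent of the vectorised, max-subtracted
production path). With a mean-zero sparse truth matrix many registers
have zero or negative energies, where "largest Boltzmann term" and
"largest ΔG" can name different windows; the sidecar uses the model's own
largest-|T| definition so that register-recovery checks compare two
implementations of one definition. Registers whose top two term
magnitudes differ by ≤ 1e-9 are marked ambiguous and excluded from
recovery scoring.

What the generator does *not* emulate: allele-specific pocket
preferences, assay-to-assay systematic shifts, length-dependent effects,
thresholded measurements, and real amino-acid composition biases.
Passing recovery tests therefore shows the estimator inverts its own
forward model under realistic noise and similarity structure — not that
it attains any particular accuracy on real IEDB data.

## Numerical choices

- All Boltzmann exponentials are computed after subtracting max_M ΔG_M/kT;
  weights are exact to 1e-9 normalisation over the tested range.
- Scoring-matrix TSVs print 17 significant digits and round-trip
  bit-exactly.
- The analytic gradient of the MSE through the weighted average,
  ∂ΔG/∂β_ij = Σ_M f_M x^(M)_ij [1 + (ΔG_M − ΔG)/kT], matches central
  differences to <1e-4 relative (typically ~1e-8).
- Degenerate inputs: single-register peptides give weight [1.0] and an
  undefined second-term ratio (NaN); a vanishing Boltzmann-sum total
  gives NaN ratios; empty datasets, non-positive IC50, out-of-range
  registers and malformed files raise typed errors.

## Experiment sizes

The packaged experiments use sizes chosen to exercise each property
clearly: 2000 peptides (1600 train / 400 test) with a 6-value t grid for
parameter recovery, 1000 peptides for register recovery and for the
noiseless cross-validation pipeline, 400 peptides / 3 folds for the
leakage contrast, and 100–500 random (matrix, peptide) pairs for the
oracle and limit checks.

## Known limitations

- Single-allotype model; no pan-allele parameter sharing and no pairwise
  residue-interaction terms.
- No peptide-flanking-residue or length features.
- The entropic register-count correction to the free energy is not
  implemented.
- Local solver from two constant starts: the objective is nonconvex, and
  a better local minimum than the one found can exist; the convex
  (all-9-mer) special case is verified against a lasso oracle.
- Similarity is exact 9-mer sharing only; fuzzier criteria (e.g. 80%
  identity) would need a different graph construction, for which the
  splitter's group/partition machinery can be reused unchanged.
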