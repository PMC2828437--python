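"""Scikit-learn style estimators wrapping the thermodynamic-average model.

``RTARegressor`` is the user-facing entry point: X is a sequence of
peptide strings, y the experimental binding free energies (kcal/mol, from
-kT ln IC50[M]).  ``SimilarityKFold`` is a CV splitter in the mould of
GroupKFold that derives its folds from the shared-9-mer similarity graph,
so the two compose with ``sklearn.model_selection`` utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import Peptide
from .graphs import build_fold_assignment
from .model import decompose, predict_core
from .thermo import ThermoParams, affinity_to_ic50_nM
from .training import TrainingConfig, fit_sweep, pack_dataset, predict_packed

__all__ = ["RTARegressor", "SimilarityKFold"]


def _as_sequences(X) -> list[str]:
    if hasattr(X, "sequences"):  # BindingDataset
        return list(X.sequences)
    seqs = list(np.asarray(X, dtype=object).ravel())
    if not all(isinstance(s, str) for s in seqs):
        raise TypeError("X must be a 1-d collection of peptide strings")
    return seqs


class RTARegressor(RegressorMixin, BaseEstimator):
    """Regularized thermodynamic-average binding-affinity model.

    Fits the 9 x 20 position-specific energy matrix to free energies by
    L1-constrained nonlinear least squares (split nonnegative variables,
    constant starts, descending t sweep with inner-validation selection).

    Parameters
    ----------
    t_values : sequence of float or None
        L1 budgets to sweep; None derives a geometric grid from the data.
    start_values : tuple of float
        Constant initial values for the split variables (default (1, 2)).
    kT : float
        Thermal energy in kcal/mol (default 0.586, room temperature).
    model_form : str
        "weighted_average" (Boltzmann-weighted mean of register
        affinities) or "logsumexp" (apparent-dissociation form).
    validation_fraction, tol, max_iter, n_t, random_state
        Model-selection split size, solver tolerance, iteration cap,
        default grid length, and seed.

    Attributes
    ----------
    coef_ : ndarray of shape (9, 20)
        Fitted energy matrix, kcal/mol.
    t_, start_ : float
        Budget and start value of the selected solve.
    fit_path_ : pandas.DataFrame
        One row per (t, start): train/validation MSE, L1 norm, support
        size, convergence flag.
    fit_result_ : FitResult
        Full diagnostics of the winning solve.
    """

    def __init__(
        self,
        t_values=None,
        start_values=(1.0, 2.0),
        kT: float = 0.586,
        model_form: str = "weighted_average",
        validation_fraction: float = 0.2,
        tol: float = 1e-6,
        max_iter: int = 2000,
        n_t: int = 12,
        random_state: int = 0,
    ):
        self.t_values = t_values
        self.start_values = start_values
        self.kT = kT
        self.model_form = model_form
        self.validation_fraction = validation_fraction
        self.tol = tol
        self.max_iter = max_iter
        self.n_t = n_t
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            t_values=tuple(self.t_values) if self.t_values is not None else None,
            start_values=tuple(self.start_values),
            kT=self.kT,
            tol=self.tol,
            max_iter=self.max_iter,
            validation_fraction=self.validation_fraction,
            seed=self.random_state,
            model_form=self.model_form,
            n_t=self.n_t,
        )

    def fit(self, X, y):
        sequences = _as_sequences(X)
        y = np.asarray(y, dtype=float).ravel()
        packed = pack_dataset(sequences, y)
        result, path = fit_sweep(packed, self._config())
        self.coef_ = result.beta
        self.t_ = result.t
        self.start_ = result.start_value
        self.fit_result_ = result
        self.fit_path_ = path
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted total binding free energies, kcal/mol."""
        check_is_fitted(self, "coef_")
        sequences = _as_sequences(X)
        packed = pack_dataset(sequences, np.zeros(len(sequences)))
        return predict_packed(packed, self.coef_, self.kT, self.model_form)

    def predict_ic50_nM(self, X) -> np.ndarray:
        """Predicted IC50 in nM."""
        return np.array([affinity_to_ic50_nM(dg, self.thermo_) for dg in self.predict(X)])

    def predict_register(self, X) -> list[tuple[int, str]]:
        """Predicted binding register (offset, core 9-mer) per peptide."""
        check_is_fitted(self, "coef_")
        return [predict_core(self.coef_, s, self.thermo_) for s in _as_sequences(X)]

    def decompose(self, X) -> list:
        """Full per-register decomposition for each peptide."""
        check_is_fitted(self, "coef_")
        return [
            decompose(self.coef_, s, self.thermo_, model_form=self.model_form)
            for s in _as_sequences(X)
        ]

    @property
    def thermo_(self) -> ThermoParams:
        return ThermoParams(kT=self.kT)


class SimilarityKFold(BaseEstimator):
    """K-fold CV splitter that keeps 9-mer-sharing peptides together.

    Connected components of the shared-9-mer graph are kept whole where
    possible; components larger than one fold's share are split at
    approximate sparsest cuts, and groups are packed greedily onto the
    smallest fold.  ``split`` yields (train_indices, test_indices) like
    sklearn splitters.  The realised assignment (with overlap accounting)
    is stored on ``assignment_`` after a call to ``split``.
    """

    def __init__(self, n_splits: int = 5, max_group_size: int | None = None):
        self.n_splits = n_splits
        self.max_group_size = max_group_size

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_splits

    def build(self, X):
        sequences = _as_sequences(X)
        peptides = (
            list(X.peptides)
            if hasattr(X, "peptides")
            else [Peptide(id=f"idx{i:06d}", sequence=s) for i, s in enumerate(sequences)]
        )
        self.assignment_ = build_fold_assignment(
            peptides, k=self.n_splits, max_group_size=self.max_group_size
        )
        self._ids = [p.id for p in peptides]
        return self.assignment_

    def split(self, X, y=None, groups=None):
        assignment = self.build(X)
        all_idx = np.arange(len(self._ids))
        for fold in range(1, self.n_splits + 1):
            test = assignment.test_indices(self._ids, fold)
            if test.size == 0:
                continue
            train = np.setdiff1d(all_idx, test)
            yield train, test
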