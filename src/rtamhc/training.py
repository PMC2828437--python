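"""Fitting the 9 x 20 energy matrix under an L1 budget.

The fit minimises the mean squared error between the model's
Boltzmann-averaged affinity and the IC50-derived dG_exp, subject to
sum_ij |beta_ij| <= t.  Following the standard lasso device, beta is split
into nonnegative parts beta = beta_plus - beta_minus, turning the problem
into a smooth, linearly-constrained (nonconvex) program over 360 bounded
variables that a local gradient solver handles directly.  Every solve is
started from the constant vectors 1 and 2, and a descending schedule of t
values traces the regularization path; the returned model is the
(t, start) run with the lowest inner-validation MSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize

from .alphabet import CORE_LENGTH, N_PARAMETERS, N_RESIDUES, encode_indices
from .data import BindingDataset
from .thermo import DEFAULT_THERMO, ThermoParams

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "FitResult",
    "PackedDataset",
    "pack_dataset",
    "mse_objective",
    "l1_norm",
    "split_variables",
    "merge_variables",
    "objective_gradient",
    "fit_at_t",
    "fit_sweep",
    "default_t_grid",
    "read_training_config",
]

NONZERO_TOL = 1e-8


@dataclass(frozen=True)
class TrainingConfig:
    """Solver and model-selection settings for the L1-constrained fit.

    ``t_values``: descending L1 cutoffs (kcal/mol); None derives a
    geometric grid from the data via :func:`default_t_grid`.
    ``start_values``: constant initial values for every component of the
    split variables.  ``validation_fraction`` of the training data is held
    out (seeded) to pick the best (t, start) run.
    """

    t_values: tuple[float, ...] | None = None
    start_values: tuple[float, ...] = (1.0, 2.0)
    kT: float = DEFAULT_THERMO.kT
    tol: float = 1e-6
    max_iter: int = 2000
    validation_fraction: float = 0.2
    seed: int = 0
    model_form: str = "weighted_average"
    n_t: int = 12

    def __post_init__(self) -> None:
        if self.t_values is not None:
            if not all(t > 0 for t in self.t_values):
                raise ValueError("all t_values must be positive")
        if any(s < 0 for s in self.start_values):
            raise ValueError("start_values must be nonnegative")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")

    @property
    def thermo(self) -> ThermoParams:
        return ThermoParams(kT=self.kT)


@dataclass
class FitResult:
    """One (t, start) solve: fitted matrix plus diagnostics."""

    beta: np.ndarray
    t: float
    start_value: float
    train_mse: float
    validation_mse: float
    l1_norm: float
    n_nonzero: int
    converged: bool
    n_evaluations: int
    message: str = ""


@dataclass
class PackedDataset:
    """Vectorised view of a dataset: all (peptide, register) core windows.

    ``design`` stacks the flattened 9 x 20 occupancy rows of every register
    of every peptide (CSR, nine ones per row); ``starts`` delimits each
    peptide's contiguous block of rows and ``y`` holds dG_exp.
    """

    design: sp.csr_matrix
    starts: np.ndarray
    seg: np.ndarray
    y: np.ndarray
    n_peptides: int


def pack_dataset(sequences: Sequence[str], y: np.ndarray) -> PackedDataset:
    y = np.asarray(y, dtype=float)
    if len(sequences) == 0:
        raise ValueError("empty dataset")
    if len(sequences) != len(y):
        raise ValueError("sequences and y length mismatch")
    rows, starts = [], [0]
    pos = np.arange(CORE_LENGTH)
    for seq in sequences:
        idx = encode_indices(seq)
        if len(idx) < CORE_LENGTH:
            raise ValueError(f"peptide {seq!r} shorter than {CORE_LENGTH}")
        n_reg = len(idx) - CORE_LENGTH + 1
        windows = idx[np.arange(n_reg)[:, None] + pos[None, :]]
        rows.append(pos[None, :] * N_RESIDUES + windows)  # flat (i, j) indices
        starts.append(starts[-1] + n_reg)
    flat = np.concatenate([r.ravel() for r in rows])
    n_rows = starts[-1]
    design = sp.csr_matrix(
        (
            np.ones(flat.size),
            flat,
            np.arange(0, flat.size + 1, CORE_LENGTH),
        ),
        shape=(n_rows, N_PARAMETERS),
    )
    starts_arr = np.asarray(starts[:-1], dtype=np.intp)
    seg = np.repeat(np.arange(len(sequences)), np.diff(starts))
    return PackedDataset(design=design, starts=starts_arr, seg=seg, y=y, n_peptides=len(sequences))


def _forward(packed: PackedDataset, beta_flat: np.ndarray, kT: float, model_form: str):
    """Predicted dG per peptide plus intermediates reused by the gradient."""
    g = packed.design @ beta_flat
    gmax = np.maximum.reduceat(g, packed.starts)
    w = np.exp((g - gmax[packed.seg]) / kT)
    z = np.add.reduceat(w, packed.starts)
    f = w / z[packed.seg]
    if model_form == "logsumexp":
        pred = gmax + kT * np.log(z)
    else:
        pred = np.add.reduceat(f * g, packed.starts)
    return pred, g, f


def predict_packed(
    packed: PackedDataset,
    beta: np.ndarray,
    kT: float = DEFAULT_THERMO.kT,
    model_form: str = "weighted_average",
) -> np.ndarray:
    """Model predictions for every peptide of a packed dataset."""
    pred, _, _ = _forward(packed, np.asarray(beta, dtype=float).ravel(), kT, model_form)
    return pred


def _mse_and_grad(
    packed: PackedDataset, beta_flat: np.ndarray, kT: float, model_form: str
) -> tuple[float, np.ndarray]:
    pred, g, f = _forward(packed, beta_flat, kT, model_form)
    resid = pred - packed.y
    mse = float(resid @ resid) / packed.n_peptides
    if model_form == "logsumexp":
        # d pred / d beta = sum_M f_M x_M
        row_coeff = f
    else:
        # d pred / d beta = sum_M f_M x_M [1 + (dG_M - pred) / kT]
        row_coeff = f * (1.0 + (g - pred[packed.seg]) / kT)
    w = row_coeff * (2.0 / packed.n_peptides) * resid[packed.seg]
    grad = packed.design.T @ w
    return mse, grad


def mse_objective(
    beta: np.ndarray,
    dataset: BindingDataset | PackedDataset,
    thermo: ThermoParams = DEFAULT_THERMO,
    model_form: str = "weighted_average",
) -> float:
    """Mean squared error of the model against dG_exp, (kcal/mol)^2."""
    packed = _as_packed(dataset)
    mse, _ = _mse_and_grad(packed, np.asarray(beta, dtype=float).ravel(), thermo.kT, model_form)
    return mse


def objective_gradient(
    beta: np.ndarray,
    dataset: BindingDataset | PackedDataset,
    thermo: ThermoParams = DEFAULT_THERMO,
    model_form: str = "weighted_average",
) -> np.ndarray:
    """Analytic gradient of :func:`mse_objective`, shape 9 x 20."""
    packed = _as_packed(dataset)
    _, grad = _mse_and_grad(packed, np.asarray(beta, dtype=float).ravel(), thermo.kT, model_form)
    return grad.reshape(CORE_LENGTH, N_RESIDUES)


def _as_packed(dataset: BindingDataset | PackedDataset) -> PackedDataset:
    if isinstance(dataset, PackedDataset):
        return dataset
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    return pack_dataset(dataset.sequences, dataset.dG_exp)


def l1_norm(beta: np.ndarray) -> float:
    """Sum of absolute coefficient values."""
    return float(np.abs(np.asarray(beta, dtype=float)).sum())


def split_variables(beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Canonical split beta = beta_plus - beta_minus with disjoint supports."""
    beta = np.asarray(beta, dtype=float)
    return np.maximum(beta, 0.0), np.maximum(-beta, 0.0)


def merge_variables(beta_plus: np.ndarray, beta_minus: np.ndarray) -> np.ndarray:
    """Recombine nonnegative split variables into beta."""
    beta_plus = np.asarray(beta_plus, dtype=float)
    beta_minus = np.asarray(beta_minus, dtype=float)
    if (beta_plus < 0).any() or (beta_minus < 0).any():
        raise ValueError("split variables must be nonnegative")
    return beta_plus - beta_minus


def fit_at_t(
    dataset: BindingDataset | PackedDataset,
    t: float,
    start_value: float,
    config: TrainingConfig = TrainingConfig(),
    validation: PackedDataset | None = None,
) -> FitResult:
    """One local solve at L1 budget ``t`` from a constant start.

    Minimises the MSE over z = (beta_plus, beta_minus) >= 0 subject to
    sum(z) <= t with SLSQP, every component of z initialised to
    ``start_value``.  A failed solve is returned flagged, never raised.
    """
    if not t > 0:
        raise ValueError(f"t must be positive, got {t}")
    packed = _as_packed(dataset)
    kT, form = config.kT, config.model_form
    n = N_PARAMETERS

    def fun(z: np.ndarray) -> tuple[float, np.ndarray]:
        mse, grad = _mse_and_grad(packed, z[:n] - z[n:], kT, form)
        return mse, np.concatenate([grad, -grad])

    z0 = np.full(2 * n, float(start_value))
    res = minimize(
        fun,
        z0,
        jac=True,
        method="SLSQP",
        bounds=[(0.0, None)] * (2 * n),
        constraints=[
            {
                "type": "ineq",
                "fun": lambda z: t - z.sum(),
                "jac": lambda z: -np.ones_like(z),
            }
        ],
        options={"maxiter": config.max_iter, "ftol": config.tol},
    )
    beta = merge_variables(res.x[:n], res.x[n:]).reshape(CORE_LENGTH, N_RESIDUES)
    train_mse, _ = _mse_and_grad(packed, beta.ravel(), kT, form)
    val_mse = (
        float(np.mean((predict_packed(validation, beta, kT, form) - validation.y) ** 2))
        if validation is not None
        else train_mse
    )
    norm = l1_norm(beta)
    converged = bool(res.success) and norm <= t + max(config.tol, 1e-6)
    if not res.success:
        logger.warning("solve at t=%.4g start=%g did not converge: %s", t, start_value, res.message)
    return FitResult(
        beta=beta,
        t=float(t),
        start_value=float(start_value),
        train_mse=train_mse,
        validation_mse=val_mse,
        l1_norm=norm,
        n_nonzero=int((np.abs(beta) > NONZERO_TOL).sum()),
        converged=converged,
        n_evaluations=int(res.nfev),
        message=str(res.message),
    )


def default_t_grid(
    dataset: BindingDataset | PackedDataset,
    n_t: int = 12,
    kT: float = DEFAULT_THERMO.kT,
) -> np.ndarray:
    """Data-driven descending geometric grid of L1 cutoffs.

    An unconstrained least-squares fit on each peptide's best-scoring core
    (best register chosen under a first-pass uniform-register fit) sets the
    scale t_OLS; the grid spans 0.05 t_OLS .. 2 t_OLS, bracketing both the
    restrictive and the loose regime.
    """
    packed = _as_packed(dataset)
    n_reg = np.diff(np.append(packed.starts, packed.design.shape[0]))
    # pass 1: uniform register weights -> plain linear model on averaged cores
    avg = sp.csr_matrix(
        (1.0 / n_reg[packed.seg], (packed.seg, np.arange(packed.design.shape[0])))
    )
    X_avg = (avg @ packed.design).toarray()
    beta0, *_ = np.linalg.lstsq(X_avg, packed.y, rcond=None)
    # pass 2: OLS on the best register under the first-pass matrix
    g = packed.design @ beta0
    order = np.argsort(g, kind="stable")  # ties -> smallest offset wins below
    best_rows = np.empty(packed.n_peptides, dtype=np.intp)
    best_rows.fill(-1)
    for row in order:  # later (larger g) overwrite earlier
        best_rows[packed.seg[row]] = row
    X_best = packed.design[best_rows].toarray()
    beta_ols, *_ = np.linalg.lstsq(X_best, packed.y, rcond=None)
    t_ols = max(float(np.abs(beta_ols).sum()), 1e-6)
    return np.geomspace(2.0 * t_ols, 0.05 * t_ols, n_t)


def fit_sweep(
    dataset: BindingDataset | PackedDataset,
    config: TrainingConfig = TrainingConfig(),
) -> tuple[FitResult, pd.DataFrame]:
    """Sweep (t, start) pairs, select by inner-validation MSE.

    A seeded ``validation_fraction`` of the data is held out; every
    (t, start) solve is run on the remainder and scored on the held-out
    part.  Returns the winning :class:`FitResult` (refit diagnostics keep
    the inner-train MSE) and the full path log.
    """
    packed = _as_packed(dataset)
    if packed.n_peptides < 5:
        raise ValueError("need at least 5 records to fit")
    rng = np.random.default_rng(config.seed)
    n = packed.n_peptides
    n_val = max(1, int(round(config.validation_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = np.sort(perm[:n_val]), np.sort(perm[n_val:])
    sub_train = _subset_packed(packed, train_idx)
    sub_val = _subset_packed(packed, val_idx)

    t_values = (
        np.asarray(config.t_values, dtype=float)
        if config.t_values is not None
        else default_t_grid(sub_train, n_t=config.n_t, kT=config.kT)
    )
    rows, results = [], []
    for t in t_values:
        for start in config.start_values:
            fit = fit_at_t(sub_train, float(t), float(start), config, validation=sub_val)
            results.append(fit)
            rows.append(
                {
                    "t": fit.t,
                    "start": fit.start_value,
                    "train_mse": fit.train_mse,
                    "validation_mse": fit.validation_mse,
                    "l1_norm": fit.l1_norm,
                    "n_nonzero": fit.n_nonzero,
                    "converged": fit.converged,
                }
            )
    path = pd.DataFrame(rows)
    # an iteration-limited solve is still a feasible point with a measured
    # validation MSE; only constraint-violating runs are excluded
    feasible = [
        r for r in results if r.l1_norm <= r.t + max(config.tol, 1e-6)
    ]
    if not feasible:
        raise RuntimeError(f"every (t, start) solve violated its budget; path:\n{path}")
    best = min(feasible, key=lambda r: (r.validation_mse, r.t, r.start_value))
    return best, path


def _subset_packed(packed: PackedDataset, idx: np.ndarray) -> PackedDataset:
    n_reg = np.diff(np.append(packed.starts, packed.design.shape[0]))
    rows = np.concatenate(
        [np.arange(packed.starts[i], packed.starts[i] + n_reg[i]) for i in idx]
    )
    sizes = n_reg[idx]
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.intp)
    return PackedDataset(
        design=packed.design[rows],
        starts=starts,
        seg=np.repeat(np.arange(len(idx)), sizes),
        y=packed.y[idx],
        n_peptides=len(idx),
    )


def read_training_config(path: str | Path) -> TrainingConfig:
    """Parse a key-value training-config text file (``key = value`` lines)."""
    kwargs: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in ("t_values", "start_values"):
            kwargs[key] = tuple(float(v) for v in value.replace(",", " ").split())
        elif key in ("kT", "tol", "validation_fraction"):
            kwargs[key] = float(value)
        elif key in ("max_iter", "seed", "n_t"):
            kwargs[key] = int(value)
        elif key == "model_form":
            kwargs[key] = value
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    return TrainingConfig(**kwargs)
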