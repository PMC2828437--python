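"""The thermodynamic-average scoring model.

A peptide of length L can occupy the open class II MHC groove in any of
L - 8 binding registers; register M places residues M..M+8 in pockets
P1..P9.  With a 9 x 20 energy matrix ``beta`` (kcal/mol) the affinity of
register M is the sum of the nine selected entries,

    dG_M = sum_i beta[i, seq[M + i]],

and the apparent total affinity is the Boltzmann-weighted average

    dG = sum_M f_M dG_M,    f_M = exp(dG_M / kT) / sum_M' exp(dG_M' / kT),

where larger dG means stronger binding.  All exponentials are computed
after subtracting max_M dG_M / kT.  An alternative log-sum-exp form
kT * ln sum_M exp(dG_M / kT) is available via ``model_form="logsumexp"``.

The predicted binding core is the register carrying the largest-magnitude
term T_M = dG_M * exp(dG_M / kT) of the Boltzmann sum; ties break toward
the smallest offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import (
    AMINO_ACIDS,
    CORE_LENGTH,
    N_RESIDUES,
    encode_indices,
    validate_sequence,
)
from .thermo import DEFAULT_THERMO, ThermoParams, affinity_to_ic50_nM

__all__ = [
    "MODEL_FORMS",
    "RegisterDecomposition",
    "n_registers",
    "encode_register",
    "register_affinity",
    "register_affinities",
    "register_weights",
    "total_affinity",
    "max_register_affinity",
    "predict_core",
    "term_ratios",
    "decompose",
    "ratio_distributions",
]

MODEL_FORMS = ("weighted_average", "logsumexp")


class RegisterRangeError(IndexError):
    """Register offset outside 0 .. L - 9."""


def _check_beta(beta: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (CORE_LENGTH, N_RESIDUES):
        raise ValueError(f"beta must be {CORE_LENGTH}x{N_RESIDUES}, got {beta.shape}")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta contains non-finite entries")
    return beta


def n_registers(sequence: str) -> int:
    """Number of binding registers, L - 8."""
    validate_sequence(sequence)
    return len(sequence) - CORE_LENGTH + 1


def encode_register(sequence: str, M: int) -> np.ndarray:
    """Binary 9 x 20 occupancy grid of the core window starting at offset M.

    Entry (i, j) is 1 iff residue type j sits at core position i, i.e.
    ``sequence[M + i]``; exactly nine ones in total.
    """
    idx = encode_indices(validate_sequence(sequence))
    if not 0 <= M <= len(sequence) - CORE_LENGTH:
        raise RegisterRangeError(
            f"register {M} out of range 0..{len(sequence) - CORE_LENGTH} "
            f"for length-{len(sequence)} peptide"
        )
    grid = np.zeros((CORE_LENGTH, N_RESIDUES))
    grid[np.arange(CORE_LENGTH), idx[M : M + CORE_LENGTH]] = 1.0
    return grid


def register_affinity(beta: np.ndarray, sequence: str, M: int) -> float:
    """Affinity dG_M (kcal/mol) of binding in register M."""
    beta = _check_beta(beta)
    idx = encode_indices(validate_sequence(sequence))
    if not 0 <= M <= len(sequence) - CORE_LENGTH:
        raise RegisterRangeError(
            f"register {M} out of range 0..{len(sequence) - CORE_LENGTH}"
        )
    return float(beta[np.arange(CORE_LENGTH), idx[M : M + CORE_LENGTH]].sum())


def register_affinities(beta: np.ndarray, sequence: str) -> np.ndarray:
    """Vector of dG_M for every register M = 0 .. L - 9."""
    beta = _check_beta(beta)
    idx = encode_indices(validate_sequence(sequence))
    n_reg = len(sequence) - CORE_LENGTH + 1
    pos = np.arange(CORE_LENGTH)
    windows = idx[np.arange(n_reg)[:, None] + pos[None, :]]
    return beta[pos[None, :], windows].sum(axis=1)


def register_weights(
    beta: np.ndarray, sequence: str, thermo: ThermoParams = DEFAULT_THERMO
) -> np.ndarray:
    """Fraction of bound peptide in each register (Boltzmann weights)."""
    dg = register_affinities(beta, sequence)
    return _softmax(dg / thermo.kT)


def _softmax(scaled: np.ndarray) -> np.ndarray:
    w = np.exp(scaled - scaled.max())
    return w / w.sum()


def total_affinity(
    beta: np.ndarray,
    sequence: str,
    thermo: ThermoParams = DEFAULT_THERMO,
    model_form: str = "weighted_average",
) -> float:
    """Apparent total binding affinity dG (kcal/mol).

    ``weighted_average`` (default) returns sum_M f_M dG_M, a convex
    combination of register affinities; ``logsumexp`` returns
    kT * ln sum_M exp(dG_M / kT), the apparent-dissociation form.  Both
    reduce to the single register affinity for a 9-mer.
    """
    if model_form not in MODEL_FORMS:
        raise ValueError(f"model_form must be one of {MODEL_FORMS}, got {model_form!r}")
    dg = register_affinities(beta, sequence)
    scaled = dg / thermo.kT
    if model_form == "logsumexp":
        m = scaled.max()
        return float(thermo.kT * (m + math.log(np.exp(scaled - m).sum())))
    return float(_softmax(scaled) @ dg)


def max_register_affinity(beta: np.ndarray, sequence: str) -> float:
    """Best single-register affinity max_M dG_M (the kT -> 0 limit)."""
    return float(register_affinities(beta, sequence).max())


def _boltzmann_terms(
    beta: np.ndarray, sequence: str, thermo: ThermoParams
) -> tuple[np.ndarray, np.ndarray]:
    """Return (dG_M, T_M) with the shared normalisation factored out.

    T_M = dG_M * exp((dG_M - max dG) / kT); the common positive factor
    exp(max dG / kT) cancels in every ratio and in the argmax.
    """
    dg = register_affinities(beta, sequence)
    return dg, dg * np.exp((dg - dg.max()) / thermo.kT)


def predict_core(
    beta: np.ndarray, sequence: str, thermo: ThermoParams = DEFAULT_THERMO
) -> tuple[int, str]:
    """Predicted binding register: (offset M_max, core 9-mer).

    M_max is the offset of the largest-|T_M| Boltzmann-sum term; ties break
    toward the smallest offset.  Offsets are 0-based (P1 residue index).
    """
    _, terms = _boltzmann_terms(beta, validate_sequence(sequence), thermo)
    m_max = int(np.argmax(np.abs(terms)))
    return m_max, sequence[m_max : m_max + CORE_LENGTH]


def term_ratios(
    beta: np.ndarray, sequence: str, thermo: ThermoParams = DEFAULT_THERMO
) -> tuple[float, float]:
    """Suboptimal-register diagnostics (ratio_top, ratio_second).

    With terms ordered by magnitude |T_(1)| >= |T_(2)| >= ...:
    ratio_top = |T_(1) / sum_M T_M| and ratio_second = |T_(2) / T_(1)|.
    ratio_second is NaN for a single register; both are NaN when the sum
    (ratio_top) or leading term (ratio_second) vanishes.
    """
    _, terms = _boltzmann_terms(beta, validate_sequence(sequence), thermo)
    mags = np.sort(np.abs(terms))[::-1]
    total = terms.sum()
    ratio_top = math.nan if total == 0.0 else float(mags[0] / abs(total))
    if len(terms) < 2 or mags[0] == 0.0:
        ratio_second = math.nan
    else:
        ratio_second = float(mags[1] / mags[0])
    return ratio_top, ratio_second


@dataclass
class RegisterDecomposition:
    """Per-register breakdown of one peptide's predicted binding."""

    peptide_id: str
    sequence: str
    dG_by_register: np.ndarray
    weights: np.ndarray
    terms: np.ndarray
    M_max: int
    core: str
    dG_total: float
    ratio_top: float
    ratio_second: float
    predicted_ic50_nM: float = field(default=math.nan)


def decompose(
    beta: np.ndarray,
    sequence: str,
    thermo: ThermoParams = DEFAULT_THERMO,
    peptide_id: str = "",
    model_form: str = "weighted_average",
) -> RegisterDecomposition:
    """Full register decomposition for one peptide."""
    dg, terms = _boltzmann_terms(beta, validate_sequence(sequence), thermo)
    weights = _softmax(dg / thermo.kT)
    m_max = int(np.argmax(np.abs(terms)))
    dg_total = total_affinity(beta, sequence, thermo, model_form=model_form)
    ratio_top, ratio_second = term_ratios(beta, sequence, thermo)
    return RegisterDecomposition(
        peptide_id=peptide_id or sequence,
        sequence=sequence,
        dG_by_register=dg,
        weights=weights,
        terms=terms,
        M_max=m_max,
        core=sequence[m_max : m_max + CORE_LENGTH],
        dG_total=dg_total,
        ratio_top=ratio_top,
        ratio_second=ratio_second,
        predicted_ic50_nM=affinity_to_ic50_nM(dg_total, thermo),
    )


def ratio_distributions(
    beta: np.ndarray,
    sequences: list[str],
    thermo: ThermoParams = DEFAULT_THERMO,
) -> dict[str, np.ndarray]:
    """Empirical distributions of the two term ratios over a peptide set.

    Returns sorted arrays (empirical CDF supports) under keys
    ``"ratio_top"`` and ``"ratio_second"``; undefined (NaN) ratios are
    dropped.  Mirrors the dataset-level view of how much suboptimal
    registers contribute to the Boltzmann sum.
    """
    tops, seconds = [], []
    for seq in sequences:
        rt, rs = term_ratios(beta, seq, thermo)
        if not math.isnan(rt):
            tops.append(rt)
        if not math.isnan(rs):
            seconds.append(rs)
    return {
        "ratio_top": np.sort(np.asarray(tops)),
        "ratio_second": np.sort(np.asarray(seconds)),
    }
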