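"""Synthetic competition-assay datasets with known ground truth.

The generator emulates IEDB-style binding tables: peptides of 12-25
residues over the 20 canonical amino acids, IC50 values spanning roughly
1 nM to beyond 50 uM, produced by a sparse ground-truth 9 x 20 energy
matrix through the thermodynamic-average forward model plus Gaussian
noise on the free-energy scale.  A configurable fraction of peptides are
generated as families of overlapping variants of seed peptides so that
they share exact 9-mers, exercising the similarity-aware CV splitter.

Each dataset ships with a truth sidecar holding, per peptide, the
noise-free model affinity and the binding register the generating model
itself assigns (largest-magnitude Boltzmann term, computed here by plain
direct enumeration, independent of the stabilized production code path).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, CORE_LENGTH, N_RESIDUES
from .data import BindingDataset, BindingRecord, Peptide
from .thermo import DEFAULT_THERMO, ThermoParams, affinity_to_ic50_nM, ic50_nM_to_affinity

__all__ = ["SyntheticSpec", "generate_beta", "generate_peptides", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    ``beta_sparsity`` nonzero energies of scale ``beta_scale`` (kcal/mol,
    standard-normal draws times the scale) define the ground truth;
    ``noise_sd`` is the measurement noise on the free-energy scale
    (kcal/mol); ``family_fraction`` of the peptides are 9-mer-sharing
    variants of seed peptides.
    """

    n_peptides: int = 500
    length_range: tuple[int, int] = (12, 25)
    beta_sparsity: int = 20
    beta_scale: float = 5.0
    noise_sd: float = 1.0
    family_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < CORE_LENGTH:
            raise ValueError("minimum peptide length is 9")
        if not 0 <= self.family_fraction <= 1:
            raise ValueError("family_fraction must be in [0, 1]")
        if not 0 <= self.beta_sparsity <= CORE_LENGTH * N_RESIDUES:
            raise ValueError("beta_sparsity must be in 0..180")


def generate_beta(spec: SyntheticSpec) -> np.ndarray:
    """Sparse seeded ground-truth matrix: exact nonzero count, normal values."""
    rng = np.random.default_rng(spec.seed)
    beta = np.zeros(CORE_LENGTH * N_RESIDUES)
    support = rng.choice(beta.size, size=spec.beta_sparsity, replace=False)
    values = rng.standard_normal(spec.beta_sparsity) * spec.beta_scale
    values[values == 0.0] = spec.beta_scale  # exact sparsity even on a zero draw
    beta[support] = values
    return beta.reshape(CORE_LENGTH, N_RESIDUES)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[j] for j in rng.integers(0, N_RESIDUES, size=length))


def generate_peptides(spec: SyntheticSpec, rng: np.random.Generator) -> list[Peptide]:
    """Seed peptides plus 9-mer-sharing family variants.

    A family member keeps a random window (>= 9 residues) of its seed
    peptide and re-randomises fresh flanks to a new length, guaranteeing at
    least one shared 9-mer with the seed.
    """
    lo, hi = spec.length_range
    n_family = int(round(spec.family_fraction * spec.n_peptides))
    n_seed = spec.n_peptides - n_family
    peptides = [
        Peptide(id=f"pep{k:05d}", sequence=_random_sequence(rng, int(rng.integers(lo, hi + 1))))
        for k in range(n_seed)
    ]
    if n_family and not peptides:
        raise ValueError("family_fraction = 1 requires at least one seed peptide")
    for k in range(n_family):
        seed_pep = peptides[int(rng.integers(0, n_seed))]
        seq = seed_pep.sequence
        keep_len = int(rng.integers(CORE_LENGTH, len(seq) + 1))
        start = int(rng.integers(0, len(seq) - keep_len + 1))
        core = seq[start : start + keep_len]
        target_len = int(rng.integers(max(lo, keep_len), hi + 1))
        n_flank = target_len - keep_len
        n_left = int(rng.integers(0, n_flank + 1))
        variant = (
            _random_sequence(rng, n_left)
            + core
            + _random_sequence(rng, n_flank - n_left)
        )
        peptides.append(Peptide(id=f"pep{n_seed + k:05d}", sequence=variant))
    return peptides


def _direct_decomposition(
    beta: np.ndarray, sequence: str, kT: float
) -> tuple[float, int, float]:
    """Plain-loop forward model: (total dG, register of largest |term|, margin).

    Deliberately naive (no max-subtraction; per-window Python loop) so it
    can serve as an oracle for the vectorised production path.
    """
    dgs = []
    for m in range(len(sequence) - CORE_LENGTH + 1):
        dg = sum(
            beta[i, AMINO_ACIDS.index(sequence[m + i])] for i in range(CORE_LENGTH)
        )
        dgs.append(dg)
    shift = max(dgs)  # only to keep exp finite; cancels in weights and ratios
    weights = [math.exp((dg - shift) / kT) for dg in dgs]
    total = sum(w * dg for w, dg in zip(weights, dgs)) / sum(weights)
    terms = [abs(dg * w) for dg, w in zip(weights, dgs)]
    order = sorted(range(len(terms)), key=lambda m: (-terms[m], m))
    best = order[0]
    margin = terms[best] - terms[order[1]] if len(terms) > 1 else math.inf
    return total, best, margin


def generate_dataset(
    beta: np.ndarray,
    spec: SyntheticSpec,
    thermo: ThermoParams = DEFAULT_THERMO,
    allele: str = "synthetic",
) -> tuple[BindingDataset, pd.DataFrame]:
    """Forward-simulate a binding table plus its truth sidecar.

    dG_obs = model dG + Normal(0, noise_sd); IC50 = exp(-dG_obs / kT) in nM.
    The sidecar columns: peptide_id, sequence, true_dG (noise-free),
    true_core_offset (largest-|term| register of the generating model),
    term_margin (gap to the runner-up term; <= 1e-9 means the register
    call is ambiguous).  A pure function of (beta, spec, thermo).
    """
    rng = np.random.default_rng(spec.seed + 1)
    peptides = generate_peptides(spec, rng)
    noise = rng.normal(0.0, spec.noise_sd, size=len(peptides)) if spec.noise_sd > 0 else np.zeros(len(peptides))

    records, truth_rows = [], []
    for pep, eps in zip(peptides, noise):
        true_dg, core, margin = _direct_decomposition(beta, pep.sequence, thermo.kT)
        dg_obs = true_dg + eps
        ic50_nM = affinity_to_ic50_nM(dg_obs, thermo)
        records.append(
            BindingRecord(
                peptide=pep,
                ic50_nM=ic50_nM,
                dG_exp=ic50_nM_to_affinity(ic50_nM, thermo),
                allele=allele,
            )
        )
        truth_rows.append(
            {
                "peptide_id": pep.id,
                "sequence": pep.sequence,
                "true_dG": true_dg,
                "true_core_offset": core,
                "term_margin": margin,
            }
        )
    return BindingDataset(records, allele=allele), pd.DataFrame(truth_rows)
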