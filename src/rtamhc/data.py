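"""Binding-data containers and the package's text file formats.

The on-disk convention follows IEDB-style competition-assay tables:
tab-separated, one peptide per row, IC50 in nM (a ``>`` or ``<`` prefix
marks a thresholded measurement, e.g. ``>50000`` for "weaker than 50 uM").
Internally IC50 is converted to molar before the free-energy transform.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import AMINO_ACIDS, AlphabetError, CORE_LENGTH, validate_sequence
from .thermo import DEFAULT_THERMO, ThermoParams, ic50_nM_to_affinity

logger = logging.getLogger(__name__)

__all__ = [
    "Peptide",
    "BindingRecord",
    "BindingDataset",
    "read_binding_table",
    "write_binding_table",
    "read_fasta",
    "write_matrix",
    "read_matrix",
    "write_folds",
    "read_folds",
    "write_predictions",
    "write_fit_log",
]


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with an identifier; length must be >= 9."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_registers(self) -> int:
        return len(self.sequence) - CORE_LENGTH + 1


@dataclass(frozen=True)
class BindingRecord:
    """One peptide-allele measurement: IC50 (nM), derived dG_exp (kcal/mol).

    ``thresholded`` marks bound-only values ("IC50 > 50000"); dG_exp is
    computed at the bound.  Thresholded records take part in training and
    in binder/non-binder labelling but are excluded from RMSE/Pearson.
    """

    peptide: Peptide
    ic50_nM: float
    dG_exp: float
    allele: str = ""
    thresholded: bool = False


@dataclass
class BindingDataset:
    """A deduplicated set of binding records for one allele."""

    records: list[BindingRecord]
    allele: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.peptide.sequence for r in self.records]

    @property
    def peptides(self) -> list[Peptide]:
        return [r.peptide for r in self.records]

    @property
    def dG_exp(self) -> np.ndarray:
        return np.array([r.dG_exp for r in self.records])

    @property
    def ic50_nM(self) -> np.ndarray:
        return np.array([r.ic50_nM for r in self.records])

    @property
    def thresholded(self) -> np.ndarray:
        return np.array([r.thresholded for r in self.records], dtype=bool)

    def subset(self, indices: Iterable[int]) -> "BindingDataset":
        return BindingDataset([self.records[i] for i in indices], allele=self.allele)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peptide_id": [r.peptide.id for r in self.records],
                "peptide": self.sequences,
                "ic50_nM": self.ic50_nM,
                "dG_exp": self.dG_exp,
                "thresholded": self.thresholded,
                "allele": [r.allele for r in self.records],
            }
        )


def _parse_ic50(cell: str) -> tuple[float, bool]:
    cell = str(cell).strip()
    thresholded = cell.startswith((">", "<"))
    value = float(cell.lstrip("<>").strip())
    return value, thresholded


def read_binding_table(
    path: str | Path, thermo: ThermoParams = DEFAULT_THERMO
) -> BindingDataset:
    """Read a TSV binding table (columns ``peptide``, ``ic50_nM``, ``allele``).

    Rows with non-canonical residues or non-positive IC50 are rejected with
    a logged warning naming the line.  Multiple measurements of the same
    (peptide, allele) are aggregated by the median IC50 before conversion.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"peptide", "ic50_nM", "allele"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")

    groups: dict[tuple[str, str], list[tuple[float, bool]]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        seq = str(row.peptide).strip().upper()
        try:
            validate_sequence(seq)
            ic50, thr = _parse_ic50(row.ic50_nM)
            if not ic50 > 0:
                raise ValueError(f"non-positive IC50 {ic50}")
        except (AlphabetError, ValueError) as exc:
            logger.warning("%s line %d: rejected record (%s)", path, row_no, exc)
            continue
        groups.setdefault((seq, str(row.allele)), []).append((ic50, thr))

    records = []
    for (seq, allele), measurements in groups.items():
        ic50 = statistics.median(v for v, _ in measurements)
        thresholded = all(t for _, t in measurements) and any(t for _, t in measurements)
        records.append(
            BindingRecord(
                peptide=Peptide(id=seq, sequence=seq),
                ic50_nM=ic50,
                dG_exp=ic50_nM_to_affinity(ic50, thermo),
                allele=allele,
                thresholded=thresholded,
            )
        )
    if not records:
        raise ValueError(f"{path}: no valid records after cleaning")
    alleles = {r.allele for r in records}
    return BindingDataset(records, allele=alleles.pop() if len(alleles) == 1 else "")


def write_binding_table(dataset: BindingDataset, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("peptide\tic50_nM\tallele\n")
        for r in dataset.records:
            prefix = ">" if r.thresholded else ""
            fh.write(f"{r.peptide.sequence}\t{prefix}{r.ic50_nM:.17g}\t{r.allele}\n")


def read_fasta(path: str | Path) -> list[Peptide]:
    """Read peptides from FASTA; headers become ids, sequences uppercased."""
    peptides, seen = [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        try:
            validate_sequence(seq)
        except (AlphabetError, ValueError) as exc:
            raise type(exc)(f"record {rec.id!r}: {exc}") from exc
        peptides.append(Peptide(id=rec.id, sequence=seq))
    return peptides


# ---------------------------------------------------------------------------
# Scoring matrix TSV: '#' header comments (kT, allele), positions P1..P9 as
# rows, the 20 residues as labelled columns, 17 significant digits so the
# round trip is bit-exact.

def write_matrix(
    beta: np.ndarray,
    path: str | Path,
    thermo: ThermoParams = DEFAULT_THERMO,
    allele: str = "",
) -> None:
    beta = np.asarray(beta, dtype=float)
    with Path(path).open("w") as fh:
        fh.write(f"# kT_kcal_mol\t{thermo.kT:.17g}\n")
        fh.write(f"# allele\t{allele}\n")
        fh.write("pos\t" + "\t".join(AMINO_ACIDS) + "\n")
        for i in range(beta.shape[0]):
            fh.write(f"P{i + 1}\t" + "\t".join(f"{v:.17g}" for v in beta[i]) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, ThermoParams, str]:
    """Read a scoring-matrix TSV; returns (beta, thermo, allele)."""
    kT, allele = DEFAULT_THERMO.kT, ""
    rows: list[list[float]] = []
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            fields = line[1:].strip().split("\t")
            if fields[0] == "kT_kcal_mol":
                kT = float(fields[1])
            elif fields[0] == "allele":
                allele = fields[1] if len(fields) > 1 else ""
            continue
        fields = line.split("\t")
        if header is None:
            if fields[0] != "pos" or fields[1:] != list(AMINO_ACIDS):
                raise ValueError(f"{path}: bad matrix header {fields[:3]}...")
            header = fields
            continue
        rows.append([float(v) for v in fields[1:]])
    beta = np.array(rows)
    if beta.shape != (9, 20):
        raise ValueError(f"{path}: expected 9x20 matrix, got {beta.shape}")
    return beta, ThermoParams(kT=kT), allele


# ---------------------------------------------------------------------------
# Fold files: peptide_id, sequence, fold (1..k); rows ordered by fold then id.

def write_folds(fold_of: dict[str, int], peptides: Sequence[Peptide], path: str | Path) -> None:
    seq_of = {p.id: p.sequence for p in peptides}
    with Path(path).open("w") as fh:
        fh.write("peptide_id\tsequence\tfold\n")
        for pid in sorted(fold_of, key=lambda i: (fold_of[i], i)):
            fh.write(f"{pid}\t{seq_of[pid]}\t{fold_of[pid]}\n")


def read_folds(path: str | Path, k: int | None = None) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "fold": int})
    fold_of = dict(zip(df["peptide_id"], df["fold"]))
    k_seen = max(fold_of.values())
    limit = k if k is not None else k_seen
    bad = {p: f for p, f in fold_of.items() if not 1 <= f <= limit}
    if bad:
        raise ValueError(f"{path}: fold index outside 1..{limit}: {bad}")
    return fold_of


def write_predictions(decompositions, path: str | Path) -> None:
    """Write per-peptide predictions as TSV."""
    with Path(path).open("w") as fh:
        fh.write(
            "peptide_id\tsequence\tpredicted_dG_kcal_mol\tpredicted_IC50_nM\t"
            "core_offset\tcore_sequence\tratio_top\tratio_second\n"
        )
        for d in decompositions:
            fh.write(
                f"{d.peptide_id}\t{d.sequence}\t{d.dG_total:.6g}\t"
                f"{d.predicted_ic50_nM:.6g}\t{d.M_max}\t{d.core}\t"
                f"{d.ratio_top:.6g}\t{d.ratio_second:.6g}\n"
            )


def write_fit_log(path_rows: pd.DataFrame, path: str | Path) -> None:
    """Write the regularization-path log (one row per (t, start))."""
    cols = ["t", "start", "train_mse", "validation_mse", "l1_norm", "n_nonzero", "converged"]
    path_rows.to_csv(path, sep="\t", index=False, columns=cols)
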