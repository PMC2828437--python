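"""Structurally determined peptide binding registers for class II MHC.

Eighteen peptide-MHC complexes with X-ray structures in the PDB, each with
the 9-mer core (the P1..P9 residues seen in the groove) annotated as a
0-based offset into the peptide.  Peptide sequences and core spans follow
the publications reporting the structures, not the (sometimes truncated or
alanine-substituted) coordinate files; the 1AQD core annotation in
particular differs between renderings of the source material, and the
9-mer given here (WRFLRGYHQ) is the structure paper's P1-anchored span.

The CLIP peptide binds HLA-DRB1*0301 (1A6A) and H2-IA^b (1MUJ) in the same
register, as it does for most allotypes; 1DLH and 2G9H share one entry.

These are sequence + offset fixtures for scoring register prediction; no
structure files are read.
"""

from __future__ import annotations

from typing import NamedTuple

from .alphabet import CORE_LENGTH


class StructureEntry(NamedTuple):
    allele: str
    pdb_id: str
    sequence: str
    core_offset: int

    @property
    def core(self) -> str:
        return self.sequence[self.core_offset : self.core_offset + CORE_LENGTH]


_ENTRIES: tuple[tuple[str, str, str, int], ...] = (
    ("DRB1*0101", "1AQD", "VGSDWRFLRGYHQYA", 4),
    ("DRB1*0101", "1DLH,2G9H", "PKYVKQNTLKLAT", 2),
    ("DRB1*0101", "1KLG", "GELIGILNAAKVPAD", 3),
    ("DRB1*0101", "1KLU", "GELIGTLNAAKVPAD", 3),
    ("DRB1*0101", "1SJE", "PEVIPMFSALSEGATP", 2),
    ("DRB1*0101", "1T5W", "AAYSDQATPLLLSPR", 2),
    ("DRB1*0101", "2FSE", "AGFKGEQGPKGEPG", 2),
    ("DRB1*0301", "1A6A", "LPKPPKPVSKMRMATPLLMQALPM", 10),
    ("DRB1*0401", "1J8H", "PKYVKQNTLKLAT", 2),
    ("DRB1*0401", "2SEB", "QYMRADQAAGGLR", 2),
    ("DRB1*1501", "1BX2", "ENPVVHFFKNIVTPR", 4),
    ("DRB3*0101", "2Q6W", "AWRSDEALPLGS", 1),
    ("DRB5*0101", "1FV1", "NPVVHFFKNIVTPRTPPPSQ", 6),
    ("DRB5*0101", "1H15", "GGVYHFVKKHVHES", 3),
    ("H2-IAb", "1LNU", "FEAQKAKANKAVD", 2),
    ("H2-IAb", "1MUJ", "LPKPPKPVSKMRMATPLLMQALPM", 10),
    ("H2-IAd", "1IAO", "RGISQAVHAAHAEINEAGR", 3),
    ("H2-IAd", "2IAD", "RGHNTNGVTAASSHE", 4),
)


def structural_registers() -> list[StructureEntry]:
    """The 18 structure-annotated (allele, pdb, peptide, core offset) entries."""
    return [StructureEntry(*row) for row in _ENTRIES]


def register_accuracy(beta, thermo=None) -> tuple[int, int]:
    """Score a matrix's register predictions on the structural fixtures.

    Returns (n_correct, n_total) over all 18 complexes, comparing
    ``predict_core`` against the annotated offsets.
    """
    from .model import predict_core
    from .thermo import DEFAULT_THERMO

    thermo = thermo or DEFAULT_THERMO
    entries = structural_registers()
    correct = sum(
        1 for e in entries if predict_core(beta, e.sequence, thermo)[0] == e.core_offset
    )
    return correct, len(entries)
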