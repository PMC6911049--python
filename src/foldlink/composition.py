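"""Sequence composition: average molecular masses of monomer and oligomers.

Average (not monoisotopic) residue masses are used, matching the scale on
which SEC-MALS masses are compared. The residue-mass table below is the
standard average-isotopic table (Expasy), frozen here to 0.01 Da; a
protein mass is the sum of its residue masses plus one water (18.02 Da).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
    "SequenceRecord",
    "average_mass",
    "oligomer_mass",
    "read_fasta",
]

#: Average residue (amino-acid minus water) masses, daltons.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

#: Mass of one water molecule, daltons.
WATER_MASS: float = 18.0153


@dataclass(frozen=True)
class SequenceRecord:
    """One-letter amino-acid sequence with identifier.

    Only the 20 canonical letters are accepted; a non-canonical letter is
    rejected naming its position.
    """

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        for i, c in enumerate(self.sequence):
            if c not in AVERAGE_RESIDUE_MASS:
                raise ValueError(
                    f"non-canonical residue {c!r} at position {i + 1} "
                    f"in sequence {self.identifier!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def average_mass(seq: SequenceRecord | str) -> float:
    """Average molecular mass of the polypeptide, daltons."""
    if isinstance(seq, str):
        seq = SequenceRecord("anonymous", seq)
    return sum(AVERAGE_RESIDUE_MASS[c] for c in seq.sequence) + WATER_MASS


def oligomer_mass(monomer: float, n: int) -> float:
    """Mass of an n-mer of non-covalently associated monomers (no correction)."""
    if n < 1:
        raise ValueError("oligomer count must be >= 1")
    if not monomer > 0:
        raise ValueError("monomer mass must be > 0")
    return n * monomer


def read_fasta(path) -> list[SequenceRecord]:
    """Read sequences from FASTA (canonical residues only)."""
    return [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
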