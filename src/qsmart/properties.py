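"""Physicochemical residue properties and the BLOSUM62 substitution matrix.

Residue-level mutation features quantify how a substitution perturbs the
local chemistry of a kinase: change in formal charge, polarity class,
hydrophobicity, solvent-accessible surface area, side-chain volume, and a
per-residue transfer free energy, plus the BLOSUM62 log-odds score of the
substitution itself.

The numeric scales are packaged assets and are swappable through
:class:`AminoAcidPropertyTable`; the defaults are standard published scales
(Kyte–Doolittle hydrophobicity, Tien et al. theoretical maximum ASA,
Zamyatnin side-chain volumes, Guy transfer free energies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Formal charge at physiological pH (unit charges).
_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}

# Polarity class: 1 = polar, 0 = nonpolar.
_POLAR = set("RNDCQEHKSTY")

# Kyte & Doolittle hydropathy index.
_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Theoretical maximum accessible surface area (Å²), Tien et al. 2013.
_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Side-chain volume (Å³), Zamyatnin.
_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Transfer free energy per residue (kcal/mol), Guy 1985.
_ENERGY = {
    "A": 0.10, "R": 1.91, "N": 0.48, "D": 0.78, "C": -1.42,
    "Q": 0.95, "E": 0.83, "G": 0.33, "H": -0.50, "I": -1.13,
    "L": -1.18, "K": 1.40, "M": -1.59, "F": -2.12, "P": 0.73,
    "S": 0.52, "T": 0.07, "W": -0.51, "Y": -0.21, "V": -1.27,
}

#: Property code -> human name, in the column-naming order used by
#: the residue-level feature block (``PKA_<pos>_<PROP>``).
PROPERTY_CODES = ("MUT", "CHA", "POL", "HYD", "ASA", "VOL", "ENE", "BLO")


def _load_blosum62() -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load("BLOSUM62")
    out: dict[tuple[str, str], float] = {}
    for a in CANONICAL_RESIDUES:
        for b in CANONICAL_RESIDUES:
            out[(a, b)] = float(mat[a, b])
    return out


@dataclass(frozen=True)
class AminoAcidPropertyTable:
    """Lookup table of residue properties used for mutation delta features.

    Each scalar property maps residue letter -> value; ``blosum62`` maps a
    residue pair -> substitution score.  All 20 canonical residues must be
    present; alternative scales can be supplied to the constructor.
    """

    charge: dict[str, float] = field(default_factory=lambda: {
        r: _CHARGE.get(r, 0.0) for r in CANONICAL_RESIDUES})
    polarity: dict[str, float] = field(default_factory=lambda: {
        r: (1.0 if r in _POLAR else 0.0) for r in CANONICAL_RESIDUES})
    hydrophobicity: dict[str, float] = field(default_factory=lambda: dict(_HYDROPATHY))
    asa: dict[str, float] = field(default_factory=lambda: dict(_ASA))
    volume: dict[str, float] = field(default_factory=lambda: dict(_VOLUME))
    energy: dict[str, float] = field(default_factory=lambda: dict(_ENERGY))
    blosum62: dict[tuple[str, str], float] = field(default_factory=_load_blosum62)

    def __post_init__(self) -> None:
        for name in ("charge", "polarity", "hydrophobicity", "asa",
                     "volume", "energy"):
            table = getattr(self, name)
            missing = [r for r in CANONICAL_RESIDUES if r not in table]
            if missing:
                raise ValueError(f"{name} table missing residues {missing}")
        for a in CANONICAL_RESIDUES:
            for b in CANONICAL_RESIDUES:
                if (a, b) not in self.blosum62:
                    raise ValueError(f"BLOSUM62 missing pair ({a}, {b})")
                if self.blosum62[(a, b)] != self.blosum62[(b, a)]:
                    raise ValueError("BLOSUM62 must be symmetric")

    def is_canonical(self, residue: str) -> bool:
        return residue in CANONICAL_RESIDUES

    def delta(self, prop: str, wild: str, mutant: str) -> float:
        """Property change of a substitution: value(mutant) - value(wild)."""
        table = {
            "CHA": self.charge, "POL": self.polarity,
            "HYD": self.hydrophobicity, "ASA": self.asa,
            "VOL": self.volume, "ENE": self.energy,
        }[prop]
        return table[mutant] - table[wild]

    def substitution_score(self, wild: str, mutant: str) -> float:
        return self.blosum62[(wild, mutant)]

    def as_matrix(self) -> np.ndarray:
        """20x6 array of scalar properties in CANONICAL_RESIDUES order."""
        cols = [self.charge, self.polarity, self.hydrophobicity,
                self.asa, self.volume, self.energy]
        return np.array([[c[r] for c in cols] for r in CANONICAL_RESIDUES])
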