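"""Polypeptide physico-chemical properties: average molecular weight and
isoelectric point.

MW uses average (not monoisotopic) residue masses plus one water, the
ProtParam convention.  pI solves net_charge(pH) = 0 by bisection on
[0, 14]; the net charge is a Henderson-Hasselbalch sum over ionizable
side chains (D, E, C, Y, H, K, R) and the two termini, and is strictly
decreasing in pH, so the root is unique.  The pKa set defaults to the
Bjellqvist/ExPASy values and is injectable (e.g. to swap in EMBOSS
values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["PkaTable", "molecular_weight", "net_charge", "isoelectric_point"]

# Average residue masses (Da): amino acid mass minus water.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
_X_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)


@dataclass
class PkaTable:
    """Side-chain and terminal pKa values (Bjellqvist/ExPASy defaults)."""

    side_chains: dict[str, float] = field(
        default_factory=lambda: {
            "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
            "H": 5.98, "K": 10.0, "R": 12.0,
        }
    )
    n_terminus: float = 7.5
    c_terminus: float = 3.55

    def __post_init__(self) -> None:
        for k, v in {**self.side_chains,
                     "Nterm": self.n_terminus,
                     "Cterm": self.c_terminus}.items():
            if not 0 < v < 14:
                raise ValueError(f"pKa for {k} outside (0, 14): {v}")

    @classmethod
    def from_yaml(cls, path) -> "PkaTable":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            side_chains=dict(cfg["side_chains"]),
            n_terminus=float(cfg["n_terminus"]),
            c_terminus=float(cfg["c_terminus"]),
        )


def molecular_weight(protein: str, kda: bool = True) -> float:
    """Average molecular weight of a protein; kDa by default."""
    if not protein:
        raise ValueError("empty protein sequence")
    protein = protein.upper()
    mass = WATER_MASS
    for aa in protein:
        if aa == "X":
            mass += _X_MASS
        elif aa in RESIDUE_MASS:
            mass += RESIDUE_MASS[aa]
        else:
            raise ValueError(f"unknown residue {aa!r}")
    return mass / 1000.0 if kda else mass


def net_charge(protein: str, ph: float, pka: PkaTable | None = None) -> float:
    """Net charge at the given pH (positive basic groups minus acidic)."""
    pka = pka or PkaTable()
    protein = protein.upper()

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10 ** (ph - pk))

    def neg(pk: float) -> float:
        return -1.0 / (1.0 + 10 ** (pk - ph))

    charge = pos(pka.n_terminus) + neg(pka.c_terminus)
    for aa in protein:
        pk = pka.side_chains.get(aa)
        if pk is None:
            continue
        charge += pos(pk) if aa in "HKR" else neg(pk)
    return charge


def isoelectric_point(
    protein: str, pka: PkaTable | None = None, tol: float = 1e-3
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    if not protein:
        raise ValueError("empty protein sequence")
    pka = pka or PkaTable()
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
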