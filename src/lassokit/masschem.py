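"""Monoisotopic mass arithmetic for linear and lasso-cyclized peptides.

Lasso peptides carry a macrolactam ring between the N-terminal amine and the
side-chain carboxylate of an Asp/Glu in the core, formed with loss of one
water molecule.  Intact-mass prediction therefore reduces to summing residue
masses: the cyclized monoisotopic mass of a core peptide equals its linear
peptide mass minus one water (18.010565 Da), independent of where the ring
closes.

Two charge-carrier conventions coexist in practice and both are exposed here:
precursor charge states ([M+zH]^z+) use the proton mass (1.007276 Da), while
fragment-ion m/z tables conventionally add a hydrogen atom mass (1.007825 Da);
see :mod:`lassokit.lasso_fragments`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "WATER_MASS",
    "PROTON_MASS",
    "HYDROGEN_ATOM_MASS",
    "CO_MASS",
    "RESIDUE_MASSES",
    "LassoPeptide",
    "linear_peptide_mass",
    "cyclized_mass",
    "mz",
    "neutral_from_mz",
]

#: Monoisotopic mass of H2O (Da).
WATER_MASS = 18.010565
#: Monoisotopic mass of a proton (Da); charge carrier for precursor ions.
PROTON_MASS = 1.007276
#: Monoisotopic mass of a hydrogen atom (Da); charge carrier for fragment ions.
HYDROGEN_ATOM_MASS = 1.007825
#: Monoisotopic mass of carbon monoxide (Da); a ions = b ions - CO.
CO_MASS = 27.994915

#: Monoisotopic residue (amino-acid minus water) masses, Da, to 5 decimals,
#: derived from elemental formulas and IUPAC monoisotopic atomic masses.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Residues whose side-chain carboxylate can close the macrolactam.
ACIDIC_RESIDUES = frozenset("DE")


class UnknownResidueError(ValueError):
    """Raised when a sequence contains a letter outside the residue table."""


def _residue_masses(seq: str) -> Iterator[float]:
    for pos, letter in enumerate(seq, start=1):
        try:
            yield RESIDUE_MASSES[letter]
        except KeyError:
            raise UnknownResidueError(
                f"unknown residue {letter!r} at position {pos} of {seq!r}"
            ) from None


@dataclass(frozen=True)
class LassoPeptide:
    """A core peptide with the ring-closing residue position.

    Parameters
    ----------
    core:
        Core peptide sequence (one-letter codes), length ``n``.
    ring_pos:
        1-based position ``r`` of the Asp/Glu whose side chain closes the
        macrolactam with the N-terminal amine.  Must satisfy ``2 <= r <= n``.
    provenance:
        ``"predicted"`` or ``"confirmed"``.
    """

    core: str
    ring_pos: int
    provenance: str = "predicted"

    def __post_init__(self) -> None:
        n = len(self.core)
        # validates letters as a side effect
        sum(_residue_masses(self.core))
        if not 2 <= self.ring_pos <= n:
            raise ValueError(
                f"ring position {self.ring_pos} outside 2..{n} for core of length {n}"
            )
        if self.core[self.ring_pos - 1] not in ACIDIC_RESIDUES:
            raise ValueError(
                f"residue at ring position {self.ring_pos} is "
                f"{self.core[self.ring_pos - 1]!r}, expected Asp or Glu"
            )

    @property
    def n(self) -> int:
        return len(self.core)

    def cyclized_mass(self) -> float:
        return cyclized_mass(self.core)


def linear_peptide_mass(seq: str) -> float:
    """Monoisotopic mass (Da) of the linear peptide ``seq``.

    Sum of residue masses plus one water.  Additive under concatenation:
    ``mass(AB) == mass(A) + mass(B) - WATER_MASS``.
    """
    if not seq:
        raise ValueError("empty sequence")
    return sum(_residue_masses(seq)) + WATER_MASS


def cyclized_mass(p: LassoPeptide | str) -> float:
    """Monoisotopic mass (Da) after macrolactam formation.

    One water is lost on ring closure, so the cyclized mass is simply the sum
    of residue masses.  The ring position affects fragmentation, never the
    intact mass, so a plain sequence is accepted as well as a
    :class:`LassoPeptide`.
    """
    seq = p.core if isinstance(p, LassoPeptide) else p
    return linear_peptide_mass(seq) - WATER_MASS


def mz(neutral_mass: float, z: int) -> float:
    """m/z of ``[M + zH]^z+`` for a neutral monoisotopic mass (proton carrier)."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * PROTON_MASS) / z


def neutral_from_mz(observed_mz: float, z: int) -> float:
    """Neutral monoisotopic mass from an observed m/z at charge ``z``.

    Exact inverse of :func:`mz`; round-trips to well below 1e-9 Da.
    """
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return observed_mz * z - z * PROTON_MASS
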