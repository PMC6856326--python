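"""Theoretical a/b/y fragment-ion tables for linear and lasso-cyclized peptides.

Fragment m/z values use the hydrogen-atom charge-carrier convention
(+1.007825 Da), which reproduces published fragment-ion calculators:

* ``b_k`` = sum of residues 1..k + H
* ``a_k`` = ``b_k`` - CO
* ``y_j`` = sum of the last j residues + H2O + H

For a lasso peptide with the macrolactam closed at ring position ``r``:

* a/b ions with ``k >= r`` contain the intact ring and lose one water
  (the ring correction, -18.010565 Da);
* backbone cleavages inside the ring (a/b with ``k < r``, y with
  ``j > n - r``) cannot release a fragment, and the bare macrolactam
  ``a_r``/``b_r`` is not observed either — these ions are emitted with
  ``observable=False`` rather than omitted, because their absence is
  evidence the ring-localization scorer uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import accumulate

from .masschem import (
    CO_MASS,
    HYDROGEN_ATOM_MASS,
    WATER_MASS,
    LassoPeptide,
    RESIDUE_MASSES,
    linear_peptide_mass,
    _residue_masses,
)

__all__ = ["FragmentIon", "IonTable", "linear_ion_table", "lasso_ion_table"]


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "a" | "b" | "y"
    index: int  # 1-based cleavage index (k for a/b, j for y)
    mz: float  # theoretical singly charged m/z, Da
    ring_corrected: bool = False
    observable: bool = True

    @property
    def label(self) -> str:
        return f"{self.series}{self.index}"


@dataclass(frozen=True)
class IonTable:
    """All a/b/y ions of a peptide: 3*(n-1) entries, one triplet per site."""

    peptide: str
    ring_pos: int | None  # None for a linear peptide
    ions: tuple[FragmentIon, ...]
    conventions: dict = field(
        default_factory=lambda: {
            "charge_carrier_mass": HYDROGEN_ATOM_MASS,
            "water_mass": WATER_MASS,
        },
        compare=False,
    )

    def series(self, name: str) -> list[FragmentIon]:
        return [ion for ion in self.ions if ion.series == name]

    def get(self, series: str, index: int) -> FragmentIon:
        for ion in self.ions:
            if ion.series == series and ion.index == index:
                return ion
        raise KeyError(f"{series}{index} not in table for {self.peptide!r}")

    def observable_ions(self) -> list[FragmentIon]:
        return [ion for ion in self.ions if ion.observable]


def linear_ion_table(seq: str) -> IonTable:
    """Singly charged a/b/y ions of a linear peptide; all observable."""
    if len(seq) < 2:
        raise ValueError("need at least 2 residues to fragment")
    masses = list(_residue_masses(seq))
    prefix = list(accumulate(masses))
    suffix = list(accumulate(reversed(masses)))
    ions: list[FragmentIon] = []
    n = len(seq)
    for k in range(1, n):
        b = prefix[k - 1] + HYDROGEN_ATOM_MASS
        ions.append(FragmentIon("a", k, b - CO_MASS))
        ions.append(FragmentIon("b", k, b))
    for j in range(1, n):
        ions.append(
            FragmentIon("y", j, suffix[j - 1] + WATER_MASS + HYDROGEN_ATOM_MASS)
        )
    return IonTable(peptide=seq, ring_pos=None, ions=tuple(ions))


def lasso_ion_table(p: LassoPeptide, bare_ring_observable: bool = False) -> IonTable:
    """a/b/y ion table for a lasso topology with the ring closed at ``p.ring_pos``.

    Ring-containing a/b ions (k >= r) get the -H2O ring correction.
    Observability encodes the topology: only tail-side cleavages release
    fragments, so a/b are observable for k >= r+1 and y for j <= n-r.
    ``bare_ring_observable`` lets a_r/b_r (the macrolactam itself) count as
    observable; by default they do not.
    """
    base = linear_ion_table(p.core)
    r, n = p.ring_pos, p.n
    ions: list[FragmentIon] = []
    for ion in base.ions:
        if ion.series in ("a", "b"):
            k = ion.index
            ring_corrected = k >= r
            mz = ion.mz - WATER_MASS if ring_corrected else ion.mz
            observable = k >= r + 1 or (k == r and bare_ring_observable)
            ions.append(
                FragmentIon(ion.series, k, mz, ring_corrected, observable)
            )
        else:
            observable = ion.index <= n - r
            ions.append(FragmentIon("y", ion.index, ion.mz, False, observable))
    return IonTable(peptide=p.core, ring_pos=r, ions=tuple(ions))
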