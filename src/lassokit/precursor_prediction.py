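"""Leader/core prediction for lasso peptide precursors.

A lasso precursor is an N-terminal leader followed by the 14-24 residue core
that survives maturation.  Two complementary cleavage rules are enumerated:

* **motif cleavage** — leaders carry the conserved 17-position motif
  ``YxxPx[LV]xxxGxxxxxTx`` (anchors Y1/P4/G10/T16, with the penultimate
  leader residue an invariant Thr); cleavage falls one residue past the
  motif, i.e. after motif position 17.
* **Gly start** — the historical rule that the mature core begins with Gly;
  every Gly in the C-terminal half of the precursor opens a candidate core.

Candidates are ranked motif-cleavage first, then by motif score, then by
compliance with the typical 14-24 residue core-length window (a soft
penalty, not a filter).  Each candidate carries the Asp/Glu ring-closure
candidates at core positions 7-9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .masschem import ACIDIC_RESIDUES, LassoPeptide, cyclized_mass, mz

__all__ = [
    "PrecursorRecord",
    "LeaderMotif",
    "CoreCandidate",
    "MotifMatch",
    "DEFAULT_MOTIF",
    "scan_motif",
    "enumerate_core_candidates",
    "predict_products",
]

MIN_CORE_LENGTH = 5
DEFAULT_CORE_WINDOW = (14, 24)
DEFAULT_RING_POSITIONS = (7, 8, 9)


@dataclass(frozen=True)
class PrecursorRecord:
    """A precursor peptide sequence with an identifier and a source tag."""

    id: str
    sequence: str
    source: str = "user input"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"precursor {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class LeaderMotif:
    """The conserved leader motif as anchored positions over a fixed window.

    ``anchors`` maps 1-based window position to the required residue;
    ``tolerated`` maps a window position to an accepted residue set (the only
    documented deviation is Val for Leu at position 6).
    """

    length: int = 17
    anchors: tuple[tuple[int, str], ...] = ((1, "Y"), (4, "P"), (10, "G"), (16, "T"))
    tolerated: tuple[tuple[int, frozenset[str]], ...] = ((6, frozenset("LV")),)

    def score_window(self, window: str) -> tuple[bool, int, list[int]]:
        """Return (all anchors matched, score, matched 1-based positions)."""
        matched: list[int] = []
        for pos, residue in self.anchors:
            if window[pos - 1] == residue:
                matched.append(pos)
        full = len(matched) == len(self.anchors)
        score = len(matched)
        for pos, allowed in self.tolerated:
            if window[pos - 1] in allowed:
                matched.append(pos)
                score += 1
        return full, score, sorted(matched)


DEFAULT_MOTIF = LeaderMotif()


@dataclass(frozen=True)
class MotifMatch:
    """A motif hit: 0-based window start, matched positions, score."""

    start: int
    matched_positions: tuple[int, ...]
    score: int
    window: str


@dataclass(frozen=True)
class CoreCandidate:
    """One possible leader/core split of a precursor."""

    precursor_id: str
    leader: str
    core: str
    cleavage_site: int  # 0-based: cleavage occurs after this many residues
    motif_score: int
    rule: str  # "motif-cleavage" | "gly-start"
    ring_candidates: tuple[tuple[int, str], ...]
    core_length_ok: bool

    @property
    def precursor(self) -> str:
        return self.leader + self.core


def scan_motif(
    precursor: PrecursorRecord | str, motif: LeaderMotif = DEFAULT_MOTIF
) -> list[MotifMatch]:
    """Find every window of ``precursor`` matching all motif anchors.

    Returns matches best-score first (ties broken leftmost).  The score is
    the number of matched anchor positions plus one for a tolerated
    position-6 residue, so a canonical Leu6/Val6 leader scores 5.
    """
    seq = precursor.sequence if isinstance(precursor, PrecursorRecord) else precursor
    hits: list[MotifMatch] = []
    for start in range(len(seq) - motif.length + 1):
        window = seq[start : start + motif.length]
        full, score, matched = motif.score_window(window)
        if full:
            hits.append(MotifMatch(start, tuple(matched), score, window))
    hits.sort(key=lambda m: (-m.score, m.start))
    return hits


def enumerate_core_candidates(
    precursor: PrecursorRecord | str,
    motif: LeaderMotif = DEFAULT_MOTIF,
    core_window: tuple[int, int] = DEFAULT_CORE_WINDOW,
    ring_positions: tuple[int, ...] = DEFAULT_RING_POSITIONS,
) -> list[CoreCandidate]:
    """Enumerate leader/core splits under the motif-cleavage and Gly-start rules.

    Motif-cleavage candidates cleave after motif position 17 (one residue past
    the conserved Thr).  Gly-start candidates cleave before each Gly in the
    C-terminal half.  Ranking: motif-cleavage first, then motif score, then
    core-length-window compliance, then leftmost cleavage.
    """
    if isinstance(precursor, str):
        precursor = PrecursorRecord("precursor", precursor)
    seq = precursor.sequence
    if len(seq) < motif.length + MIN_CORE_LENGTH:
        raise ValueError(
            f"precursor {precursor.id!r} too short ({len(seq)} aa) for "
            f"motif + minimum core"
        )

    def make(site: int, rule: str, score: int) -> CoreCandidate | None:
        core = seq[site:]
        if len(core) < MIN_CORE_LENGTH:
            return None
        rings = tuple(
            (p, core[p - 1])
            for p in ring_positions
            if p <= len(core) and core[p - 1] in ACIDIC_RESIDUES
        )
        return CoreCandidate(
            precursor_id=precursor.id,
            leader=seq[:site],
            core=core,
            cleavage_site=site,
            motif_score=score,
            rule=rule,
            ring_candidates=rings,
            core_length_ok=core_window[0] <= len(core) <= core_window[1],
        )

    candidates: list[CoreCandidate] = []
    seen_sites: dict[tuple[int, str], None] = {}
    for hit in scan_motif(precursor, motif):
        site = hit.start + motif.length
        cand = make(site, "motif-cleavage", hit.score)
        if cand and (site, cand.rule) not in seen_sites:
            seen_sites[(site, cand.rule)] = None
            candidates.append(cand)
    half = len(seq) // 2
    for site, letter in enumerate(seq):
        if letter == "G" and site >= half:
            cand = make(site, "gly-start", 0)
            if cand and (site, "gly-start") not in seen_sites:
                seen_sites[(site, "gly-start")] = None
                candidates.append(cand)

    candidates.sort(
        key=lambda c: (
            c.rule != "motif-cleavage",
            -c.motif_score,
            not c.core_length_ok,
            c.cleavage_site,
        )
    )
    return candidates


def predict_products(
    candidate: CoreCandidate,
) -> list[tuple[LassoPeptide, float, dict[int, float]]]:
    """Predicted mature products for each ring candidate of a core.

    Returns ``(LassoPeptide, cyclized mass Da, {z: m/z})`` per Asp/Glu ring
    candidate, sorted by ring position.  A core with no acidic residue at the
    allowed positions yields an empty list and a warning.
    """
    if not candidate.ring_candidates:
        warnings.warn(
            f"core {candidate.core!r} has no Asp/Glu ring candidate; "
            "no mature product predicted",
            stacklevel=2,
        )
        return []
    products = []
    for pos, _residue in sorted(candidate.ring_candidates):
        peptide = LassoPeptide(candidate.core, pos)
        mass = cyclized_mass(peptide)
        products.append((peptide, mass, {1: mz(mass, 1), 2: mz(mass, 2)}))
    return products
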