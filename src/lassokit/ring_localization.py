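"""Ring-residue localization from deconvoluted MS/MS peak lists.

The macrolactam blocks backbone fragmentation inside the ring, so the
fragment ladder of a lasso peptide stops at the ring: for a ring closed at
position ``r`` of an ``n``-residue core, the first observable b/a ion is
``b_{r+1}``/``a_{r+1}`` and the largest observable y ion is ``y_{n-r}``.
Localization therefore scores each candidate ring position against the
observed peaks and calls ``r`` only when the ladder endpoints agree with it
and it uniquely maximizes the evidence score:

    score(r) = (# matched observable ions) - w * (# matched ions the
               topology says should be unobservable)

Peaks are assumed deconvoluted to neutral-singly-protonated m/z, as produced
by standard charge deconvolution of high-resolution spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from pyteomics import mgf as _mgf

from .lasso_fragments import FragmentIon, IonTable, lasso_ion_table
from .masschem import ACIDIC_RESIDUES, LassoPeptide

__all__ = [
    "PeakList",
    "PeakMatch",
    "CandidateEvidence",
    "RingCallResult",
    "match_peaks",
    "infer_ring",
    "annotate_spectrum",
    "load_peaks",
]

DEFAULT_TOLERANCE_DA = 0.01


@dataclass(frozen=True)
class PeakList:
    """Deconvoluted peaks: (m/z, intensity) pairs with a matching tolerance.

    ``tolerance`` is interpreted in Da when ``tolerance_unit == "da"`` and in
    parts-per-million when ``"ppm"``.  Peaks are sorted ascending on ingestion.
    """

    peaks: tuple[tuple[float, float], ...]
    tolerance: float = DEFAULT_TOLERANCE_DA
    tolerance_unit: str = "da"
    source: str = ""

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        unit = self.tolerance_unit.lower()
        if unit not in ("da", "ppm"):
            raise ValueError(f"tolerance unit must be 'da' or 'ppm', got {unit!r}")
        object.__setattr__(self, "tolerance_unit", unit)
        if any(mz <= 0 for mz, _ in self.peaks):
            raise ValueError("peak m/z values must be positive")
        object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))

    def tolerance_at(self, mz: float) -> float:
        if self.tolerance_unit == "ppm":
            return mz * self.tolerance * 1e-6
        return self.tolerance

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class PeakMatch:
    ion: FragmentIon
    peak_mz: float
    peak_intensity: float
    delta: float  # observed - theoretical, Da (signed)


def load_peaks(
    path: str | Path,
    tolerance: float = DEFAULT_TOLERANCE_DA,
    tolerance_unit: str = "da",
) -> PeakList:
    """Read a peak list from MGF or two-column (m/z, intensity) text.

    MGF spectra must already be deconvoluted: a declared charge above 1 is
    rejected with instructions rather than silently misinterpreted.
    """
    path = Path(path)
    peaks: list[tuple[float, float]] = []
    if path.suffix.lower() == ".mgf":
        with _mgf.read(str(path)) as reader:
            for spectrum in reader:
                charges = spectrum.get("params", {}).get("charge", [])
                if any(int(c) > 1 for c in charges):
                    raise ValueError(
                        f"{path}: spectrum declares charge > 1; this reader "
                        "expects spectra deconvoluted to singly-protonated "
                        "masses — deconvolute first"
                    )
                peaks.extend(
                    zip(
                        (float(x) for x in spectrum["m/z array"]),
                        (float(x) for x in spectrum["intensity array"]),
                    )
                )
    else:
        for line_no, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 'm/z intensity'")
            peaks.append((float(parts[0]), float(parts[1])))
    return PeakList(tuple(peaks), tolerance, tolerance_unit, source=str(path))


def match_peaks(table: IonTable, peaks: PeakList) -> list[PeakMatch]:
    """Greedy nearest matching of theoretical ions to observed peaks.

    Candidate (ion, peak) pairs within tolerance are assigned smallest
    |delta| first; each peak matches at most one ion and vice versa.  Ties
    are broken deterministically by ion order then peak order.
    """
    pairs: list[tuple[float, int, int]] = []
    for i, ion in enumerate(table.ions):
        tol = peaks.tolerance_at(ion.mz)
        for j, (mz, _intensity) in enumerate(peaks.peaks):
            if abs(mz - ion.mz) <= tol:
                pairs.append((abs(mz - ion.mz), i, j))
    pairs.sort()
    used_ions: set[int] = set()
    used_peaks: set[int] = set()
    matches: list[PeakMatch] = []
    for _delta, i, j in pairs:
        if i in used_ions or j in used_peaks:
            continue
        used_ions.add(i)
        used_peaks.add(j)
        ion = table.ions[i]
        mz, intensity = peaks.peaks[j]
        matches.append(PeakMatch(ion, mz, intensity, mz - ion.mz))
    matches.sort(key=lambda m: (m.ion.series, m.ion.index))
    return matches


@dataclass(frozen=True)
class CandidateEvidence:
    """Per-candidate summary of the matched fragment evidence."""

    ring_pos: int
    matched_observable: int
    matched_unobservable: int
    first_ab_index: int | None  # smallest matched a-or-b index
    largest_y_index: int | None
    score: float
    ladder_consistent: bool
    matches: tuple[PeakMatch, ...] = field(repr=False)


@dataclass(frozen=True)
class RingCallResult:
    core: str
    verdict: str  # "called" | "ambiguous" | "no-call"
    ring_pos: int | None
    evidence: tuple[CandidateEvidence, ...]
    notes: tuple[str, ...] = ()


def _evaluate_candidate(
    core: str, r: int, peaks: PeakList, penalty_weight: float
) -> CandidateEvidence:
    # two-pass matching: observable ions claim peaks first, and only peaks no
    # observable ion explains may count as negative (forbidden-ion) evidence —
    # otherwise a near-isobar (e.g. linear b5 vs y4) would turn positive
    # evidence into a penalty
    table = lasso_ion_table(LassoPeptide(core, r))
    obs_table = IonTable(table.peptide, table.ring_pos, tuple(table.observable_ions()))
    observable = match_peaks(obs_table, peaks)
    claimed = {m.peak_mz for m in observable}
    rest = PeakList(
        tuple(p for p in peaks.peaks if p[0] not in claimed),
        peaks.tolerance,
        peaks.tolerance_unit,
        peaks.source,
    ) if len(peaks) else peaks
    forb_table = IonTable(
        table.peptide, table.ring_pos,
        tuple(i for i in table.ions if not i.observable),
    )
    unobservable = match_peaks(forb_table, rest)
    matches = sorted(
        observable + unobservable, key=lambda m: (m.ion.series, m.ion.index)
    )
    # ladder endpoints consider every matched ion, observable or not: a peak
    # matching an ion the candidate topology forbids breaks that candidate's
    # ladder just as decisively as a missing diagnostic ion
    ab = sorted(m.ion.index for m in matches if m.ion.series in "ab")
    ys = sorted(m.ion.index for m in matches if m.ion.series == "y")
    first_ab = ab[0] if ab else None
    largest_y = ys[-1] if ys else None
    n = len(core)
    consistent = first_ab == r + 1 and largest_y == n - r
    score = len(observable) - penalty_weight * len(unobservable)
    return CandidateEvidence(
        ring_pos=r,
        matched_observable=len(observable),
        matched_unobservable=len(unobservable),
        first_ab_index=first_ab,
        largest_y_index=largest_y,
        score=score,
        ladder_consistent=consistent,
        matches=tuple(matches),
    )


def infer_ring(
    core: str,
    candidates: tuple[int, ...] | list[int],
    peaks: PeakList,
    penalty_weight: float = 1.0,
) -> RingCallResult:
    """Infer the macrolactam ring position from observed fragment peaks.

    A candidate ``r`` is called only when (a) the first matched a-or-b index
    is ``r+1``, (b) the largest matched y index is ``n-r`` and (c) ``r``
    uniquely maximizes the evidence score.  Conflicting or absent evidence
    yields ``"ambiguous"`` or ``"no-call"`` — never a guess.
    """
    if not candidates:
        raise ValueError("no ring candidates supplied")
    for r in candidates:
        if not 1 <= r <= len(core) or core[r - 1] not in ACIDIC_RESIDUES:
            raise ValueError(
                f"candidate position {r} of {core!r} is not an Asp/Glu residue"
            )
    evidence = tuple(
        _evaluate_candidate(core, r, peaks, penalty_weight)
        for r in sorted(candidates)
    )
    notes: list[str] = []
    if all(ev.matched_observable == 0 and ev.matched_unobservable == 0 for ev in evidence):
        return RingCallResult(core, "no-call", None, evidence, ("no peaks matched any candidate's ions",))

    best = max(ev.score for ev in evidence)
    top = [ev for ev in evidence if ev.score == best]
    consistent = [ev for ev in evidence if ev.ladder_consistent]
    for ev in evidence:
        notes.append(
            f"r={ev.ring_pos}: {ev.matched_observable} observable matched, "
            f"{ev.matched_unobservable} forbidden matched, first a/b="
            f"{ev.first_ab_index}, last y={ev.largest_y_index}, "
            f"score={ev.score:g}"
        )
    # the ladder endpoints (first matched a/b = r+1, last matched y = n-r)
    # pin down r, so at most one candidate can be consistent; it is called
    # iff no other candidate out-scores it
    if len(consistent) == 1 and consistent[0].score >= best:
        ev = consistent[0]
        notes.append(
            f"called r={ev.ring_pos}: fragment ladder endpoints match and no "
            "other candidate scores higher"
        )
        return RingCallResult(core, "called", ev.ring_pos, evidence, tuple(notes))
    if not consistent:
        notes.append("no candidate's ladder endpoints are consistent")
        return RingCallResult(core, "no-call", None, evidence, tuple(notes))
    notes.append("evidence does not single out one candidate")
    return RingCallResult(core, "ambiguous", None, evidence, tuple(notes))


@dataclass(frozen=True)
class SpectrumAnnotation:
    core: str
    ring_pos: int
    rows: tuple[dict, ...]  # one per ion: series, index, mz, observable, detected, ...
    tail_sites_covered: int  # cleavage sites outside the ring with any ion detected
    tail_sites_total: int
    unmatched_peaks: tuple[tuple[float, float], ...]


def annotate_spectrum(core: str, r: int, peaks: PeakList) -> SpectrumAnnotation:
    """Annotate a peak list against the theoretical table for ring position ``r``.

    Produces one row per theoretical ion with a detected flag and the matched
    peak, plus tail sequence-coverage (cleavage sites C-terminal of the ring
    with at least one detected ion) and the list of unmatched major peaks.
    """
    table = lasso_ion_table(LassoPeptide(core, r))
    matches = match_peaks(table, peaks)
    by_ion = {(m.ion.series, m.ion.index): m for m in matches}
    rows = []
    for ion in table.ions:
        m = by_ion.get((ion.series, ion.index))
        rows.append(
            {
                "series": ion.series,
                "index": ion.index,
                "mz": round(ion.mz, 4),
                "ring_corrected": ion.ring_corrected,
                "observable": ion.observable,
                "detected": m is not None,
                "observed_mz": round(m.peak_mz, 4) if m else None,
                "delta": round(m.delta, 4) if m else None,
            }
        )
    n = len(core)
    # tail cleavage sites: between residues i and i+1 for i = r..n-1, i.e. the
    # n-r sites whose b_{i} (i>r) or y_{n-i} ions are observable
    covered = 0
    for site in range(r, n):
        detected_here = any(
            row["detected"]
            and (
                (row["series"] in "ab" and row["index"] == site)
                or (row["series"] == "y" and row["index"] == n - site)
            )
            for row in rows
        )
        if detected_here:
            covered += 1
    matched_mzs = {m.peak_mz for m in matches}
    unmatched = tuple(p for p in peaks.peaks if p[0] not in matched_mzs)
    return SpectrumAnnotation(
        core=core,
        ring_pos=r,
        rows=tuple(rows),
        tail_sites_covered=covered,
        tail_sites_total=n - r,
        unmatched_peaks=unmatched,
    )
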