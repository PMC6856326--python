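"""Seeded synthetic inputs for every pipeline stage.

Three generators emulate the data a lasso peptide discovery campaign
consumes, with full ground truth attached so recovery can be tested without
any downloads:

* :func:`gen_precursor` — precursor peptides whose leaders carry one
  instance of the conserved ``YxxPx[LV]xxxGxxxxxTx`` motif and whose cores
  hide a single Asp/Glu ring residue at position 7, 8 or 9;
* :func:`gen_cluster_genome` — a high-GC bacterial contig with a compact
  planted lasso BGC (cyclase/RRE/peptidase, the precursor gene, optional
  ABC transporters) back-translated with GC-biased codon choice and small
  intergenic gaps;
* :func:`gen_spectrum` — deconvoluted lasso MS/MS peak lists in which only
  topology-observable ions appear, with configurable mass jitter, per-series
  ion dropout and uniform noise peaks.

Everything is driven by a single integer seed; the same seed reproduces the
same artifacts byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .bgc_mining import ReferenceSet, load_reference_set
from .lasso_fragments import lasso_ion_table
from .masschem import ACIDIC_RESIDUES, LassoPeptide
from .precursor_prediction import (
    DEFAULT_MOTIF,
    PrecursorRecord,
    enumerate_core_candidates,
    scan_motif,
)
from .ring_localization import PeakList

__all__ = [
    "SimulationSpec",
    "LEEPEPTIN_PRECURSOR",
    "LEEPEPTIN_LEADER",
    "LEEPEPTIN_CORE",
    "LEEPEPTIN_RING",
    "gen_precursor",
    "gen_core",
    "gen_cluster_genome",
    "gen_spectrum",
    "mutate_peptide",
]

# The leepeptin precursor and its confirmed maturation (Glu8-cyclized core),
# used as the default template for template-based generation.
LEEPEPTIN_LEADER = "MEHDEKTPYETPAVYGLGAFAEETG"
LEEPEPTIN_CORE = "LYGVRNDEEINWHFDYWT"
LEEPEPTIN_PRECURSOR = LEEPEPTIN_LEADER + LEEPEPTIN_CORE
LEEPEPTIN_RING = 8

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# Background residue frequencies loosely following high-GC actinobacterial
# proteomes (Ala/Gly/Pro/Arg-rich); exact values are a documented placeholder.
_BACKGROUND = {
    "A": 0.12, "C": 0.01, "D": 0.06, "E": 0.06, "F": 0.03, "G": 0.09,
    "H": 0.02, "I": 0.03, "K": 0.02, "L": 0.10, "N": 0.02, "P": 0.06,
    "Q": 0.03, "R": 0.08, "S": 0.06, "T": 0.06, "V": 0.08, "W": 0.02,
    "Y": 0.02, "M": 0.03,
}
_BG_LETTERS = np.array(list(_BACKGROUND))
_BG_PROBS = np.array(list(_BACKGROUND.values()))
_BG_PROBS = _BG_PROBS / _BG_PROBS.sum()


@dataclass(frozen=True)
class SimulationSpec:
    """All knobs for the three generators; the seed fixes every draw.

    ``cluster_layout`` is an ordered tuple of role letters per the compact
    cluster architectures seen in lasso BGCs: C (cyclase), E (RRE),
    B (peptidase), A (precursor), D/F (ABC transporters).
    """

    seed: int = 0
    gc_content: float = 0.72
    cluster_layout: tuple[str, ...] = ("C", "E", "B", "A", "D", "F")
    intergenic_gap_bp: tuple[int, int] = (20, 120)
    flank_bp: int = 1500
    total_length: int | None = None
    precursor_template: str | None = None
    template_split: int | None = None
    template_ring: int | None = None
    mutation_rate: float = 0.0
    protein_mutation_rate: float = 0.3
    precursor_strand: str = "+"
    # spectrum parameters
    dropout: float | dict[str, float] = 0.0
    noise_peaks: int = 0
    noise_mz_range: tuple[float, float] = (100.0, 2500.0)
    noise_intensity_mu: float = 5.0
    noise_intensity_sigma: float = 1.0
    true_intensity_floor: float = 1e3
    true_intensity_ceiling: float = 1e5
    jitter_sd: float = 0.002

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        drops = (
            self.dropout.values() if isinstance(self.dropout, dict) else [self.dropout]
        )
        if any(not 0.0 <= d <= 1.0 for d in drops):
            raise ValueError("dropout must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _draw_background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BG_LETTERS, size=n, p=_BG_PROBS))


def mutate_peptide(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    preserve: frozenset[int] = frozenset(),
) -> str:
    """Substitute each position with probability ``rate`` (never to itself).

    0-based positions in ``preserve`` are left untouched.
    """
    out = list(seq)
    for i, letter in enumerate(out):
        if i in preserve or rng.random() >= rate:
            continue
        choices = [a for a in AMINO_ACIDS if a != letter]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def gen_core(rng: np.random.Generator) -> tuple[str, int]:
    """A random core of length 14-24, Gly-initial, with one ring Asp/Glu.

    Exactly one acidic residue is placed among positions 7-9 (the ring
    residue); the rest of those positions are non-acidic so the ring ground
    truth is unambiguous.
    """
    n = int(rng.integers(14, 25))
    ring = int(rng.integers(7, 10))
    residues = ["G"] + list(_draw_background(rng, n - 1))
    non_acidic = [a for a in AMINO_ACIDS if a not in ACIDIC_RESIDUES]
    for pos in (7, 8, 9):
        if pos == ring:
            residues[pos - 1] = "D" if rng.random() < 0.5 else "E"
        elif residues[pos - 1] in ACIDIC_RESIDUES:
            residues[pos - 1] = non_acidic[rng.integers(len(non_acidic))]
    return "".join(residues), ring


def _gen_motif_window(rng: np.random.Generator) -> str:
    window = list(_draw_background(rng, DEFAULT_MOTIF.length))
    for pos, residue in DEFAULT_MOTIF.anchors:
        window[pos - 1] = residue
    for pos, allowed in DEFAULT_MOTIF.tolerated:
        window[pos - 1] = sorted(allowed)[rng.integers(len(allowed))]
    return "".join(window)


def gen_precursor(
    spec: SimulationSpec,
) -> tuple[PrecursorRecord, dict]:
    """A precursor with one leader-motif instance; ground truth attached.

    With a ``precursor_template`` the template is returned mutated at
    ``mutation_rate`` (rate 0 gives the exact template string); otherwise a
    random leader (Met-initial prefix + one motif window) is joined to a
    :func:`gen_core` core.  De novo precursors are rejection-sampled until
    the motif-cleavage rule recovers the planted core, so the ground truth
    is consistent by construction.
    """
    rng = spec.rng()
    if spec.precursor_template is not None:
        split = spec.template_split
        if split is None:
            raise ValueError("template_split required with precursor_template")
        motif_positions = {
            spec.template_split - DEFAULT_MOTIF.length + i for i in range(DEFAULT_MOTIF.length)
        }
        seq = mutate_peptide(
            spec.precursor_template,
            spec.mutation_rate,
            rng,
            preserve=frozenset(motif_positions),
        )
        leader, core = seq[:split], seq[split:]
        truth = {
            "leader": leader,
            "core": core,
            "ring_pos": spec.template_ring,
            "template": spec.precursor_template,
        }
        return PrecursorRecord("synthetic_precursor", seq, "synthetic"), truth

    for _attempt in range(200):
        prefix = "M" + _draw_background(rng, int(rng.integers(3, 8)))
        leader = prefix + _gen_motif_window(rng)
        core, ring = gen_core(rng)
        seq = leader + core
        rec = PrecursorRecord("synthetic_precursor", seq, "synthetic")
        hits = scan_motif(rec)
        if len(hits) != 1:
            continue
        top = enumerate_core_candidates(rec)[0]
        if top.core == core:
            truth = {"leader": leader, "core": core, "ring_pos": ring}
            return rec, truth
    raise RuntimeError("failed to generate a self-consistent precursor")


# ---------------------------------------------------------------------------
# genome generation

_ROLE_BY_LETTER = {
    "C": "cyclase",
    "E": "rre",
    "B": "peptidase",
    "A": "precursor",
    "D": "transporter",
    "F": "transporter",
}


def _codon_weights(gc_content: float) -> dict[str, list[tuple[str, float]]]:
    table = unambiguous_dna_by_id[11]
    by_aa: dict[str, list[tuple[str, float]]] = {}
    p = {"G": gc_content / 2, "C": gc_content / 2, "A": (1 - gc_content) / 2, "T": (1 - gc_content) / 2}
    for codon, aa in table.forward_table.items():
        w = p[codon[0]] * p[codon[1]] * p[codon[2]]
        by_aa.setdefault(aa, []).append((codon, w))
    for aa, options in by_aa.items():
        total = sum(w for _, w in options)
        by_aa[aa] = [(c, w / total) for c, w in options]
    return by_aa


def _back_translate(
    protein: str, weights: dict[str, list[tuple[str, float]]], rng: np.random.Generator
) -> str:
    codons = []
    for aa in protein:
        options = weights[aa]
        u = rng.random()
        acc = 0.0
        for codon, w in options:
            acc += w
            if u <= acc:
                codons.append(codon)
                break
        else:
            codons.append(options[-1][0])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    bases = np.array(list("GCAT"))
    probs = np.array([gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    return "".join(rng.choice(bases, size=n, p=probs))


def gen_cluster_genome(
    spec: SimulationSpec, references: ReferenceSet | None = None
) -> tuple[SeqRecord, dict]:
    """A contig with one planted lasso BGC, annotation, and ground truth.

    Role proteins come from the bundled reference exemplars, mutated at
    ``protein_mutation_rate`` so homology search is exercised non-trivially;
    the precursor gene is a :func:`gen_precursor` product.  All coding
    sequences are back-translated with GC-biased codon choice and joined
    with short intergenic spacers, then embedded in random flanking DNA (or
    padded to ``total_length``).
    """
    if "C" not in spec.cluster_layout:
        raise ValueError("cluster layout must contain a cyclase (C) gene")
    if references is None:
        references = load_reference_set()
    rng = spec.rng()
    weights = _codon_weights(spec.gc_content)
    precursor, prec_truth = gen_precursor(spec)

    role_pool = {
        role: [seq for _rid, seq in references.by_role(role)]
        for role in ("cyclase", "rre", "peptidase", "transporter")
    }
    transporter_cursor = 0
    stop_codon = "TGA"  # GC-richest stop; table 11

    parts: list[str] = []
    features: list[dict] = []
    pos = spec.flank_bp
    parts.append(_random_dna(rng, spec.flank_bp, spec.gc_content))
    for i, letter in enumerate(spec.cluster_layout):
        role = _ROLE_BY_LETTER.get(letter)
        if role is None:
            raise ValueError(f"unknown cluster layout letter {letter!r}")
        if role == "precursor":
            protein = precursor.sequence
        elif role == "transporter":
            pool = role_pool[role]
            template = pool[transporter_cursor % len(pool)]
            transporter_cursor += 1
            protein = mutate_peptide(template, spec.protein_mutation_rate, rng)
        else:
            protein = mutate_peptide(
                role_pool[role][0], spec.protein_mutation_rate, rng
            )
        cds = _back_translate(protein, weights, rng) + stop_codon
        strand = "+"
        if role == "precursor" and spec.precursor_strand == "-":
            cds = str(Seq(cds).reverse_complement())
            strand = "-"
        features.append(
            {
                "locus_tag": f"gene_{i}_{letter}",
                "role": role,
                "start": pos,
                "end": pos + len(cds),
                "strand": strand,
                "protein": protein,
            }
        )
        parts.append(cds)
        pos += len(cds)
        if i < len(spec.cluster_layout) - 1:
            gap = int(rng.integers(spec.intergenic_gap_bp[0], spec.intergenic_gap_bp[1] + 1))
            parts.append(_random_dna(rng, gap, spec.gc_content))
            pos += gap
    cluster_end = pos
    tail = spec.flank_bp
    if spec.total_length is not None:
        tail = max(tail, spec.total_length - pos)
    parts.append(_random_dna(rng, tail, spec.gc_content))
    dna = "".join(parts)

    record = SeqRecord(
        Seq(dna),
        id=f"synthetic_contig_seed{spec.seed}",
        name="synthetic",
        description="synthetic high-GC contig with one planted lasso BGC",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    for f in features:
        strand = 1 if f["strand"] == "+" else -1
        feat = SeqFeature(
            FeatureLocation(f["start"], f["end"], strand=strand),
            type="CDS",
            qualifiers={
                "locus_tag": [f["locus_tag"]],
                "product": [f["role"]],
                "transl_table": ["11"],
                "translation": [f["protein"]],
            },
        )
        record.features.append(feat)

    truth = {
        "seed": spec.seed,
        "gc_content": spec.gc_content,
        "layout": list(spec.cluster_layout),
        "cluster_span": [spec.flank_bp, cluster_end],
        "genes": [
            {k: f[k] for k in ("locus_tag", "role", "start", "end", "strand")}
            for f in features
        ],
        "transporter_count": sum(1 for f in features if f["role"] == "transporter"),
        "precursor": prec_truth | {"sequence": precursor.sequence, "strand": spec.precursor_strand},
    }
    return record, truth


# ---------------------------------------------------------------------------
# spectrum generation


def gen_spectrum(
    core: str, ring_pos: int, spec: SimulationSpec
) -> tuple[PeakList, dict]:
    """A deconvoluted lasso MS/MS peak list for ``core`` ring-closed at ``ring_pos``.

    All topology-observable a/b/y ions are emitted (ring-internal ions
    never), each jittered by a Gaussian of sd ``jitter_sd`` Da and dropped
    with probability ``dropout`` (a scalar, or a per-series dict like
    ``{"a": 0.1, "b": 0.1, "y": 0}``); ``noise_peaks`` uniform-m/z peaks
    with log-normal intensities are added.  Ground truth lists emitted,
    dropped and noise peaks.
    """
    rng = spec.rng()
    table = lasso_ion_table(LassoPeptide(core, ring_pos))
    emitted, dropped = [], []
    peaks: list[tuple[float, float]] = []
    for ion in table.observable_ions():
        rate = (
            spec.dropout.get(ion.series, 0.0)
            if isinstance(spec.dropout, dict)
            else spec.dropout
        )
        if rng.random() < rate:
            dropped.append(ion.label)
            continue
        mz = ion.mz + (rng.normal(0.0, spec.jitter_sd) if spec.jitter_sd > 0 else 0.0)
        intensity = float(
            rng.uniform(spec.true_intensity_floor, spec.true_intensity_ceiling)
        )
        peaks.append((mz, intensity))
        emitted.append(ion.label)
    noise = []
    for _ in range(spec.noise_peaks):
        mz = float(rng.uniform(*spec.noise_mz_range))
        intensity = float(
            rng.lognormal(spec.noise_intensity_mu, spec.noise_intensity_sigma)
        )
        peaks.append((mz, intensity))
        noise.append(mz)
    truth = {
        "core": core,
        "ring_pos": ring_pos,
        "emitted": emitted,
        "dropped": dropped,
        "noise_mz": noise,
        "seed": spec.seed,
    }
    return (
        PeakList(tuple(peaks), source=f"synthetic seed={spec.seed}"),
        truth,
    )


# ---------------------------------------------------------------------------
# file emission (used by the CLI)


def write_spectrum_mgf(peaks: PeakList, path: str | Path, title: str = "synthetic") -> None:
    lines = ["BEGIN IONS", f"TITLE={title}"]
    lines += [f"{mz:.5f} {intensity:.2f}" for mz, intensity in peaks.peaks]
    lines.append("END IONS")
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def write_genome(record: SeqRecord, path: str | Path) -> None:
    SeqIO.write([record], str(path), "genbank")
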