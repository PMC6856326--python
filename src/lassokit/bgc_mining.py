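"""Lasso peptide BGC mining by cyclase homology and neighborhood context.

The mining strategy mirrors how compact lasso clusters are found in practice:
seed on local-alignment homology to a lasso cyclase (C-protein) exemplar,
then inspect the genomic neighborhood for the leader peptidase (B), the RiPP
recognition element (E), optional ABC transporters, and short precursor ORFs
whose leaders carry the conserved motif.  A cluster is complete when B, C
and E are all present; transporters are optional (clusters without any
transporter gene exist).

Similarity search is Smith-Waterman local alignment with BLOSUM62 and affine
gaps (open 10, extend 0.5; a gap of length L costs open + (L-1)*extend),
executed by Biopython's PairwiseAligner.  Scores are reported raw and
normalized by the query's self-alignment score.  Reference exemplars for the
C/B/E/transporter roles are bundled as a synthetic FASTA (see
``data/synthetic_references.fasta``); no network access is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .precursor_prediction import (
    DEFAULT_MOTIF,
    LeaderMotif,
    MotifMatch,
    PrecursorRecord,
    scan_motif,
)

__all__ = [
    "ProteinRecord",
    "AlignmentResult",
    "ClusterCandidate",
    "OrfHit",
    "ReferenceSet",
    "smith_waterman",
    "find_seed_hits",
    "assemble_cluster",
    "find_precursor_orfs",
    "mine_genome",
    "load_reference_set",
]

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5
DEFAULT_NORM_THRESHOLD = 0.3
DEFAULT_WINDOW_GENES = 8
DEFAULT_WINDOW_BP = 10_000
SUBSTANTIAL_GAP_BP = 500
ORF_MIN_AA = 25
ORF_MAX_AA = 70
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with optional genomic coordinates (0-based half-open)."""

    id: str
    sequence: str
    contig: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None  # "+" | "-"
    role: str = "other"

    @property
    def has_coordinates(self) -> bool:
        return self.contig is not None and self.start is not None and self.end is not None


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    percent_identity: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    normalized_score: float


@dataclass(frozen=True)
class SeedHit:
    protein: ProteinRecord
    role: str
    reference_id: str
    alignment: AlignmentResult


@dataclass(frozen=True)
class ClusterCandidate:
    contig: str
    start: int
    end: int
    seed: SeedHit
    members: tuple[ProteinRecord, ...]
    max_intergenic_gap: int
    has_substantial_gap: bool
    transporter_count: int
    has_peptidase_b: bool
    has_cyclase_c: bool
    has_rre_e: bool
    precursor_orfs: tuple["OrfHit", ...] = ()

    @property
    def complete(self) -> bool:
        return self.has_peptidase_b and self.has_cyclase_c and self.has_rre_e


def _make_aligner(matrix: str | object, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    if isinstance(matrix, str):
        matrix = substitution_matrices.load(matrix)
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _check_letters(seq: str, alphabet: frozenset[str]) -> None:
    bad = [(i + 1, c) for i, c in enumerate(seq) if c not in alphabet]
    if bad:
        pos, c = bad[0]
        raise ValueError(f"letter {c!r} at position {pos} not covered by the scoring matrix")


def smith_waterman(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal local alignment of two protein sequences under affine gaps.

    The normalized score divides by the self-alignment score of ``a`` (the
    query), so an exact full-length copy of the query scores 1.0.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    mat = substitution_matrices.load(matrix)
    alphabet = frozenset(str(mat.alphabet))
    _check_letters(a, alphabet)
    _check_letters(b, alphabet)
    aligner = _make_aligner(mat, gap_open, gap_extend)
    self_score = aligner.score(a, a)
    score = aligner.score(a, b)
    if score <= 0:
        return AlignmentResult(0.0, 0.0, (0, 0), (0, 0), 0.0)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    qspan = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    tspan = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    return AlignmentResult(
        score=float(score),
        percent_identity=identity,
        query_span=qspan,
        target_span=tspan,
        normalized_score=float(score) / float(self_score),
    )


# ---------------------------------------------------------------------------
# reference exemplars


@dataclass(frozen=True)
class ReferenceSet:
    """Role-labelled protein exemplars used to seed and annotate clusters."""

    references: tuple[tuple[str, str, str], ...]  # (id, role, sequence)

    def by_role(self, role: str) -> list[tuple[str, str]]:
        return [(rid, seq) for rid, r, seq in self.references if r == role]

    @property
    def roles(self) -> set[str]:
        return {r for _, r, _ in self.references}


def load_reference_set(path: str | Path | None = None) -> ReferenceSet:
    """Load the bundled (or a user-supplied) role-annotated reference FASTA.

    Headers carry a ``role=`` token: cyclase, peptidase, rre or transporter.
    """
    if path is None:
        ref = resources.files("lassokit") / "data" / "synthetic_references.fasta"
        with resources.as_file(ref) as p:
            return load_reference_set(p)
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        role = "other"
        for token in rec.description.split():
            if token.startswith("role="):
                role = token.split("=", 1)[1]
        refs.append((rec.id, role, str(rec.seq)))
    if not any(r == "cyclase" for _, r, _ in refs):
        raise ValueError(f"reference set {path} contains no cyclase exemplar")
    return ReferenceSet(tuple(refs))


def find_seed_hits(
    proteome: list[ProteinRecord],
    references: ReferenceSet,
    roles: tuple[str, ...] = ("cyclase",),
    threshold: float = DEFAULT_NORM_THRESHOLD,
    **align_kwargs,
) -> list[SeedHit]:
    """Proteins similar to any reference of the requested roles.

    Each protein is aligned against every reference exemplar; hits with
    normalized score >= ``threshold`` are labelled with the best reference's
    role and returned sorted by normalized score, descending.
    """
    hits: list[SeedHit] = []
    for protein in proteome:
        best: SeedHit | None = None
        for rid, role, rseq in references.references:
            if role not in roles:
                continue
            aln = smith_waterman(rseq, protein.sequence, **align_kwargs)
            if aln.normalized_score >= threshold and (
                best is None or aln.normalized_score > best.alignment.normalized_score
            ):
                best = SeedHit(replace(protein, role=role), role, rid, aln)
        if best is not None:
            hits.append(best)
    hits.sort(key=lambda h: -h.alignment.normalized_score)
    return hits


def assign_role(
    protein: ProteinRecord,
    references: ReferenceSet,
    threshold: float = DEFAULT_NORM_THRESHOLD,
    **align_kwargs,
) -> tuple[str, AlignmentResult | None]:
    """Best-matching reference role for a protein, or ("other", None)."""
    best_role, best_aln = "other", None
    for _rid, role, rseq in references.references:
        aln = smith_waterman(rseq, protein.sequence, **align_kwargs)
        if aln.normalized_score >= threshold and (
            best_aln is None or aln.normalized_score > best_aln.normalized_score
        ):
            best_role, best_aln = role, aln
    return best_role, best_aln


def assemble_cluster(
    hit: SeedHit,
    annotations: list[ProteinRecord],
    references: ReferenceSet | None = None,
    window_genes: int = DEFAULT_WINDOW_GENES,
    window_bp: int = DEFAULT_WINDOW_BP,
    threshold: float = DEFAULT_NORM_THRESHOLD,
) -> ClusterCandidate:
    """Gather the genomic neighborhood of a cyclase seed into a candidate.

    Neighbors within +-``window_genes`` genes AND +-``window_bp`` bp of the
    seed are kept (the tighter constraint wins), roles are assigned by
    similarity to the reference exemplars, and completeness (B+C+E) and the
    maximum intergenic gap are computed.
    """
    if not hit.protein.has_coordinates:
        raise ValueError(
            "seed hit carries no genomic coordinates; use proteome-only mode "
            "(find_seed_hits) for FASTA input without annotation"
        )
    if references is None:
        references = load_reference_set()
    contig = hit.protein.contig
    neighbors = sorted(
        (p for p in annotations if p.contig == contig and p.has_coordinates),
        key=lambda p: (p.start, p.end, p.id),
    )
    seed_idx = next(
        i for i, p in enumerate(neighbors)
        if (p.start, p.end, p.id) == (hit.protein.start, hit.protein.end, hit.protein.id)
    )
    seed = neighbors[seed_idx]
    members: list[ProteinRecord] = []
    for i, p in enumerate(neighbors):
        if abs(i - seed_idx) > window_genes:
            continue
        if p.start >= seed.end + window_bp or p.end <= seed.start - window_bp:
            continue
        if i == seed_idx:
            members.append(replace(p, role="cyclase"))
        else:
            role, _aln = assign_role(p, references, threshold)
            members.append(replace(p, role=role))
    members.sort(key=lambda p: p.start)
    gaps = [
        max(0, nxt.start - prev.end)
        for prev, nxt in zip(members, members[1:])
    ]
    max_gap = max(gaps, default=0)
    roles = {m.role for m in members}
    return ClusterCandidate(
        contig=contig,
        start=members[0].start,
        end=members[-1].end,
        seed=hit,
        members=tuple(members),
        max_intergenic_gap=max_gap,
        has_substantial_gap=max_gap > SUBSTANTIAL_GAP_BP,
        transporter_count=sum(m.role == "transporter" for m in members),
        has_peptidase_b="peptidase" in roles,
        has_cyclase_c="cyclase" in roles,
        has_rre_e="rre" in roles,
    )


# ---------------------------------------------------------------------------
# precursor ORF discovery


@dataclass(frozen=True)
class OrfHit:
    """A short ORF with coordinates, translation and leader-motif evidence."""

    record: PrecursorRecord
    contig: str
    start: int  # 0-based half-open on the forward strand
    end: int
    strand: str
    motif_hits: tuple[MotifMatch, ...]

    @property
    def is_candidate_precursor(self) -> bool:
        return bool(self.motif_hits)


def _scan_strand(
    dna: str, strand: str, contig: str, contig_len: int, motif: LeaderMotif
) -> list[OrfHit]:
    hits = []
    for frame in range(3):
        i = frame
        while i + 3 <= len(dna):
            codon = dna[i : i + 3]
            if codon in START_CODONS:
                j = i + 3
                while j + 3 <= len(dna):
                    c = dna[j : j + 3]
                    if c in STOP_CODONS:
                        aa_len = (j - i) // 3
                        if ORF_MIN_AA <= aa_len <= ORF_MAX_AA:
                            protein = "M" + str(
                                Seq(dna[i + 3 : j]).translate(table=11)
                            )
                            if strand == "+":
                                start, end = i, j + 3
                            else:
                                start, end = contig_len - (j + 3), contig_len - i
                            rec = PrecursorRecord(
                                id=f"{contig}:{start}-{end}({strand})",
                                sequence=protein,
                                source="mined ORF",
                            )
                            motif_hits = (
                                tuple(scan_motif(rec, motif))
                                if len(protein) >= motif.length
                                else ()
                            )
                            hits.append(
                                OrfHit(rec, contig, start, end, strand, motif_hits)
                            )
                        break
                    j += 3
            i += 3
    return hits


def find_precursor_orfs(
    dna: str,
    span: tuple[int, int] | None = None,
    contig: str = "contig",
    margin: int = 500,
    motif: LeaderMotif = DEFAULT_MOTIF,
) -> list[OrfHit]:
    """Short ORFs (25-70 aa, starts ATG/GTG/TTG, genetic code 11, both strands).

    ``span`` restricts the search to a cluster region +- ``margin`` bp.  Every
    ORF is scored against the leader motif; motif-positive ORFs are candidate
    precursor (A) genes.
    """
    dna = dna.upper()
    bad = [str(i) for i, c in enumerate(dna) if c not in "ACGT"]
    if bad:
        raise ValueError(f"non-ACGT characters at positions: {', '.join(bad[:10])}")
    if span is not None:
        lo = max(0, span[0] - margin)
        hi = min(len(dna), span[1] + margin)
    else:
        lo, hi = 0, len(dna)
    region = dna[lo:hi]
    fwd = _scan_strand(region, "+", contig, len(region), motif)
    rev = _scan_strand(
        str(Seq(region).reverse_complement()), "-", contig, len(region), motif
    )
    hits = fwd + rev
    shifted = [
        OrfHit(
            PrecursorRecord(
                f"{contig}:{h.start + lo}-{h.end + lo}({h.strand})",
                h.record.sequence,
                h.record.source,
            ),
            h.contig,
            h.start + lo,
            h.end + lo,
            h.strand,
            h.motif_hits,
        )
        for h in hits
    ]
    shifted.sort(key=lambda h: (h.start, h.end, h.strand))
    return shifted


# ---------------------------------------------------------------------------
# genome-level convenience


def _proteins_from_genbank(path: str | Path) -> tuple[list[ProteinRecord], dict[str, str]]:
    proteins: list[ProteinRecord] = []
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        contigs[rec.id] = str(rec.seq)
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            seq = feat.qualifiers.get("translation", [None])[0]
            if seq is None:
                seq = str(feat.extract(rec.seq).translate(table=11, to_stop=True))
            name = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", ["cds"]))[0]
            proteins.append(
                ProteinRecord(
                    id=name,
                    sequence=seq,
                    contig=rec.id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand="+" if feat.location.strand >= 0 else "-",
                )
            )
    return proteins, contigs


def mine_genome(
    genbank_path: str | Path,
    references: ReferenceSet | None = None,
    threshold: float = DEFAULT_NORM_THRESHOLD,
    window_genes: int = DEFAULT_WINDOW_GENES,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[ClusterCandidate]:
    """Mine an annotated GenBank genome for lasso BGC candidates.

    Seeds on cyclase homology, assembles each seed's neighborhood, then
    searches the cluster span for motif-positive precursor ORFs.
    """
    if references is None:
        references = load_reference_set()
    proteins, contigs = _proteins_from_genbank(genbank_path)
    hits = find_seed_hits(proteins, references, roles=("cyclase",), threshold=threshold)
    clusters = []
    claimed: list[tuple[str, int, int]] = []
    for hit in hits:
        p = hit.protein
        if any(c == p.contig and p.start < e and p.end > s for c, s, e in claimed):
            continue
        cluster = assemble_cluster(
            hit, proteins, references, window_genes, window_bp, threshold
        )
        orfs = find_precursor_orfs(
            contigs[cluster.contig], (cluster.start, cluster.end), cluster.contig
        )
        precursors = tuple(o for o in orfs if o.is_candidate_precursor)
        clusters.append(replace(cluster, precursor_orfs=precursors))
        claimed.append((cluster.contig, cluster.start, cluster.end))
    clusters.sort(key=lambda c: (c.contig, c.start))
    return clusters
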