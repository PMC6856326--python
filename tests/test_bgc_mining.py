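"""Alignment, seed-hit search, cluster assembly and short-ORF discovery.

The Smith-Waterman check uses an independent brute-force oracle: a local
alignment is a pair of equal-length subsequences with affine gap costs for
the skipped internal residues, so for tiny sequences the optimum can be
found by exhaustive enumeration over all subsequence pairs.
"""

from itertools import combinations

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from lassokit.bgc_mining import (
    ProteinRecord,
    assemble_cluster,
    find_precursor_orfs,
    find_seed_hits,
    load_reference_set,
    mine_genome,
    smith_waterman,
)
from lassokit.synthetic_data import (
    SimulationSpec,
    gen_cluster_genome,
    mutate_peptide,
    write_genome,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXTEND = 10.0, 0.5
AA = "ARNDCQEGHILKMFPSTWYV"


def _gap_cost(length: int) -> float:
    if length <= 0:
        return 0.0
    return GAP_OPEN + (length - 1) * GAP_EXTEND


def brute_force_local_score(a: str, b: str) -> float:
    """Exhaustive optimum over all subsequence-pair alignments (oracle)."""
    best = 0.0
    for k in range(1, min(len(a), len(b)) + 1):
        for ai in combinations(range(len(a)), k):
            for bj in combinations(range(len(b)), k):
                score = 0.0
                for t in range(k):
                    score += BLOSUM62[a[ai[t]], b[bj[t]]]
                    if t:
                        score -= _gap_cost(ai[t] - ai[t - 1] - 1)
                        score -= _gap_cost(bj[t] - bj[t - 1] - 1)
                best = max(best, score)
    return best


class TestSmithWaterman:
    def test_self_alignment(self):
        result = smith_waterman("ACDEFGHIK", "ACDEFGHIK")
        assert result.percent_identity == 100.0
        assert result.normalized_score == pytest.approx(1.0)

    def test_oracle_equivalence_100_seeded_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = "".join(rng.choice(list(AA), size=rng.integers(3, 6)))
            b = "".join(rng.choice(list(AA), size=rng.integers(3, 7)))
            expected = brute_force_local_score(a, b)
            got = smith_waterman(a, b).score
            assert got == pytest.approx(expected, abs=1e-9), (a, b)

    def test_symmetry_for_symmetric_matrix(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=12))
            b = "".join(rng.choice(list(AA), size=15))
            assert smith_waterman(a, b).score == pytest.approx(
                smith_waterman(b, a).score
            )

    def test_reversed_sequence_lower_bound(self):
        result = smith_waterman("ACDEFG", "GFEDCA")
        best_single = max(float(BLOSUM62[x, x]) for x in "ACDEFG")
        assert result.score >= best_single

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError, match="not covered"):
            smith_waterman("AC1DE", "ACDE")
        with pytest.raises(ValueError):
            smith_waterman("", "ACDE")


class TestFindSeedHits:
    def test_exact_reference_copy_scores_one(self):
        refs = load_reference_set()
        cyclase_seq = refs.by_role("cyclase")[0][1]
        proteome = [ProteinRecord("p1", cyclase_seq)]
        hits = find_seed_hits(proteome, refs)
        assert len(hits) == 1
        assert hits[0].role == "cyclase"
        assert hits[0].alignment.normalized_score == pytest.approx(1.0)

    def test_mutated_cyclase_above_threshold(self):
        refs = load_reference_set()
        cyclase_seq = refs.by_role("cyclase")[0][1]
        rng = np.random.default_rng(5)
        mutant = mutate_peptide(cyclase_seq, 0.4, rng)  # ~60% identity
        identity = smith_waterman(cyclase_seq, mutant).percent_identity
        assert 50 < identity < 75
        hits = find_seed_hits([ProteinRecord("mut", mutant)], refs)
        assert hits and hits[0].alignment.normalized_score >= 0.3

    def test_unrelated_peptides_empty(self):
        refs = load_reference_set()
        proteome = [
            ProteinRecord("x1", "GFGSKPLDSFGLNFF"),
            ProteinRecord("x2", "LYGVRNDEEINWHFDYWT"),
        ]
        assert find_seed_hits(proteome, refs) == []


class TestClusterAssembly:
    def _mined(self, layout, seed, strand="+"):
        spec = SimulationSpec(
            seed=seed, cluster_layout=layout, precursor_strand=strand
        )
        record, truth = gen_cluster_genome(spec)
        return record, truth

    def test_compact_cluster_without_transporters(self, tmp_path):
        record, truth = self._mined(("B", "C", "E", "A"), seed=13)
        path = tmp_path / "genome.gbk"
        write_genome(record, path)
        clusters = mine_genome(path)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.complete and c.transporter_count == 0
        assert c.max_intergenic_gap <= 500 and not c.has_substantial_gap

    def test_lee_order_cluster_with_two_transporters(self, tmp_path):
        record, truth = self._mined(("C", "E", "B", "A", "D", "F"), seed=17)
        path = tmp_path / "genome.gbk"
        write_genome(record, path)
        clusters = mine_genome(path)
        assert len(clusters) == 1
        assert clusters[0].transporter_count == 2
        assert clusters[0].complete

    def test_incomplete_cluster_flags(self, tmp_path):
        record, truth = self._mined(("C",), seed=19)
        path = tmp_path / "solo.gbk"
        write_genome(record, path)
        clusters = mine_genome(path)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.has_cyclase_c and not c.has_peptidase_b and not c.has_rre_e
        assert not c.complete

    def test_proteome_only_seed_requires_coordinates(self):
        refs = load_reference_set()
        cyclase_seq = refs.by_role("cyclase")[0][1]
        hits = find_seed_hits([ProteinRecord("p", cyclase_seq)], refs)
        with pytest.raises(ValueError, match="proteome-only"):
            assemble_cluster(hits[0], [hits[0].protein], refs)

    def test_member_order_invariance(self, tmp_path):
        record, truth = self._mined(("C", "E", "B"), seed=23)
        refs = load_reference_set()
        proteins = []
        for f in record.features:
            proteins.append(
                ProteinRecord(
                    id=f.qualifiers["locus_tag"][0],
                    sequence=f.qualifiers["translation"][0],
                    contig=record.id,
                    start=int(f.location.start),
                    end=int(f.location.end),
                    strand="+",
                )
            )
        hits = find_seed_hits(proteins, refs)
        forward = assemble_cluster(hits[0], proteins, refs)
        backward = assemble_cluster(hits[0], list(reversed(proteins)), refs)
        assert forward.members == backward.members
        assert forward.max_intergenic_gap == backward.max_intergenic_gap


class TestPrecursorOrfs:
    def test_planted_precursor_recovered_plus_strand(self):
        spec = SimulationSpec(seed=29)
        record, truth = gen_cluster_genome(spec)
        span = tuple(truth["cluster_span"])
        orfs = find_precursor_orfs(str(record.seq), span)
        sequences = {o.record.sequence for o in orfs if o.is_candidate_precursor}
        assert truth["precursor"]["sequence"] in sequences
        hit = next(
            o for o in orfs if o.record.sequence == truth["precursor"]["sequence"]
        )
        assert hit.strand == "+"

    def test_planted_precursor_recovered_minus_strand(self):
        spec = SimulationSpec(seed=31, precursor_strand="-")
        record, truth = gen_cluster_genome(spec)
        orfs = find_precursor_orfs(str(record.seq), tuple(truth["cluster_span"]))
        hit = next(
            (o for o in orfs if o.record.sequence == truth["precursor"]["sequence"]),
            None,
        )
        assert hit is not None and hit.strand == "-"

    def test_reverse_complement_mirror(self):
        spec = SimulationSpec(seed=37)
        record, truth = gen_cluster_genome(spec)
        dna = str(record.seq)
        fwd = find_precursor_orfs(dna)
        rev = find_precursor_orfs(str(Seq(dna).reverse_complement()))
        n = len(dna)
        mirrored = sorted(
            (n - o.end, n - o.start, "-" if o.strand == "+" else "+", o.record.sequence)
            for o in fwd
        )
        direct = sorted((o.start, o.end, o.strand, o.record.sequence) for o in rev)
        assert mirrored == direct

    def test_no_start_codons_empty(self):
        assert find_precursor_orfs("CCCCCCCCGGGGGGGGCCCCGGGG") == []

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            find_precursor_orfs("ATGNNNTGA")
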