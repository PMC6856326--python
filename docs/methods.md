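# Methods

## Scope and model

`lassokit` models the desk half of a lasso peptide discovery campaign: from
genome to candidate cluster, from precursor sequence to predicted mature
mass, and from MS/MS peak list to the ring-closing residue. The underlying
chemical model is deliberately minimal: a lasso peptide is a core sequence
of n residues (typical window 14–24) with a single macrolactam bond between
the N-terminal amine and the side-chain carboxylate of an Asp/Glu at
position r ∈ {7, 8, 9}. No other modifications are modeled (no citrulline,
no disulfides, no adducts beyond protons), and the threading of the tail
through the ring is treated as a covalent-topology constraint on
fragmentation only, not sterically.

## Mass conventions

Residue masses are monoisotopic, stored to 5 decimals, derived from
elemental formulas with IUPAC atomic masses (verified in the tests against
pyteomics' formula arithmetic to 1e-3 Da). Constants: water 18.010565 Da,
proton 1.007276 Da, hydrogen atom 1.007825 Da, CO 27.994915 Da.

Two charge-carrier conventions coexist deliberately:

* precursor charge states use the proton mass — `[M+2H]²⁺` of a 2338.0440 Da
  neutral is m/z 1170.0293;
* fragment-ion m/z uses the hydrogen-atom mass (b_k = Σ residues 1..k + H),
  the convention of the fragment-ion calculators used in peptide MS/MS
  practice. With proton arithmetic the same ions would differ by ~0.0005 Da,
  which is outside the agreement we obtain against published fragment
  values.

Both constants are surfaced in every `IonTable.conventions` record. Residual
±0.0005 Da offsets against published four-decimal values are attributed to
rounding in whichever atomic-mass table the original calculators used;
comparisons therefore always use explicit tolerances (±0.002 Da for intact
masses, ±0.003 for fragments), never string equality.

## Leader/core prediction

The leader motif is a 17-position template `YxxPx[LV]xxxGxxxxxTx` with four
hard anchors (Y1, P4, G10, T16) and a tolerated substitution set at position
6 (default {L, V}, the only documented deviation being Val). A window
matching all four anchors scores 4, plus 1 if position 6 is in the tolerated
set; matches are ordered score-descending, then leftmost. Cleavage is placed
after motif position 17 — one residue past the conserved Thr — because that
registration is the unique one consistent with both experimentally confirmed
cores (leader …EETG | LYGV… and …SEDTL | GFGS…).

The Gly-start rule enumerates a candidate at every Gly in the C-terminal
half of the precursor; restricting to the C-terminal half avoids a
combinatorial explosion from leader-internal glycines while covering every
historically considered candidate. The core-length window [14, 24] is a
soft ranking penalty, not a filter, since real predictions near the window
edge exist. Ring candidates are the Asp/Glu residues at core positions
7–9 (configurable).

## Fragment topology

For a ring at r, backbone cleavage inside the ring cannot release a
fragment, so: a/b ions with k ≥ r contain the intact ring and get the −H₂O
ring correction; a/b are observable only for k ≥ r+1; y only for j ≤ n−r;
and a_r/b_r (the bare macrolactam) is unobservable by default (configurable
via `bare_ring_observable`). Unobservable ions are emitted with flags rather
than dropped because the localizer uses them as negative evidence. Only
singly charged fragment m/z is generated — inputs are assumed deconvoluted.

## Ring localization

Candidates are scored as
`score(r) = #matched observable − w · #matched forbidden` (w = 1 by
default: a peak matching an ion the topology forbids counts against the
candidate exactly as strongly as positive evidence counts for it).
Matching is greedy nearest-first within tolerance (default 0.01 Da on
deconvoluted masses — generous against the ≤0.002 Da accuracy of modern
instruments yet far below inter-ion spacing), one peak per ion and vice
versa. Scoring uses two matching passes: observable ions claim peaks first,
and only peaks no observable ion explains can match forbidden ions. Without
this, near-isobars (e.g. linear b5 vs y4 of some cores, Δ < 3 mDa) would
convert positive evidence into penalties under mass jitter.

The ladder endpoints — first matched a-or-b index and largest matched y
index — pin the ring: they must equal r+1 and n−r respectively, which at
most one candidate can satisfy. That candidate is called iff no other
candidate out-scores it; otherwise the verdict is `ambiguous` (conflicting
evidence) or `no-call` (no usable evidence). Ties are never broken by a
prior over r. One known limit: if every diagnostic ion of the true ring is
absent and the surviving ladder is exactly the complete spectrum of a
neighboring candidate, the evidence genuinely supports that candidate and
the call follows the evidence; with the default generator conditions
(dropout applied to non-diagnostic ions) this situation does not arise, and
the 200-draw recovery test shows 100% correct calls with zero wrong calls.

## Similarity search and networks

Local similarity (cluster mining) is Smith–Waterman with BLOSUM62, gap open
10 / extend 0.5 (a gap of length L costs open + (L−1)·extend), executed by
Biopython's `PairwiseAligner`; an independent brute-force enumeration over
all subsequence alignments verifies the scores on small inputs. Scores are
normalized by the query's self-score; the seed threshold 0.3 is an
engineering default validated on synthetic data only (no E-value model).
Cluster neighborhoods span ±8 genes and ±10 kb, whichever is tighter;
intergenic gaps > 500 bp are flagged as substantial. Completeness requires
B+C+E; transporters are counted but optional, since transporter-less lasso
clusters exist.

SSN edges use end-gap-free global alignment percent identity (identical
columns over aligned columns, terminal overhangs excluded) under the same
scoring scheme — reproducible without an external search engine, unlike
bitscore-based SSN services. Default thresholds: 40% for precursors, 50%
for cores; both are reported in the graph metadata. Components are labeled
by their lexicographically smallest member so output is input-order
invariant.

The bundled reference exemplars (cyclase, peptidase, RRE, two transporters)
are synthetic sequences with actinobacteria-like composition and realistic
lengths, generated once under a fixed seed and versioned in
`data/synthetic_references.fasta`; they exercise the homology machinery but
carry no real evolutionary signal, so mining results on real genomes
require a user-supplied reference FASTA (`role=` tags in the headers).

## Synthetic data: what it emulates, what it does not

`SimulationSpec` drives all three generators from one integer seed;
identical seeds give byte-identical artifacts, and every artifact ships its
ground truth.

* Precursors: Met-initial random leader containing exactly one motif
  window, Gly-initial core of length 14–24 with exactly one acidic residue
  in positions 7–9. De novo draws are rejection-sampled until the
  motif-cleavage rule recovers the planted core, making ground truth
  consistent by construction. Template mode reproduces a supplied precursor
  exactly at mutation rate 0, or mutates it outside the motif anchors.
* Genomes: role proteins mutated at 30% of positions by default (≈65–70%
  identity — far from the seed threshold in either direction),
  back-translated with codon choice weighted by per-base GC to hit the
  target genomic GC of 0.72 (Streptomyces-like), joined with 20–120 bp
  spacers and embedded in random flanking DNA. Realized GC lands within
  ±0.02 of target at 100 kb. Not emulated: real codon-usage tables,
  operonic promoters/terminators, repeat structure, sequencing error.
* Spectra: all topology-observable ions with Gaussian mass jitter
  (sd 0.002 Da, consistent with observed sub-mDa deviations on
  high-resolution instruments), per-series dropout, and uniform-m/z noise
  peaks with log-normal intensities. Intensity distributions are
  placeholders — the matcher is intensity-agnostic, so only peak presence
  matters. Not emulated: isotope envelopes, multiply charged fragments,
  chromatography, co-isolation.

Consequently, passing recovery tests demonstrate correctness of the
topology logic, the scoring and the search plumbing under controlled noise;
they do not demonstrate performance on real instrument data, where
deconvolution artifacts and real homology structure add failure modes the
generators do not produce.

## Numerical and interface choices

* Problem sizes in the test suite are chosen for exhaustive verifiability:
  alignment oracles run on ≤6-mers (where all subsequence alignments can be
  enumerated), SSN oracles on ≤20 nodes, localization recovery on 200
  seeded draws, mining recovery on single-cluster contigs of ~8 kb.
* Coordinates are 0-based half-open internally; GenBank emission converts
  to the format's 1-based inclusive convention via Biopython.
* ORF discovery uses genetic code 11 with starts {ATG, GTG, TTG} on both
  strands, reporting *every* ORF of 25–70 aa (including nested in-frame
  starts — the miner cannot know the true start, and motif scoring ranks
  them).
* Degenerate inputs fail loudly: unknown residue letters name the offender
  and position, non-ACGT bases list their positions, MGF blocks declaring
  charge > 1 are rejected with instructions to deconvolute, and a core
  without an acidic ring candidate yields an empty product list plus a
  warning rather than an error.
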