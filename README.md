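# lassokit

Lasso peptides are ribosomally synthesized and post-translationally modified
peptides (RiPPs) in which the N-terminal amine of a 14–24 residue core is
bonded to the side-chain carboxylate of an Asp/Glu at core position 7, 8 or 9,
forming a macrolactam ring through which the C-terminal tail is threaded.
`lassokit` implements the computational chain used to discover and
characterize them, for natural-product and proteomics researchers working
from genome sequences and high-resolution MS/MS data:

* **Genome mining** (`lassokit.bgc_mining`) — seed on Smith–Waterman homology
  to a lasso cyclase (C-protein), gather the compact gene neighborhood,
  annotate leader peptidase (B), RiPP recognition element (E) and ABC
  transporters, and find short precursor ORFs on either strand.
* **Leader/core prediction** (`lassokit.precursor_prediction`) — split a
  precursor using the conserved leader motif `YxxPx[LV]xxxGxxxxxTx`
  (cleavage one residue past the invariant penultimate Thr) and the
  historical Gly-start rule, and enumerate Asp/Glu ring candidates.
* **Mass chemistry** (`lassokit.masschem`) — monoisotopic masses of linear
  and macrolactam-cyclized peptides. Ring closure loses one water:
  `M_cyclized = Σ residue masses = M_linear − 18.010565 Da`, independent of
  the ring position; charge states follow `m/z = (M + z·1.007276)/z`.
* **Topology-aware fragment ions** (`lassokit.lasso_fragments`) — a/b/y
  tables where ring-containing a/b ions (index ≥ r) carry the −H₂O ring
  correction and ions requiring a backbone cleavage inside the ring are
  flagged unobservable: observable b/a start at index r+1, observable y stop
  at index n−r.
* **Ring localization** (`lassokit.ring_localization`) — match deconvoluted
  peaks to candidate tables and call the ring residue r from the fragment
  ladder endpoints (first b/a = r+1, last y = n−r) plus an evidence score
  that penalizes peaks matching topologically forbidden ions.
* **Subfamily networks** (`lassokit.ssn_subfamily`) — all-vs-all global
  percent-identity networks over precursors; connected components
  approximate subfamilies.
* **Synthetic data** (`lassokit.synthetic_data`) — seeded generators for
  high-GC genomes with planted clusters, motif-bearing precursors, and
  deconvoluted lasso spectra with jitter/dropout/noise, each with ground
  truth, so the whole pipeline is testable offline.

## Worked example

```python
>>> from lassokit import enumerate_core_candidates, predict_products
>>> lp2 = "MEHDEKTPYETPAVYGLGAFAEETGLYGVRNDEEINWHFDYWT"
>>> top = enumerate_core_candidates(lp2)[0]
>>> top.core, top.ring_candidates
('LYGVRNDEEINWHFDYWT', ((7, 'D'), (8, 'E'), (9, 'E')))
>>> peptide, mass, mzs = predict_products(top)[1]
>>> round(mass, 4), round(mzs[2], 4)
(2338.0443, 1170.0294)
```

The top-ranked candidate core of the leepeptin precursor is the confirmed
18-mer, its cyclized monoisotopic mass is 2338.0443 Da and its doubly
protonated ion sits at m/z 1170.03 — the values a deconvoluted LC-MS run of
the mature peptide shows. Fragment evidence then pins the ring:

```python
>>> from lassokit import LassoPeptide, PeakList, infer_ring, lasso_ion_table
>>> table = lasso_ion_table(LassoPeptide("LYGVRNDEEINWHFDYWT", 8))
>>> peaks = PeakList(tuple((i.mz, 1000.0) for i in table.observable_ions()))
>>> result = infer_ring("LYGVRNDEEINWHFDYWT", (7, 8, 9), peaks)
>>> result.verdict, result.ring_pos
('called', 8)
```

The ladder stops at a9/b9 (1030.4958 / 1058.4907) and y10, exactly what a
Leu1–Glu8 macrolactam permits, so Glu8 is called uniquely.

The `examples/` scripts walk through each capability
(`python examples/01_mass_prediction.py`, …), and a thin CLI mirrors them:
`lassokit mass|predict|ions|localize|mine|ssn|simulate --help`.

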