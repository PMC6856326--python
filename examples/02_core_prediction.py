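"""Leader/core prediction from a precursor peptide sequence.

Enumerates cleavage candidates for the leepeptin (Lp2) precursor under the
leader-motif rule (cleave one residue past the conserved ...Tx motif end)
and the historical Gly-start rule, then predicts mature macrolactam masses
for each Asp/Glu ring candidate.
"""

from lassokit import enumerate_core_candidates, predict_products

LP2 = "MEHDEKTPYETPAVYGLGAFAEETGLYGVRNDEEINWHFDYWT"

candidates = enumerate_core_candidates(LP2)
for rank, cand in enumerate(candidates, start=1):
    print(f"#{rank} [{cand.rule}] leader=...{cand.leader[-8:]} core={cand.core}")
    for peptide, mass, mzs in predict_products(cand) if cand.ring_candidates else []:
        print(
            f"    ring {peptide.core[peptide.ring_pos - 1]}{peptide.ring_pos}: "
            f"cyclized {mass:.4f} Da, [M+2H]2+ {mzs[2]:.4f}"
        )

# The top-ranked candidate is the experimentally confirmed leepeptin core
# LYGVRNDEEINWHFDYWT (2338.0443 Da); the Gly-start alternatives reproduce
# the other masses that were considered (2395.0658 and 2061.8970 Da).
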