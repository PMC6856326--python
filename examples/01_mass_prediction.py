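"""Macrolactam mass prediction for candidate lasso peptide cores.

Computes linear and cyclized monoisotopic masses and precursor charge
states for the candidate cores of the three S. leeuwenhoekii lasso
peptides.  The cyclized mass is the linear mass minus one water
(18.0106 Da), lost when the Asp/Glu side chain closes the ring.
"""

from lassokit import cyclized_mass, linear_peptide_mass, mz

CORES = {
    "Lp1 candidate (Gly start)": "GLLQRSGNDRLILSKN",
    "Lp2 candidate (Gly start)": "GLYGVRNDEEINWHFDYWT",
    "Lp2 confirmed (leepeptin)": "LYGVRNDEEINWHFDYWT",
    "Lp3 confirmed (chaxapeptin)": "GFGSKPLDSFGLNFF",
}

print(f"{'core':30s} {'linear':>10s} {'cyclized':>10s} {'[M+H]+':>10s} {'[M+2H]2+':>10s}")
for name, core in CORES.items():
    cyc = cyclized_mass(core)
    print(
        f"{name:30s} {linear_peptide_mass(core):10.4f} {cyc:10.4f} "
        f"{mz(cyc, 1):10.4f} {mz(cyc, 2):10.4f}"
    )

# The cyclized masses are what a deconvoluted MS1 spectrum of the mature
# peptide shows as neutral monoisotopic mass; e.g. leepeptin's 2338.0443 Da
# appears as the doubly protonated ion at m/z 1170.03.
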