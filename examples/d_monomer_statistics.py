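"""D-monomer statistics over peptides in Norine-style notation.

D-monomers are a hallmark of nonribosomal origin: roughly 17% of all
monomers in curated nonribosomal peptides are D-isomers, versus ~5e-6 in
ribosomal proteins.  This example counts D-monomers in a few peptide
strings and reproduces the collection-level frequency from its census
totals.
"""

from nrpsmith import DStatistics, d_statistics, parse_monomer_string

peptides = [
    # gratisin, a cyclic antibiotic with 4 D-monomers among 12
    "[Val,Orn,Leu,D-Phe,Pro,D-Tyr,Val,Orn,Leu,D-Phe,Pro,D-Tyr]",
    "Val,Leu,Ser",
    "D-Ala,Gly",
]
stats = d_statistics([parse_monomer_string(p) for p in peptides])
print(f"peptides: {stats.n_peptides}, monomers: {stats.n_monomers}")
print(f"D-monomers: {stats.n_D} (frequency {stats.freq_D:.3f})")
print(f"with >=1 D: {stats.n_with_ge1_D}, with >1 D: {stats.n_with_gt1_D}")

# collection-level census: 1920 D among 11,206 monomers in 1,164 peptides
census = DStatistics.from_counts(1164, 11206, 1920)
print(f"curated-collection D frequency: {census.freq_D:.1e}")
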