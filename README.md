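# nrpsmith

Structure prediction for nonribosomal peptides (NRPs) from the domain
architecture of their synthetases.

Nonribosomal peptide synthetases (NRPSs) are modular assembly lines:
each module — canonically `{(C)-A-T}` — incorporates one monomer, with
the adenylation (A) domain selecting it, the thiolation (T) domain
carrying it, and the condensation (C) domain forming the peptide bond.
Many NRPs owe their bioactivity to D-configured monomers produced by
epimerization, yet genome-mining tools that predict *which* monomers a
cluster incorporates rarely predict their *isomery*. `nrpsmith` fills
that gap for microbiologists and natural-product genome miners: it
parses NRPS architectures into modules, distinguishes the functional
subtypes of the condensation superfamily, and infers the D/L state of
every position in the predicted peptide.

## The model

Condensation and epimerization (E) domains share a conserved ~300-residue
core (the *Up-Seq*, Pfam PF00668 / InterPro IPR001242, carrying the
HHxxxDG active-site motif) followed by a ~150–171-residue *Down-Seq*
region specific to the catalytic subtype: C-starter, <sup>L</sup>C<sub>L</sub>,
<sup>D</sup>C<sub>L</sub>, dual C/E, fungal Ct, or E. Subtypes are
recognised two ways and reconciled:

* **context** — a C-domain with <50 aa upstream is a C-starter; in a
  tandem of C-cores with no intervening A-domain the first is an E and
  the second a <sup>D</sup>C<sub>L</sub>; the remainder are
  <sup>L</sup>C<sub>L</sub>;
* **signature** — each subtype carries two or three short windows (WL1,
  WL2, WL3; WL1/WL2 coincide with the classical C6/C7 motifs) in its
  Down-Seq. Windows are modelled as position frequency matrices; a query
  Down-Seq is scanned with the windows kept in order, scoring
  `Σᵢ log₂(f(qᵢ,i)/bg(qᵢ))` bits, and assigned to the best model that
  clears an absolute threshold with a margin over the runner-up.

Isomery then follows per module *i*: an E-domain in module *i* makes
position *i* a D (R1); a dual C/E leading module *i* epimerizes the
monomer on the preceding T-domain, position *i−1* (R2); a
<sup>D</sup>C<sub>L</sub> without an upstream E marks an expected but
unconfirmed D (R3); an Ala position with an alanine-racemase gene present
may be loaded directly as D-Ala (R4). Genus rules add topology hints
(Pseudomonas cyclic-lipopeptide pattern, fungal terminal Ct → cyclic).
Predictions render in Norine-style monomeric notation.

## Worked example

```python
from nrpsmith import IsomeryState, concat_assembly, infer_isomery, parse_architecture
from nrpsmith.data import BACITRACIN_ARCHITECTURES

assembly = concat_assembly(
    [(name, parse_architecture(arch)) for name, arch in BACITRACIN_ARCHITECTURES]
)
calls = infer_isomery(assembly)
print([m.index for m in assembly.modules if m.has_E])
print([c.position for c in calls if c.isomery is IsomeryState.D])
```

prints

```
[4, 7, 9, 11]
[4, 7, 9, 11]
```

— the bacitracin synthetase carries 12 modules with E-domains in modules
4, 7, 9 and 11, and exactly those four positions are called D. Running
`python examples/pyoverdin_prediction.py` predicts the pyoverdin
side-chain peptide of *Ps. syringae* pv. *tomato* DC3000:

```
predicted peptide: {ChrP|ChrI|ChrD},Lys,D-{Asp|bMeAsp|OH-Asp},Thr,Thr,Ser,D-{Asp|bMeAsp|OH-Asp},Ser
```

The E-domains sit in side-chain modules 2 and 6; because the fluorescent
chromophore occupies position 1 of the final peptide, the D-Asp
derivatives render at peptide positions 3 and 7. The other scripts in
`examples/` demonstrate signature training/classification on synthetic
domains and D-monomer statistics.

A thin CLI mirrors the library:

```sh
nrpsmith parse "C/E-A-T-LCL-A-T-Te-Te"
nrpsmith predict --architectures archs.tsv --organism pseudomonas
nrpsmith simulate --plan plan.json --seed 4 --out sim/
nrpsmith stats --peptides peptides.txt
```

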