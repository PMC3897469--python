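"""Predict the pyoverdin side-chain peptide of Ps. syringae pv. tomato DC3000.

Four synthetase proteins direct the side-chain biosynthesis; concatenated
in gene order they form 7 modules with E-domains in modules 2 and 6, each
followed by a DCL domain leading the next module — the classical signal
for a D-monomer.  The fluorescent chromophore occupies position 1 of the
final peptide, so every side-chain position is shifted by one.
"""

from nrpsmith import (
    CatalogEntry,
    Organism,
    concat_assembly,
    match_catalog,
    parse_architecture,
    parse_monomer_string,
    predict_structure,
    render_norine,
)
from nrpsmith.data import (
    DC3000_ARCHITECTURES,
    PYOVERDIN_CHROMOPHORES,
    PYOVERDIN_MONOMERS,
    PYOVERDIN_SIDE_CHAIN,
)

assembly = concat_assembly(
    [(p, parse_architecture(DC3000_ARCHITECTURES[p])) for p in PYOVERDIN_SIDE_CHAIN],
    Organism.PSEUDOMONAS,
)
prediction = predict_structure(
    assembly,
    PYOVERDIN_MONOMERS,
    chromophore_candidates=PYOVERDIN_CHROMOPHORES,
)
print("modules:", assembly.n_modules)
print("E-domains in modules:", [m.index for m in assembly.modules if m.has_E])
print("predicted peptide:", render_norine(prediction))

# compare against a small local catalog (a synthetic stand-in entry with
# one concrete candidate combination per position)
catalog = [
    CatalogEntry(
        "SYN:pyoverdin-19310-like",
        parse_monomer_string("ChrD,Lys,D-Asp,Thr,Thr,Ser,D-Asp,Ser"),
    )
]
for m in match_catalog(prediction, catalog, min_positional_matches=3):
    print(f"catalog match: {m.entry.id} ({m.n_matched}/{len(prediction.calls)} positions)")
# The D-Asp derivatives render at peptide positions 3 and 7 — one past
# their modules (2 and 6) because of the chromophore offset.
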