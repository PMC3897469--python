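"""Curated example NRPS architectures used in examples and tests.

Architecture strings for the NRPS gene clusters of *Pseudomonas syringae*
pv. *tomato* DC3000 (RefSeq protein ids), and an encoding of the
bacitracin synthetase of *Bacillus licheniformis* (BacA/BacB/BacC, 12
modules with epimerization domains in modules 4, 7, 9 and 11).  These are
literature-derived inputs, not outputs of this package.
"""

from __future__ import annotations

#: DC3000 NRPS proteins, in gene order within each cluster.
DC3000_ARCHITECTURES: dict[str, str] = {
    # cluster 1: yersiniabactin (NRPS/PKS hybrid parts)
    "AA056104": "T-Cy-A-T",
    "AA056106": "PKS-Cy-T-Te",
    # cluster 2: pyoverdin chromophore synthetase + side-chain synthetases
    "NP_791957": "T-^L^C_L_-A-T-^L^C_L_-A-T-E-^D^C_L_-A-T",
    "NP_791969": "^L^C_L_-A-T",
    "NP_791970": "^L^C_L_-A-T-E-^D^C_L_-A-T",
    "NP_791971": "^L^C_L_-A-T-^L^C_L_-A-T",
    "NP_791972": "^L^C_L_-A-T-E-^D^C_L_-A-T-Te",
    # cluster 3: syringafactin (SyfA, SyfB)
    "NP_792633": "C_starter_-A-T-C/E-A-T-C/E-A-T",
    "NP_792634": "C/E-A-T-^L^C_L_-A-T-C/E-A-T-^L^C_L_-A-T-C/E-A-T-Te-Te",
    # cluster 4: amphibactin-like lipopeptide
    "NP_794446": "C_starter_-A-T-^L^C_L_-A-T-C/E-A-T-^L^C_L_-A-T-Te",
    # cluster 5: PKS/NRPS hybrid + terminal component
    "NP_794271": "PKS-T-C?-A-T",
    "NP_794272": "^L^C_L_-A-T-^L^C_L_-A-T-^L^C_L_-A-T-Te",
}

#: Pyoverdin side-chain synthetases of cluster 2, in gene order.
PYOVERDIN_SIDE_CHAIN: list[str] = [
    "NP_791969",
    "NP_791970",
    "NP_791971",
    "NP_791972",
]

#: Syringafactin synthetases (SyfA, SyfB), in gene order.
SYRINGAFACTIN: list[str] = ["NP_792633", "NP_792634"]

#: Bacitracin synthetase, canonical {(C)-A-T(-E)} encoding: BacA carries
#: modules 1-5 (E in module 4), BacB modules 6-7 (E in 7), BacC modules
#: 8-12 (E in 9 and 11) ending in the thioesterase.
BACITRACIN_ARCHITECTURES: list[tuple[str, str]] = [
    ("BacA", "A-T-LCL-A-T-LCL-A-T-LCL-A-T-E-DCL-A-T"),
    ("BacB", "LCL-A-T-LCL-A-T-E"),
    ("BacC", "DCL-A-T-LCL-A-T-E-DCL-A-T-LCL-A-T-E-DCL-A-T-Te"),
]

#: Monomer candidates for the pyoverdin 19310 side chain (one list per
#: side-chain module), with the chromophore alternatives prepended at
#: prediction time.
PYOVERDIN_MONOMERS: list[list[str]] = [
    ["Lys"],
    ["Asp", "bMeAsp", "OH-Asp"],
    ["Thr"],
    ["Thr"],
    ["Ser"],
    ["Asp", "bMeAsp", "OH-Asp"],
    ["Ser"],
]

PYOVERDIN_CHROMOPHORES: list[str] = ["ChrP", "ChrI", "ChrD"]
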