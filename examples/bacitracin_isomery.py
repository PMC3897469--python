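"""Infer D-monomer positions of bacitracin from its synthetase architecture.

The bacitracin synthetase (BacA/BacB/BacC) carries 12 modules with
epimerization domains in modules 4, 7, 9 and 11; each E-domain converts
the monomer of its own module to the D-configuration (rule R1).
"""

from nrpsmith import IsomeryState, concat_assembly, infer_isomery, parse_architecture
from nrpsmith.data import BACITRACIN_ARCHITECTURES

assembly = concat_assembly(
    [(name, parse_architecture(arch)) for name, arch in BACITRACIN_ARCHITECTURES]
)
calls = infer_isomery(assembly)

print(f"modules: {assembly.n_modules}")
print("E-domains in modules:", [m.index for m in assembly.modules if m.has_E])
d_positions = [c.position for c in calls if c.isomery is IsomeryState.D]
print(f"D-monomer positions: {d_positions} ({len(d_positions)} of {len(calls)})")
# The four positions mirror the four E-domain modules: every epimerized
# monomer sits exactly where its module's E-domain acts.
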