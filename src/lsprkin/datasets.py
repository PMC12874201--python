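"""Reference dataset: PEI/PAZO polyelectrolyte complexation kinetics.

Published-style observed rate constants (mean ± SEM over duplicate
injections) for the two orientations of the PEI–PAZO electrostatic
interaction, measured by LSPR at monomeric concentrations of 1, 0.5, 0.25,
0.125 and 0.0625 mM:

* PEI (polycation, repeat unit 43.07 g/mol, chain mass ~25,000 g/mol by
  SEC) flowed over a PAZO-coated surface — the "known" orientation, whose
  chain-basis regression yields k_on and k_off;
* PAZO (azobenzene polyanion, repeat unit 401 g/mol, chain mass unknown)
  flowed over a PEI-coated surface — the "unknown" orientation, whose
  monomeric-basis slope alpha closes the M_n determination.

``PEI_CHAIN_CONCENTRATIONS_UM`` carries the chain (polymeric)
concentrations as printed in the source data table; they differ from
``monomeric_to_polymeric`` applied to 25,000/43.07 by ~0.16% (the table's
DP rounds to 581.4 rather than 580.4).  Both are kept so either convention
can be reproduced exactly.
"""

from .model import PolymerSpec

PEI = PolymerSpec("PEI", repeat_unit_mass=43.07, chain_mass=25000.0)
PAZO = PolymerSpec("PAZO", repeat_unit_mass=401.0)

#: monomeric concentration gradient, mM (shared by both orientations)
GRADIENT_MM = (1.0, 0.5, 0.25, 0.125, 0.0625)

#: PEI over PAZO surface: (monomeric conc mM, k_obs 1/s, SEM 1/s, n)
PEI_KOBS = (
    (1.0, 0.07527, 0.01028, 2),
    (0.5, 0.05154, 0.00669, 2),
    (0.25, 0.03287, 0.00628, 2),
    (0.125, 0.01830, 0.00044, 2),
    (0.0625, 0.01701, 0.00076, 2),
)

#: PAZO over PEI surface: (monomeric conc mM, k_obs 1/s, SEM 1/s, n)
PAZO_KOBS = (
    (1.0, 0.08162, 0.01599, 2),
    (0.5, 0.06280, 0.01245, 2),
    (0.25, 0.04830, 0.01123, 2),
    (0.125, 0.03560, 0.01076, 2),
    (0.0625, 0.02315, 0.00953, 2),
)

#: PEI chain concentrations (uM) as printed in the source conversion table
PEI_CHAIN_CONCENTRATIONS_UM = (1.72, 0.86, 0.43, 0.215, 0.1075)
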