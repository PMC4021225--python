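"""Monoisotopic mass constants.

Residue masses come from the standard IUPAC monoisotopic table shipped with
pyteomics; the proton and water constants are fixed here so that every module
(precursor neutral-mass arithmetic, fragment m/z generation, digestion mass
filters) uses the same values.
"""

from __future__ import annotations

from pyteomics import mass as _pt_mass

PROTON_MASS = 1.007276
WATER_MASS = 18.010565

# neutral-loss masses for the satellite fragment-ion types
H2O_LOSS = 18.010565
NH3_LOSS = 17.026549
CO_LOSS = 27.994915
NH_LOSS = 15.010899

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: monoisotopic residue (amino-acid minus water) masses, canonical letters only
RESIDUE_MASSES: dict[str, float] = {
    aa: _pt_mass.std_aa_mass[aa] for aa in CANONICAL_RESIDUES
}
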