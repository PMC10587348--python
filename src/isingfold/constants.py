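"""Physical constants and unit conventions.

All contact energies are in kcal/mol; per-residue conformational entropies
are in cal/(mol.K).  The gas constant per-mole convention is used for k_B
so that Boltzmann factors read exp(-E / (KB_KCAL * T)) with E in kcal/mol,
and entropy factors read exp(S / KB_CAL) with S in cal/(mol.K).
"""

#: Gas constant in cal/(mol.K) (per-mole k_B convention).
KB_CAL = 1.987

#: Gas constant in kcal/(mol.K).
KB_KCAL = KB_CAL / 1000.0

#: Calpha-Calpha virtual bond length (Angstrom).
CA_STEP = 3.8

#: Persistence length of a peptide chain (Angstrom).
PERSISTENCE_LENGTH = 20.0

#: Default heavy-atom contact cutoff (Angstrom).
CONTACT_CUTOFF = 4.0

#: Default raw-energy threshold below which a contact is linker-eligible
#: (kcal/mol).
LINKER_THRESHOLD = -0.6

#: Default raw-energy bonus for a formed disulfide bond (kcal/mol).
DISULFIDE_BONUS = -40.0

#: Per-residue entropy cost defaults by model variant, cal/(mol.K).
S_RESIDUE_DEFAULTS = {
    "original1": -2.0,
    "original2": -2.5,
    "linker": -3.5,
    "linker_ss": -3.5,
    "linker_ss_intact": -3.5,
}

#: Default kinetic prefactor for the 1D master equation (1/s).
PREFACTOR_A = 1.0e7
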