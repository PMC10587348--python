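# Hen egg-white lysozyme, disulfide-intact folding (documented example).
#
# This config records the published constants for the disulfide-intact
# lysozyme analysis.  It is NOT runnable offline: the structure (PDB
# 1iee) and the force-field-derived pairwise contact energies must be
# supplied by the user as local files.  The energy table format is
# 3-column TSV: i <TAB> j <TAB> energy_kcal_mol (1-based residue
# indices).

variant: linker_ss_intact
structure: lysozyme_1iee.pdb          # user-supplied
energy_table: lysozyme_energies.tsv   # user-supplied (e.g. MMPBSA-derived)
temperature: 293.0

# fitted per-protein parameters (stability target dG_NU = 16 kBT at T_f)
epsilon: 1.783
h_scale: 1.0
s_residue: -3.5                       # cal/(mol K), linker-model default

# the four native disulfide bonds
disulfides:
  - [6, 127]
  - [30, 115]
  - [76, 94]
  - [64, 80]

# alpha-domain (discontinuous) vs beta-domain order parameters
regions:
  alpha: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18,
          19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34,
          35, 36, 37, 38, 39, 86, 87, 88, 89, 90, 91, 92, 93, 94, 95, 96,
          97, 98, 99, 100, 101, 102, 103, 104, 105, 106, 107, 108, 109,
          110, 111, 112, 113, 114, 115, 116, 117, 118, 119, 120, 121, 122,
          123, 124, 125, 126, 127, 128, 129]
  beta: [40, 41, 42, 43, 44, 45, 46, 47, 48, 49, 50, 51, 52, 53, 54, 55,
         56, 57, 58, 59, 60, 61, 62, 63, 64, 65, 66, 67, 68, 69, 70, 71,
         72, 73, 74, 75, 76, 77, 78, 79, 80, 81, 82, 83, 84, 85]

linker_threshold: -0.6

# temperature-dependent contact-energy scale and heat-capacity scan
thermo:
  T_min: 280.0
  T_max: 380.0
  T_step: 1.0
  baseline: 8.0                       # kcal/(mol K), DSC comparison offset
  epsilon_of_T:
    eps_f: 1.783                      # eps at the reference temperature
    p: -0.307
    q: 11.3
    T_f: 293.0                        # reference (folding) temperature
    # chosen so that dG_NU(350 K) = 0 (thermal midpoint T_m = 350 K)

output_dir: out/lysozyme
seed: 0
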