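# isingfold

Structure-based Ising-like statistical mechanical models of protein
folding, with virtual linkers for nonlocal interactions.

Each residue carries a binary native/unfolded variable; a native
contact contributes energy only when the two residues are joined in one
native stretch — through the main chain (the classic
Wako–Saitô–Muñoz–Eaton picture) or through a *virtual linker* shortcut
that lets two distant stretches interact while the intervening chain is
still unfolded, at the price of a Gaussian-chain ring-closure entropy.
Linker ensembles over all eligible contacts enable discontinuous-domain
folding; two disulfide conventions cover oxidative folding (a large
negative bond energy on Cys–Cys contacts) and disulfide-intact folding
(mandatory covalent linkers with the bond's contact energy removed).

The package computes, exactly:

* restricted partition functions `Z(n)` over one or two order
  parameters (native-residue counts, possibly for non-contiguous
  regions), via a polynomial-time native-stretch generating-function
  solver with single- and double-linker variants — validated bin for
  bin (< 1e-9 relative) against a brute-force `2^N` enumeration oracle;
* free-energy landscapes, basins, saddles (discrete minimax), and
  dominant folding pathways;
* theoretical Φ-values (simultaneous 10 % weakening of all attractive
  contacts of a residue) and degree-of-disulfide-formation profiles;
* folding kinetics: 1D master-equation rates, two-state stability,
  (ε, h) grid fitting, multi-state schemes with barrier-derived rates
  and pathway splits, domain-formation time courses;
* thermodynamics: heat capacity `C(T) = d/dT (k_B T² d ln Z/dT)` and a
  temperature-dependent contact-energy scale.

All partition arithmetic is done in the log domain: disulfide bond
energies of −40 kcal/mol produce Boltzmann factors around `e^70` that
must coexist with O(1) bins at full relative precision.

## Command line

Everything is driven by a YAML config (see `examples/`):

```sh
# generate a self-contained toy fixture (PDB + energy table)
isingfold fixtures --topology compact --n 12 --seed 3 --out fixtures

# free-energy landscape (+ basins/saddles/pathway annotations)
isingfold landscape examples/toy_landscape.yaml

# other workflows
isingfold phi        CONFIG     # theoretical phi-value profile
isingfold phi-ss     CONFIG     # degree of disulfide formation
isingfold kinetics   CONFIG     # 1D folding rate + stability
isingfold scheme     CONFIG     # multi-state populations (2D landscape)
isingfold thermo     CONFIG     # heat-capacity scan
isingfold oracle-check CONFIG   # solver vs enumeration (N <= 14)
```

Model variants: `original1` (uniform contacts from a 4 Å heavy-atom
cutoff), `original2` (energy-table weighted contacts), `linker` (the
full linker ensemble), `linker_ss` (oxidative disulfide folding),
`linker_ss_intact` (disulfide-intact folding).
`examples/lysozyme_ss_intact.yaml` documents the published constants
for the disulfide-intact lysozyme analysis; it requires user-supplied
structure and contact-energy files.

Inputs are plain text: PDB structures and 3-column TSV energy tables
(`i<TAB>j<TAB>kcal/mol`, 1-based). Outputs are TSV/JSON plus a
manifest recording config hash, seed and version.

## Layout

| module | role |
| --- | --- |
| `contact_model` | structures, contact maps, energy weighting, disulfide rules, linker eligibility |
| `entropy_model` | per-residue entropy costs, ring-closure penalty |
| `enumeration` | `2^N` ground-truth oracle (N ≤ 22) and ensemble combinators |
| `transfer_matrix` | exact polynomial-time restricted partitions (0/1/2 linkers, perturbations) |
| `landscape_phi` | ensembles, landscapes, pathways, Φ-values |
| `kinetics_thermo` | master equations, fitting, kinetic schemes, heat capacity |
| `synthetic_fixtures` | deterministic toy chains and fixture files |
| `cli_io` | YAML-config CLI and serialisation |
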