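# Runnable end-to-end example on a generated fixture.
#
#   isingfold fixtures --topology compact --n 12 --seed 3 --out fixtures
#   isingfold landscape examples/toy_landscape.yaml
#   isingfold oracle-check examples/toy_landscape.yaml

variant: linker
structure: fixtures/toy.pdb
energy_table: fixtures/energies.tsv
temperature: 300.0
epsilon: 2.8
h_scale: 1.0
linker_threshold: -0.6
output_dir: out/toy
seed: 3
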