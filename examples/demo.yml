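# Study-shaped synthetic demo: 4 functional groups, ~295 complete-case
# species, 999 permutations / replications.  Replace `synthetic` with
# a `paths` block (traits/groups/cover/synonyms CSVs) to run on real data.
synthetic:
  n_groups: 4
  species_per_group: 100
  missing_fraction: 0.05
  abundance_shape: 0.3
n_permutations: 999
kmeans_n_init: 100
combos_n_species: 295
combos_n_reps: 999
seed: 7
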