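# Desk-scale bench: 6 heterogeneous centers, 16 studies each (10/3/3 split),
# 64x64 slices, desk model, 20 federated rounds. Runs in ~4 min on one CPU.
# Omitted blocks fall back to package defaults (clinical-scale centers have
# 50 studies each; see fedpet.experiment.ExperimentConfig).
simulation:
  n_centers: 6
  n_studies: 16
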