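# Demo FLIM-FRET scene: 10 donor-only cells (mono-exponential 3.02 ns)
# against 10 tandem-construct cells (37/46/16 % at 3.0/2.0/0.6 ns),
# 1e5 photons per cell, analyzed with the published Förster radius.
seed: 0
output_dir: results/flim_run
scene:
  populations:
    - label: donor-only
      amplitudes: [1.0]
      lifetimes_ns: [3.02]
      n_cells: 10
      photons_per_cell: 1.0e5
    - label: tandem
      amplitudes: [0.372, 0.464, 0.164]
      lifetimes_ns: [3.0, 2.0, 0.6]
      n_cells: 10
      photons_per_cell: 1.0e5
  shape: [256, 256]
  n_bins: 256
  rep_period_ns: 50.0
control_label: donor-only
r0_A: 57.1
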