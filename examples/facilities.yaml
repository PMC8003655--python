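# Facility acquisition specs for `gliomaft generate`.
# Each entry maps a facility id to FacilitySpec parameters; omitted
# fields default to the identity transform.
A:
  noise_sigma: 0.005

B:
  gamma: 1.8
  bias_field_amplitude: 0.2
  slice_thickness_factor: 2
  noise_sigma: 0.08
  rng_seed_offset: 1

C:
  intensity_scale: [1.1, 0.9, 1.0, 1.05]
  intensity_offset: [0.02, 0.0, -0.01, 0.0]
  gamma: 0.8
  slice_thickness_factor: 4
  noise_sigma: 0.04
  rng_seed_offset: 2
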