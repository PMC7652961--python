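# Radionuclide registry: physical half-lives in days.
In-111:
  half_life_days: 2.8047
  emission_class: auger
Lu-177:
  half_life_days: 6.647
  emission_class: beta
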