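# schema: sphere_svalues v1
# provenance: synthetic unit-density sphere dose-per-TIA table
# (S ~ absorbed energy per decay / mass, mild absorbed-fraction growth);
# not an export of any dosimetry software
nuclide,mass_g,s_gy_per_bq_s
Lu-177,0.05,4.20e-10
Lu-177,0.1,2.20e-10
Lu-177,0.2,1.12e-10
Lu-177,0.5,4.60e-11
Lu-177,1.0,2.32e-11
Lu-177,2.0,1.17e-11
Lu-177,5.0,4.70e-12
In-111,0.05,1.30e-10
In-111,0.1,6.40e-11
In-111,0.2,3.10e-11
In-111,0.5,1.20e-11
In-111,1.0,6.00e-12
In-111,2.0,2.90e-12
In-111,5.0,1.10e-12
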