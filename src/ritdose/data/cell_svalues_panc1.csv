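# schema: cell_svalues v1
# cell_radius_um: 8.5
# nucleus_radius_um: 7.0
# monolayer: true
nuclide,source,target,s_gy_per_bq_s
In-111,CS,N,7.35e-5
In-111,Cy,N,1.03e-4
In-111,N,N,5.06e-4
In-111,medium,N,1.50e-12
Lu-177,CS,N,3.55e-4
Lu-177,Cy,N,4.02e-4
Lu-177,N,N,6.93e-4
Lu-177,medium,N,4.72e-12
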