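# schema: cell_tia v1
# window_h: 0:16
# note: time-integrated activities (Bq*s) per source compartment for a
# PANC-1 monolayer exposed to 1.2 MBq (2.5 nmol/L) of each conjugate
conjugate,nuclide,source,tia_bq_s
DOTA-In111,In-111,CS,9.24e3
DOTA-In111,In-111,Cy,1.01e3
DOTA-In111,In-111,N,0.67e3
DOTA-In111,In-111,medium,5.91e10
MCP-In111,In-111,CS,2.67e3
MCP-In111,In-111,Cy,1.16e3
MCP-In111,In-111,N,0.40e3
MCP-In111,In-111,medium,6.19e10
DOTA-Lu177,Lu-177,CS,9.77e3
DOTA-Lu177,Lu-177,Cy,1.07e3
DOTA-Lu177,Lu-177,N,0.70e3
DOTA-Lu177,Lu-177,medium,6.20e10
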