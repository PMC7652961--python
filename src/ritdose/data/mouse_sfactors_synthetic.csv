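# schema: organ_sfactors v1
# provenance: synthetic mouse phantom (self-dose = energy/mass; flat photon cross-dose); not measured data
target,source,s_gy_per_bq_s
heart,heart,1.600e-10
heart,lungs,5.000e-13
heart,liver,5.000e-13
heart,spleen,5.000e-13
heart,pancreas,5.000e-13
heart,stomach,5.000e-13
heart,intestine,5.000e-13
heart,kidneys,5.000e-13
heart,whole_body,5.000e-13
lungs,heart,5.000e-13
lungs,lungs,1.200e-10
lungs,liver,5.000e-13
lungs,spleen,5.000e-13
lungs,pancreas,5.000e-13
lungs,stomach,5.000e-13
lungs,intestine,5.000e-13
lungs,kidneys,5.000e-13
lungs,whole_body,5.000e-13
liver,heart,5.000e-13
liver,lungs,5.000e-13
liver,liver,1.846e-11
liver,spleen,5.000e-13
liver,pancreas,5.000e-13
liver,stomach,5.000e-13
liver,intestine,5.000e-13
liver,kidneys,5.000e-13
liver,whole_body,5.000e-13
spleen,heart,5.000e-13
spleen,lungs,5.000e-13
spleen,liver,5.000e-13
spleen,spleen,2.400e-10
spleen,pancreas,5.000e-13
spleen,stomach,5.000e-13
spleen,intestine,5.000e-13
spleen,kidneys,5.000e-13
spleen,whole_body,5.000e-13
pancreas,heart,5.000e-13
pancreas,lungs,5.000e-13
pancreas,liver,5.000e-13
pancreas,spleen,5.000e-13
pancreas,pancreas,8.000e-11
pancreas,stomach,5.000e-13
pancreas,intestine,5.000e-13
pancreas,kidneys,5.000e-13
pancreas,whole_body,5.000e-13
stomach,heart,5.000e-13
stomach,lungs,5.000e-13
stomach,liver,5.000e-13
stomach,spleen,5.000e-13
stomach,pancreas,5.000e-13
stomach,stomach,4.800e-11
stomach,intestine,5.000e-13
stomach,kidneys,5.000e-13
stomach,whole_body,5.000e-13
intestine,heart,5.000e-13
intestine,lungs,5.000e-13
intestine,liver,5.000e-13
intestine,spleen,5.000e-13
intestine,pancreas,5.000e-13
intestine,stomach,5.000e-13
intestine,intestine,1.200e-11
intestine,kidneys,5.000e-13
intestine,whole_body,5.000e-13
kidneys,heart,5.000e-13
kidneys,lungs,5.000e-13
kidneys,liver,5.000e-13
kidneys,spleen,5.000e-13
kidneys,pancreas,5.000e-13
kidneys,stomach,5.000e-13
kidneys,intestine,5.000e-13
kidneys,kidneys,6.000e-11
kidneys,whole_body,5.000e-13
whole_body,heart,9.600e-13
whole_body,lungs,9.600e-13
whole_body,liver,9.600e-13
whole_body,spleen,9.600e-13
whole_body,pancreas,9.600e-13
whole_body,stomach,9.600e-13
whole_body,intestine,9.600e-13
whole_body,kidneys,9.600e-13
whole_body,whole_body,1.000e-12
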