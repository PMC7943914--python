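panel	gene	orientation
M1_polarization	IL1B	1
M1_polarization	TNF	1
M1_polarization	IL6	1
M1_polarization	CXCL9	1
M1_polarization	CXCL10	1
M1_polarization	CD80	1
M1_polarization	CD86	1
M1_polarization	NOS2	1
M2_polarization	MRC1	1
M2_polarization	CD163	1
M2_polarization	MSR1	1
M2_polarization	CCL22	1
M2_polarization	IL10	1
M2_polarization	TGFB1	1
M2_polarization	ARG1	1
pro_inflammatory	IL1A	1
pro_inflammatory	IL1B	1
pro_inflammatory	TNF	1
pro_inflammatory	IL6	1
pro_inflammatory	CCL2	1
pro_inflammatory	CCL3	1
pro_inflammatory	CXCL8	1
anti_inflammatory	IL10	1
anti_inflammatory	TGFB1	1
anti_inflammatory	IL4	1
anti_inflammatory	IL13	1
anti_inflammatory	MRC1	1
ros_apoptosis	SOD1	1
ros_apoptosis	SOD2	1
ros_apoptosis	CAT	1
ros_apoptosis	GPX1	1
ros_apoptosis	BAX	1
ros_apoptosis	CASP3	1
ros_apoptosis	TP53	1
hla	HLA-A	1
hla	HLA-B	1
hla	HLA-C	1
hla	HLA-DRA	1
hla	HLA-DRB1	1
hla	HLA-DPA1	1
hla	HLA-DQB1	1
innate_immune	TLR2	1
innate_immune	TLR4	1
innate_immune	MYD88	1
innate_immune	NLRP3	1
innate_immune	CD14	1
innate_immune	FCGR3A	1
innate_immune	C1QA	1
innate_immune	C1QB	1
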