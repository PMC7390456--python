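# camkinet rate table, version 1
# name	value	unit	group	note
kon1C	4	uM-1 s-1	ca_cam	Ca binding to free CaM, C lobe first site
koff1C	40.24	s-1	ca_cam
kon2C	10	uM-1 s-1	ca_cam	Ca binding to free CaM, C lobe second site
koff2C	9.3	s-1	ca_cam
kon1N	100	uM-1 s-1	ca_cam	Ca binding to free CaM, N lobe first site
koff1N	2660	s-1	ca_cam
kon2N	150	uM-1 s-1	ca_cam	Ca binding to free CaM, N lobe second site
koff2N	990	s-1	ca_cam
konCaM0	0.0038	uM-1 s-1	cam_camkii	apo-CaM to unphosphorylated CaMKII; source prints M-1 s-1, read as uM-1 s-1 for consistency with sibling rows
koffCaM0	6.56	s-1	cam_camkii
konCaM1C	0.059	uM-1 s-1	cam_camkii
koffCaM1C	6.72	s-1	cam_camkii
konCaM2C	0.92	uM-1 s-1	cam_camkii
koffCaM2C	6.35	s-1	cam_camkii
konCaM1C1N	0.33	uM-1 s-1	cam_camkii
koffCaM1C1N	5.68	s-1	cam_camkii
konCaM2C1N	5.2	uM-1 s-1	cam_camkii
koffCaM2C1N	5.25	s-1	cam_camkii
konCaM1N	0.022	uM-1 s-1	cam_camkii
koffCaM1N	5.75	s-1	cam_camkii
konCaM2N	0.1	uM-1 s-1	cam_camkii
koffCaM2N	1.68	s-1	cam_camkii
konCaM1C2N	1.9	uM-1 s-1	cam_camkii
koffCaM1C2N	2.09	s-1	cam_camkii
konCaM4	30	uM-1 s-1	cam_camkii	fully loaded CaM to unphosphorylated CaMKII
koffCaM4	1.95	s-1	cam_camkii
konK1C	44	uM-1 s-1	ca_camkii_cam	Ca binding to CaMKII-bound CaM, C lobe first site
koffK1C	29.04	s-1	ca_camkii_cam
konK2C	44	uM-1 s-1	ca_camkii_cam
koffK2C	2.42	s-1	ca_camkii_cam
konK1N	75	uM-1 s-1	ca_camkii_cam
koffK1N	301.5	s-1	ca_camkii_cam
konK2N	76	uM-1 s-1	ca_camkii_cam
koffK2N	32.68	s-1	ca_camkii_cam
konCaMKII	50	uM-1 s-1	dimer	CaMKII·CaM binding another CaMKII·CaM; monomer model only
koffCaMKII	60	s-1	dimer
kpCaM1C	0.032	s-1	phospho	phosphorylation rate, substrate CaM in state 1C
kpCaM2C	0.064	s-1	phospho
kpCaM1C1N	0.094	s-1	phospho
kpCaM2C1N	0.124	s-1	phospho
kpCaM1N	0.061	s-1	phospho
kpCaM2N	0.12	s-1	phospho
kpCaM1C2N	0.154	s-1	phospho
kpCaM4	0.96	s-1	phospho
kponCaM0	0.00127	uM-1 s-1	cam_pcamkii	CaM binding to phosphorylated CaMKII
kponCaM1C	19.7	uM-1 s-1	cam_pcamkii
kponCaM2C	0.3	uM-1 s-1	cam_pcamkii
kponCaM1C1N	1.1	uM-1 s-1	cam_pcamkii
kponCaM2C1N	1.73	uM-1 s-1	cam_pcamkii
kponCaM1N	7.3	uM-1 s-1	cam_pcamkii
kponCaM2N	0.03	uM-1 s-1	cam_pcamkii
kponCaM1C2N	0.63	uM-1 s-1	cam_pcamkii
kponCaM4	10	uM-1 s-1	cam_pcamkii
kpoffCaM	0.07	s-1	cam_pcamkii	CaM unbinding from phosphorylated CaMKII, any Ca load
konNg	5	uM-1 s-1	ng	Ng binding to calcium-free CaM
koffNg	1	s-1	ng
kcat	0.41	s-1	pp1	PP1 dephosphorylation catalytic rate
Km	11	uM	pp1	PP1 dephosphorylation Michaelis constant
konPP1	10	uM-1 s-1	pp1	PP1 association rate; not printed in the source, chosen fast so that (koffPP1+kcat)/konPP1 = Km
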