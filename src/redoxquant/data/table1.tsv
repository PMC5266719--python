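peptide	accession	description	iodo_fc_5	iodo_fc_30	iodo_fc_120	itraq_fc_5	itraq_fc_30	itraq_fc_120	disulfide_predicted
gQcNAcPSDk	AT1G78850	Curculin-like (Mannose-binding) lectin family protein	0.80	1.24	1.38	0.89	1.10	1.18	Y
lcEcPTVQGVk	AT3G52850	Vacuolar-sorting receptor 1, VSR1	0.77	1.23	0.91	1.00	0.98	1.03	Y
dGIVLNcPHVk	AT3G26370	O-fucosyltransferase family protein, O-FucT-1	0.82	1.38	0.89	1.04	1.03	1.04	Y
sQVQQAVPFLVGcPAcLR	AT4G38350	Patched family protein	0.74	1.21	1.02	0.85	0.98	1.14	Y
aFDMAQcSR	AT4G18030	S-adenosyl-methionine-dependent methyltransferase	0.74	1.08	0.97	0.96	0.96	1.00	Y
gFVGVLHNWcEPFPTYPR	AT1G78240	S-adenosyl-methionine-dependent methyltransferase	0.79	1.12	0.98	1.03	0.84	1.09	Y
vcQVIGAIVDVR	AT5G08670	ATP synthase subunit beta-1, mitochondrial, ATPBM	0.81	1.24	0.89	1.02	0.99	1.00	Y
vLSVLNEATck	AT4G24620	Phosphoglucose isomerase 1, PGI 1	0.88	1.38	0.87	1.04	0.99	1.04	Y
gTcVFPGSAk	AT2G01630	O-Glycosyl hydrolases family 17 protein, GH	0.90	1.44	1.00	1.07	1.07	0.97	N
vPcGYNAPQQVHITQGDVEGk	AT2G16430	Purple acid phosphatase 10, PPA10	0.89	1.15	0.76	1.00	0.91	1.08	Y
gGcYGGMk	AT5G15350	Nodulin-Like Proteins, NLP	0.85	1.57	0.83	0.95	1.03	0.97	Y
aVGScSEcSYTGTFR	AT3G13750	Beta-galactosidase 1, BGAL1	0.56	0.87	1.12	1.03	0.93	1.14	Y
gLVAcTGSQFcGQAIIETk	AT2G15620	Ferredoxin-nitrite reductase, chloroplastic, NR	0.84	1.51	0.87	0.96	0.99	0.99	Y
vcWSTGcFGSDILAAMDR	AT2G05920	Subtilisin serine protease, SSP	0.73	0.89	1.23	0.99	0.92	1.20	Y
hyQDLDFSNVLScAR	AT4G16120	COBRA-like protein 7, COBL7	1.08	1.29	0.96	1.04	0.94	1.02	Y
vDLSMLGTck	AT3G23990	Heat shock protein 60, HSP 60	0.90	1.40	0.74	0.99	1.05	1.00	Y
fAVcLTSGR	AT1G03230	Aspartyl protease-like protein, AP	0.72	1.08	1.17	0.97	0.97	1.11	Y
iLNYVNELcER	AT1G11910	Aspartic proteinase A1, APA1	1.52	0.96	1.17	1.00	1.00	1.00	Y
vGEGPVAQcISGFIALDVAPPR	AT1G11910	Aspartic proteinase A1, APA1	0.35	1.83	1.16	1.00	1.00	1.00	Y
lcVPLVEAQk	AT4G36195	Serine carboxypeptidase S28 family protein, SCP S28	1.03	1.33	0.85	0.96	0.99	1.06	Y
qFNTIPGLMEGTAkPDYATcVk	AT1G15690	Pyrophosphate vacuolar membrane proton pump 1	0.59	0.96	0.80	0.95	0.95	1.06	Y
eGDQcAPQILHVEPNk	AT5G21105	Ascorbate oxidase, Aox	0.95	1.24	0.68	1.13	0.98	1.12	Y
tcAQDEVLR	AT3G08030	Germination-related protein, GLP	0.28	0.43	0.73	0.76	0.75	0.95	Y
tVcVNQHQVANWNDIcLR	AT5G64816	Uncharacterized protein	0.92	0.86	0.64	1.05	0.85	0.81	Y
tPDVTVDETWFSDPELcEASk	AT5G19440	Alcohol dehydrogenase-like protein, ADH	0.86	0.97	0.73	0.97	1.00	1.00	Y
gFHIDGcQASVEAk	AT2G06850	Xyloglucan endotransglucosylase/hydrolase protein 4	0.90	1.20	0.87	0.97	0.92	0.94	Y
gQcNAcPSDk	AT1G78850	Curculin-like (Mannose-binding) lectin family protein	0.77	1.18	1.35	0.89	1.10	1.18	Y
hFEGGDWDQGGTcQR	AT2G14530	Protein trichome birefringence-like 13, TBL13	0.87	1.20	0.91	1.06	0.92	1.07	Y
vHLAGcYIR	AT5G43980	Cysteine-rich repeat secretory protein 56, CRR56	0.93	1.14	0.90	0.93	1.00	0.97	Y
sSNQVGSSAcESPER	AT1G19360	Reduced residual arabinose 3, RRA3	0.97	1.17	1.13	0.95	0.96	0.98	N
eAQMcNVLGR	AT5G25100	Transmembrane 9 superfamily member 9, TMN9	0.83	1.06	1.15	0.95	0.97	1.05	Y
eAQMcNILGR	AT5G10840	Transmembrane 8 superfamily member 8, TMN8	0.84	1.09	1.10	0.97	0.94	1.07	Y
vcQVIGAIVDVR	AT5G08670	ATP synthase subunit beta-1, ATPBM	0.82	1.19	0.87	1.02	0.99	1.00	N
sLcPSEWVDR	AT1G22450	Cytochrome c oxidase subunit 6b-1, COX6B-1	1.13	1.19	0.81	1.07	1.23	0.81	Y
vVVDTGSELTWVNcR	AT3G12700	Uncharacterized, containing aspartyl protease family	0.82	1.10	1.10	0.99	0.93	1.00	Y
ncAPIMLR	AT4G35000	L-ascorbate peroxidase 3, APX3	0.92	1.07	0.97	0.99	1.04	0.99	N
nHcDVAVNSYYQk	AT1G26450	Carbohydrate-binding X8 domain-containing protein	0.86	1.09	0.96	1.01	0.97	0.99	N
gVQGATSHcLGQNFAk	AT3G62120	Proline-tRNA ligase	0.82	1.16	1.07	0.96	0.96	0.98	N
tLNcLPIANIEHFR	AT3G18190	T-complex protein 1 subunit delta, TCPD	1.21	0.93	1.15	0.98	0.94	1.05	Y
eHLcVLk	AT5G20830	Sucrose synthase 1, SUSY1	0.92	1.24	1.10	0.97	0.91	1.03	Y
scSASLAPVILSR	AT3G48990	Oxalate-CoA ligase, 4CLLA	0.98	1.11	0.85	0.98	1.00	0.97	Y
vAVGAPDVLGDcPFSQR	AT1G75270	Glutathione S-transferase, GST	1.08	1.60	0.59	1.00	1.05	0.90	Y
sDDGGADTATDDPcPcA	AT5G20650	Copper transporter 5, COPT5	0.81	0.87	0.99	1.11	0.94	0.90	Y
nAVDmALADSScAGLETTESR	AT1G12230	Transaldolase-like protein, TLP	0.86	1.05	0.77	1.04	1.07	0.89	N
aDWHScLDNR	AT4G35830	Aconitate hydratase 1, ACO1	0.93	0.43	1.03	0.97	0.96	1.02	Y
tTSQDVDESIck	AT4G00100	40S ribosomal protein S13-2, RS13-2	0.99	1.00	1.11	0.98	0.90	0.90	N
rPPLGPGScYAQ	AT3G55260	Beta-hexosaminidase 1, HEXO1	0.99	1.00	1.11	1.00	0.89	1.05	Y
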