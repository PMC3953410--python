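gene	rsid	effect_allele	other_allele	eaf	in_ea_set	in_eaa_set	ref_beta	ref_se	imputed
NEGR1	rs2568958	A	G	0.91	1	0	NA	NA	0
TNNI3K	rs1514175	A	G	0.78	1	0	NA	NA	0
PTBP2	rs1555543	C	A	0.88	1	0	NA	NA	0
SEC16B	rs574367	T	G	0.20	1	1	NA	NA	0
TMEM18	rs11127485	C	T	0.91	1	0	NA	NA	0
RBJ	rs6545814	G	A	0.42	1	1	NA	NA	0
ETV5	rs7647305	C	T	0.95	1	0	NA	NA	0
GNPDA2	rs10938397	G	A	0.30	1	0	NA	NA	0
FLJ35779	rs2112347	T	G	0.43	1	0	NA	NA	0
PCSK1	rs261967	C	A	0.42	0	1	NA	NA	0
CDKAL1	rs9356744	T	C	0.40	0	1	NA	NA	0
NUDT3	rs206936	G	A	0.53	1	0	NA	NA	0
TFAP2B	rs987237	G	A	0.16	1	0	NA	NA	0
LRRN6C	rs10968576	G	A	0.22	1	0	NA	NA	0
KLF9	rs11142387	C	A	0.33	0	1	NA	NA	0
RPL27A	rs4929949	C	T	0.41	1	0	NA	NA	0
BDNF	rs10501087	C	T	0.53	1	1	NA	NA	0
MTCH2	rs3817334	T	C	0.32	1	0	NA	NA	0
FAIM2	rs7138803	A	G	0.28	1	0	NA	NA	0
MTIF3	rs4771122	G	A	0.19	1	0	NA	NA	0
MAP2K5	rs4776970	T	C	0.24	1	1	NA	NA	0
GP2	rs12597579	C	T	0.29	0	1	NA	NA	0
SH2B1	rs4788102	A	G	0.14	1	0	NA	NA	0
FTO	rs9939609	A	T	0.11	1	1	NA	NA	0
MC4R	rs17782313	C	T	0.23	1	1	NA	NA	0
KCTD15	rs29941	G	A	0.24	1	0	NA	NA	0
GIPR	rs11671664	G	A	0.54	1	1	NA	NA	0
TMEM160	rs3810291	A	G	0.29	1	0	NA	NA	0
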