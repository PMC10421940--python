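case	age	gender	histology	tumor_type	subtype	partner	ntrk_gene	classification	fusion_type	tmb	msi_status	novelty	fibrosarcoma
1	1	Female	Soft tissue sarcoma	Soft tissue sarcoma	Infantile fibrosarcoma	ETV6	NTRK3	Definite	interchromosomal	0	MSS	Reported	1
2	1	Male	Soft tissue sarcoma	Soft tissue sarcoma	Infantile fibrosarcoma	ETV6	NTRK3	Definite	interchromosomal	0	MSS	Reported	1
3	1	Female	Soft tissue sarcoma	Soft tissue sarcoma	Infantile fibrosarcoma	ETV6	NTRK3	Definite	interchromosomal	6.9	MSS	Reported	1
4	1	Female	Soft tissue sarcoma	Soft tissue sarcoma	Infantile fibrosarcoma	ETV6	NTRK3	Definite	interchromosomal	0.8	MSS	Reported	1
5	2	Female	Soft tissue sarcoma	Soft tissue sarcoma	Cellular plexiform schwannoma	TPM3	NTRK1	Definite	intrachromosomal	0	MSS	Reported	0
6	2	Male	Soft tissue sarcoma	Soft tissue sarcoma	Infantile fibrosarcoma	ETV6	NTRK3	Definite	interchromosomal	3	MSS	Reported	1
7	3	Male	Soft tissue sarcoma	Soft tissue sarcoma	Rhabdomyosarcoma	LMNA	NTRK1	Definite	intrachromosomal	1.2	MSS	Reported	0
8	4	Male	Soft tissue sarcoma	Soft tissue sarcoma	Infantile fibrosarcoma	TPM3	NTRK1	Definite	intrachromosomal	0.7	MSS	Reported	1
9	9	Male	Soft tissue sarcoma	Soft tissue sarcoma	Soft tissue sarcoma of the abdomen	LMNA	NTRK1	Definite	intrachromosomal	1.2	MSS	Reported	0
10	15	Male	Soft tissue sarcoma	Soft tissue sarcoma	Soft tissue sarcoma of the abdomen	LMNA	NTRK1	Definite	intrachromosomal	0.6	MSS	Reported	0
11	23	Male	Carcinoma	Head and neck carcinoma	Mucoepidermoid carcinoma of trachea	C7orf69	NTRK3	Likely	interchromosomal	0	MSS	Novel	0
12	29	Male	Soft tissue sarcoma	Soft tissue sarcoma	Spindle cell sarcoma of the prostate	RBPMS	NTRK3	Definite	interchromosomal	1.5	MSS	Reported	0
13	35	Male	Soft tissue sarcoma	Soft tissue sarcoma	Prostatic stromal tumor	IRF2BP2	NTRK1	Definite	intrachromosomal	4.7	Unknown	Reported	0
14	38	Female	Carcinoma	Thyroid tumor	Thyroid tumor	ETV6	NTRK3	Definite	interchromosomal	1.5	MSS	Reported	0
15	42	Female	Soft tissue sarcoma	Soft tissue sarcoma	Spindle cell sarcoma of the thigh	LMNA	NTRK1	Definite	intrachromosomal	0.7	MSS	Reported	1
16	42	Male	Soft tissue sarcoma	Soft tissue sarcoma	Mucinous liposarcoma	MORF4L1	NTRK3	Definite	intrachromosomal	0.7	MSS	Novel	0
16	42	Male	Soft tissue sarcoma	Soft tissue sarcoma	Mucinous liposarcoma	PPFIA2	NTRK3	Definite	interchromosomal	0.7	MSS	Novel	0
17	43	Male	Soft tissue sarcoma	Soft tissue sarcoma	Spindle cell tumors of the sacrum	LMNA	NTRK1	Definite	intrachromosomal	3	MSS	Reported	0
18	43	Female	Carcinoma	Non-small cell lung cancer	Non-small cell lung cancer	TPM3	NTRK1	Definite	intrachromosomal	0.8	MSS	Reported	0
19	43	Male	Carcinoma	Small cell lung cancer	Small cell lung cancer	ETV6	NTRK3	Definite	interchromosomal	16.4	MSS	Reported	0
20	43	Male	Carcinoma	Gastric cancer	Gastric cancer	INSRR	NTRK1	Likely	intrachromosomal	44.1	MSI-H	Novel	0
21	44	Male	Soft tissue sarcoma	Soft tissue sarcoma	High-grade spindle cell sarcoma of the small intestine	LMNA	NTRK1	Definite	intrachromosomal	2.5	MSS	Reported	0
22	46	Male	Carcinoma	Intrahepatic cholangiocarcinoma	Intrahepatic cholangiocarcinoma	PHF20	NTRK1	Likely	interchromosomal	42.5	MSI-H	Reported	0
23	48	Female	Carcinoma	Small cell lung cancer	Small cell lung cancer	ETV6	NTRK3	Definite	interchromosomal	14.8	MSS	Reported	0
24	48	Female	Carcinoma	Non-small cell lung cancer	Non-small cell lung cancer	RB1	NTRK3	Definite	interchromosomal	5.4	MSS	Novel	0
25	48	Male	Carcinoma	Hepatocellular carcinoma	Hepatocellular carcinoma	TTC28	NTRK3	Likely	interchromosomal	6.9	MSS	Novel	0
26	52	Male	Carcinoma	Non-small cell lung cancer	Non-small cell lung cancer	AMOTL2	NTRK1	Likely	interchromosomal	8.7	Unknown	Reported	0
27	53	Female	Carcinoma	Breast cancer	Invasive breast cancer	LINC01197	NTRK3	Likely	intrachromosomal	6.1	MSS	Novel	0
28	57	Male	Carcinoma	Colorectal cancer	Colorectal cancer	ETV6	NTRK3	Definite	interchromosomal	180.3	MSI-H	Reported	0
29	59	Male	Carcinoma	Colorectal cancer	Colorectal cancer	TPM3	NTRK1	Definite	intrachromosomal	8.5	MSS	Reported	0
30	59	Female	Carcinoma	Ovarian cancer	Ovarian serous cystadenocarcinoma	ITGA4	NTRK3	Definite	interchromosomal	3.9	MSS	Novel	0
31	61	Female	Carcinoma	Colorectal cancer	Colorectal cancer	TPM3	NTRK1	Definite	intrachromosomal	8.5	MSS	Reported	0
32	61	Male	Carcinoma	Non-small cell lung cancer	Non-small cell lung cancer	COL8A1	NTRK3	Definite	interchromosomal	10.8	MSS	Reported	0
33	63	Male	Carcinoma	Non-small cell lung cancer	Non-small cell lung cancer	PRDX1	NTRK1	Definite	intrachromosomal	1.5	MSS	Novel	0
34	64	Male	Carcinoma	Hepatocellular carcinoma	Hepatocellular carcinoma	PEAR1	NTRK1	Definite	intrachromosomal	6.9	MSS	Reported	0
35	66	Male	Carcinoma	Extrahepatic cholangiocarcinoma	Extrahepatic cholangiocarcinoma	MMP16	NTRK3	Likely	interchromosomal	6.1	MSS	Novel	0
36	67	Female	Soft tissue sarcoma	Soft tissue sarcoma	Uterine leiomyosarcoma	MEF2A	NTRK3	Definite	intrachromosomal	3.8	MSS	Novel	0
37	69	Female	Carcinoma	Colorectal cancer	Colorectal cancer	TPM3	NTRK1	Definite	intrachromosomal	78.1	MSI-H	Reported	0
38	71	Female	Carcinoma	Colorectal cancer	Colorectal cancer	TPR	NTRK1	Definite	intrachromosomal	54.9	MSI-H	Reported	0
39	72	Male	Carcinoma	Colorectal cancer	Colorectal cancer	ETV6	NTRK3	Definite	interchromosomal	56.2	MSI-H	Reported	0
40	76	Male	Carcinoma	Colorectal cancer	Colorectal cancer	LMNA	NTRK1	Definite	intrachromosomal	6.2	MSS	Reported	0
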