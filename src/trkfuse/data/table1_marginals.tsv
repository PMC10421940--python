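variable	level	overall	positive	negative
total	all	10194	40	10154
age_group	Infantile	12	4	8
age_group	Pediatric	157	6	151
age_group	Adult	10025	30	9995
gender	Female	4039	15	4024
gender	Male	6155	25	6130
stage	I-II	3571	11	3560
stage	III-IV	5652	23	5629
stage	Unknown	971	6	965
msi	MSI-H	186	6	180
msi	MSS	9461	32	9429
msi	Unknown	547	2	545
tumor_type	Soft tissue sarcoma	571	17	554
tumor_type	Colorectal cancer	1225	7	1218
tumor_type	Non-small cell lung cancer	2039	5	2034
tumor_type	Hepatocellular carcinoma	1133	2	1131
tumor_type	Breast cancer	323	1	322
tumor_type	Small cell lung cancer	220	2	218
tumor_type	Extrahepatic cholangiocarcinoma	351	1	350
tumor_type	Head and neck carcinoma	175	1	174
tumor_type	Intrahepatic cholangiocarcinoma	555	1	554
tumor_type	Ovarian cancer	261	1	260
tumor_type	Gastric cancer	866	1	865
tumor_type	Thyroid tumor	32	1	31
tumor_type	Gallbladder carcinoma	240	0	240
tumor_type	Bone sarcoma	183	0	183
tumor_type	Cancer of unknown primary	120	0	120
tumor_type	Endocervical carcinoma	104	0	104
tumor_type	Endometrial carcinoma	61	0	61
tumor_type	Esophageal carcinoma	610	0	610
tumor_type	Gastrointestinal neuroendocrine tumor	74	0	74
tumor_type	Melanoma	59	0	59
tumor_type	Pancreatic cancer	498	0	498
tumor_type	Renal cell carcinoma	308	0	308
tumor_type	Small bowel carcinoma	57	0	57
tumor_type	Thymic tumor	33	0	33
tumor_type	Urothelial carcinoma	96	0	96
subtype	Fibrosarcoma	55	7	48
subtype	Infantile fibrosarcoma	12	6	6
subtype	Adult fibrosarcoma	43	1	42
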