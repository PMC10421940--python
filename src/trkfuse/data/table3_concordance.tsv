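patient	tumor_type	dna_fusion	rna_seq	dna_seq	ihc
2	Infantile fibrosarcoma	ETV6 exon1-5-NTRK3 exon15-19	Positive	Positive	Negative
5	Cellular plexiform schwannoma	TPM3 exon1-10-NTRK1 exon9-17	Positive	Positive	Positive
7	Rhabdomyosarcoma	LMNA exon1-5-NTRK1 exon8-17	Positive	Positive	Positive
8	Infantile fibrosarcoma	TPM3 exon1-9-NTRK1 exon9-17	Positive	Positive	NotEvaluated
9	Soft tissue sarcoma of the abdomen	LMNA exon1-2-NTRK1 exon10-17	Positive	Positive	NotEvaluated
10	Soft tissue sarcoma of the abdomen	LMNA exon1-2-NTRK1 exon11-17	Positive	Positive	Positive
11	Mucoepidermoid carcinoma of trachea	C7orf69 exon1-3-NTRK3 exon15-19	Negative	Positive	NotEvaluated
12	Spindle cell sarcoma of the prostate	RBPMS exon1-5-NTRK3 exon14-19	Positive	Positive	NotEvaluated
13	Prostatic stromal tumor	IRF2BP2 exon1-NTRK1 exon17	Positive	Positive	Positive
15	Spindle cell sarcoma of the thigh	LMNA exon1-2-NTRK1 exon11-17	Positive	Positive	Positive
17	Spindle cell tumors of the sacrum	LMNA exon1-2-NTRK1 exon11-17	Positive	Positive	Positive
29	Colorectal cancer	TPM3 exon1-7-NTRK1 exon9-17	Positive	Positive	Positive
38	Colorectal cancer	TPR exon1-21-NTRK1 exon11-17	Positive	Positive	Negative
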