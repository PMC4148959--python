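micseq_id	freq_eur	freq_asn	freq_afr
micSeq11220	0.46	0.54	0.63
micSeq13298	0.11	0.08	0.29
micSeq16601	0.07	0.00	0.13
micSeq18764	0.11	0.08	0.38
micSeq11710	0.00	0.25	0.33
micSeq143	0.00	0.92	0.33
micSeq1824	0.14	0.29	0.13
micSeq2373	0.00	0.08	0.33
micSeq2382	0.32	0.42	0.50
micSeq30	0.25	0.04	0.79
micSeq71	0.29	0.29	0.58
micSeq634	0.14	0.00	0.00
micSeq9196	0.29	0.29	0.92
micSeq349	0.00	0.58	0.75
micSeq28	0.54	0.13	0.67
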