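mirna	logFC	p_value
hsa-mir-130a-3p	1.96	0.03
hsa-let-7b-3p	1.79	0.04
hsa-mir-199b-5p	1.76	0.03
hsa-mir-4787-3p	-2.19	0.02
hsa-mir-4281	-2.04	0.04
hsa-mir-4800-3p	-1.97	0.03
hsa-mir-23b-3p	-1.95	0.02
hsa-mir-4485-5p	-1.89	0.04
hsa-mir-7854-3p	-1.79	0.03
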