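OBESITY_14	14-gene obesity signature	ADAMTS9	NOTCH4	EYS	DHX33	EIF6	GNL3	KAT8	POLR1D	PSMC3	PUM2	RRP12	TCF12	TCF7L2	ZFHX3
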