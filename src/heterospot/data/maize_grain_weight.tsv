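# Hundred-grain weight (g) of the reference maize hybrid and its parents,
# reported as mean +/- dispersion over n measurements.
group	mean	dispersion	n
Zong3/87-1	32.15	0.41	3
Zong3	32.05	0.36	3
87-1	36.93	0.24	3
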