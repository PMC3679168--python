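# Reference mode-count table from a published maize hybrid (Zong3/87-1) embryo
# 2-DE survey: spots displayed per stage and differential spots by expression
# mode. DS = dry seed; 24HAI = 24 h after imbibition.
stage	displayed_spots	additive	++	+	+/-	D	-	--
DS	1140	71	6	12	2	1	8	34
24HAI	1443	125	18	18	4	5	9	12
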