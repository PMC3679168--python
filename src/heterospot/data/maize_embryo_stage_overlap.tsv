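# Differentially expressed spots identified at both stages of the reference
# maize embryo survey, with the mode call at each stage. Spot numbers differ
# between the dry-seed (DS) and 24 h (24HAI) gel sets; the pairing is the
# study's manual gel matching.
ds_id	hai_id	mode_ds	mode_24hai
7543	3462	+	D
7544	3453	-	additive
7551	3479	additive	additive
7529	3460	+	additive
7228	3008	++	-
7163	3093	additive	++
7458	3412	additive	+
7510	3470	+	additive
7455	3405	+	additive
7421	3448	+	additive
7234	3179	additive	additive
7110	2992	additive	-
6674	2614	-	additive
7377	3257	additive	additive
7473	3423	additive	-
7278	3223	additive	additive
7533	3546	+	additive
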