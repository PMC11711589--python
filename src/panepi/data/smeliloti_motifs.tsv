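motif	modification_type	distribution	in_rebase	avg_frequency
ACGGAG	6mA	core	no	0.0872
CCCGGG	4mC	core	yes	0.0595
CGATCG	6mA	shell	yes	0.0864
CTCGAG	6mA	core	yes	0.1927
CTGCAG	6mA	shell	yes	0.0849
CTYCCAG	6mA	core	no	0.0569
GANTC	6mA	core	yes	0.9913
GCCAGG	6mA	shell	yes	0.0162
GCCGGC	4mC	core	yes	0.0605
GCRDB	4mC	core	no	0.0417
RAGCWGCTY	4mC	shell	no	0.0384
RCCAGCC	4mC	core	no	0.1831
RGATCY	6mA	shell	yes	0.0564
TCGWCGA	4mC	core	yes	0.1625
TGGGCA	6mA	shell	no	0.0536
YCGGCCGRV	4mC	core	no	0.0948
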