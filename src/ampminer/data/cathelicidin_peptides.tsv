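id	peptide	length	net_charge	mw
VK-CATH4.1	FRWRRFFRKAKRFLKRHGVSIAIGTVRLLRRFG	33	12	4133.02
VK-CATH4.2	RRWRRFFQKAKRFVKRHGVSIAVGAYRIIG	30	10	3660.39
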