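id	length	mw	charge	pI	anomaly
VkOVOD1_VARKO	45	4930.77	4	8.0905	mw_irreproducible
VkOVOD2_VARKO	49	5582.3	4	8.5149	
VkOVOD3_VARKO	48	4950.69	8.5	8.9348	
VkOVOD4_VARKO	40	4271.9	4.5	8.0913	
VkOVOD5_VARKO	53	5869.76	1.5	7.5215	
VkOVOD6_VARKO	38	4252.89	3	7.8246	
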