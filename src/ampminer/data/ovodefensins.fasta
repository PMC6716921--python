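>VkOVOD1_VARKO
GM*PPHLCFLAMTLHLACSFCGMNFCAGAPRKLWCYCAAQRCCAL
>VkOVOD2_VARKO
GRRRASDTQSCIRREGYCKPQCNETGPVPELNLGTCTNRQQKCCRPQEL
>VkOVOD3_VARKO
GCKGHRSCSSLGGRCAKSCKSLGSGYTAYHTCDCARSGLQCCVPHKKG
>VkOVOD4_VARKO
GYRQHCSSYCHGFCSSKCPQHKVAQANCACALYGGICCVS
>VkOVOD5_VARKO
GLRDWGSEALLCSGSAPISTADFRRWCWGTLALCHGSYAMEYRRGPFCPPCCL
>VkOVOD6_VARKO
RHCNTYCYGQCLKSCPYGWVPTSNCACQHTSNICCLPP
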