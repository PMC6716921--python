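>VkBDic1_VARKO
GLAKRKPRSRRECYSLDGSCYLGRCPSVLKKYGWCGTLKRCCIR
>VkBD1_VARKO
AMGDLYDSLECHNHHGHCRRICFHNERSIGTCTNRRQLCCK
>VkBD2_VARKO
GKGDFVTLGCLFRGGACKTDTCRDNEVQIGNCSNTKQLCCKKTR
>VkBD3_VARKO
GALQDKKGSCDLALHNCRMGFCSQEEIPTGEFCFEPVILCCKHLPEKSKSPERLEGVASF
ADVLRNLL
>VkBD4_VARKO
GGGQREARFVSHCLRRGGICRYDDCSEGEEQIGTCYHHTMICCRDEVM
>VkBD5_VARKO
GASLNLSARICWQRGGRCRSSPCYYDEAQIGTCYHARLKCCRQTE
>VkBD6_VARKO
GHSNEIDTQQCLKDKGTCHPTICPTQKMSKGTCYSGAQLCCVGESVHMCVRPFFPSCCFS
RLSCSRSGGL
>VkBD7_VARKO
GQPHICKRMGGYCQITSKPCPYGFLPTTCGIFQTCCAKKPPTTNDCEKLGGFCRVPLHEK
CPSGQDLPANCGINARCCKPETA
>VkBD8_VARKO
GQVPACTKLGGHCVTPLTVTCPYGSLGANCGINAICCAR
>VkBD9_VARKO
TIGTFLVIQAKLCRKAGGFCISRFAHCPSSEIILIRCRSAQKCCKQ
>VkBD10_VARKO
EGCPVEAMLLTCTSLGGFCMLEPNQTCPSGLILDVPCHFKRRCCSKKEV
>VkBD11_VARKO
GQSLSCRELGGLCVALADDDCDSEEILPADCGRLTLCCKG
>VkBD12_VARKO
EQALRRVPPVQIRSIRRYCNGRDGYCLDRKFFCESGFVYKEEYNDCMFQNKNKCCVIQKS
K
>VkBD13_VARKO
DPSLPSKKAATSRFTTFACNGNFGYCLPRNWRCFSGLVYKEEFNDCPLPDIFKCCL
>VkBD14_VARKO
NKGLPTTTRVGKIPCLGPWGHCFFRKYRCASGFVMKERFNNCPNTRTLKCCVL
>VkBD15_VARKO
GFLHVLARHCQKLGGTCKPHKAQCKVRIQILVPCGPGRKCCL
>VkBD16_VARKO
GGGLQDGEDPPGPRASCNSGRGYCLRCGAACPSGQIYVYNDCANPCSNKCCVRR
>VkBD17_VARKO
GQSSYWGHLSCNSGRGYCLPCHLRCPYGYYYYNDCPGQCRYKCCVRR
>VkBD18_VARKO
APDRVPHEQAPPCNHGLGYCHPCSLPCTSGKYYYYNDCDKPCANRCCTKQ
>VkBD19_VARKO
GTELMEEEYLARAILCHSGQGVCRPRDLQCPSGLTYIYNDCPKTELYKCCAK
>VkBD20_VARKO
EQNRLARSKCVCRKFCYPNEYPMGMCAIILVPMCCTFDPQGGS
>VkBD21_VARKO
VSDKSSSCRSAGGKCYLILCPRGTGRIGKCSFTHVCCK
>VkBD22_VARKO
GRTEVHDVRMCKLYGGECFLLVCPPGRAFIGKCSRLNVCCRG
>VkBD23_VARKO
GLAPDTPHDRSSCELNSGFCYSSNCPRCFGQYGFCDDKHPSCCVRDNSIPGCEVVTTPTY
DKSSKTTAVPTTSETAPPQTAPPQTAPPQTAPPQTAPDESDKKC
>VkBD24_VARKO
GYGLVPAGLSDTIKCRTTPRSFCKAVVCPPTFEPTGTCFGGSMHCCSK
>VkBD25_VARKO
GEFANISNYYQCRHAGAMCAIFKCPAPFNSIGKCGIFKPCCI
>VkBD26_VARKO
GSTEIIGEAKCAEYTGTCRLFECPISSMVENIGYCREDYVCCIR
>VkBD27_VARKO
DGGTCRQLKGFCSTRRCPDKTFEVLGRCTPRKACCQKKANA
>VkBD28_VARKO
GNAQAAEPDTLQCVRAGGSCNFGECRPPSVASGTCKGETLNCCKW
>VkBD29_VARKO
GHSVSNEAECKREGGFCIIAIGNPCRFPYGFIGKCSWWKFCCK
>VkBD30_VARKO
GSARWVKNEDECKEDGGTCLAIVIGGCGPLLQIGICGLGRNCCK
>VkBD31_VARKO
GCSISDRKECREGGGFCLPFLPNMCQVFSIIIGKCSRWSYCCKW
>VkBD32_VARKO
ASTINTSQQCKNAGGHCIWSSCGFPLCPVGRCGYWSLCCKA
>VkBD33_VARKO
GTPASPVRGPLQCVKQGGFCMSGNCRFPLRKLGTCHRFKACCIR
>VkBD34_VARKO
GIYTTLDLEMLSCLSAKDAYCKTGHCLEYSVSLGKCNSYLSCCRSMINNLWRCAIAKGYC
SMWTCPPPLIKNGRCSRDSPCCVQ
>VkBD35_VARKO
GLAMRTERIDSAEECAKIQGFCTSEPECNTVYPIQGTCGEGTLCCLE
>VkBD36_VARKO
TGYTCVLEEILTKEDCELIGATCIDGEDCNPPFPSQGTCGEGTVCCIP
>VkBD37_VARKO
GLTTYVTSPEECESIKGFCTPRLCQENFRTLGECSAGIPCCTR
>VkBD38_VARKO
GFTRDIWDRPTCRSSQGFCWLITCPWPFAKHIGECIWPILRCCA
>VkBD39_VARKO
DLAADCRLREGRCTRTSCSKTDIYLGECAKEIQCCKRDPALHCERQGGLCTQASCTGSDI
NLGPCGRGLKCCKKDPVAHCEAQGGKCVQNSCPTSDVFLGRCGNGFQCCKT
>VkBD40_VARKO
GQPQKYIEKKECMDFGAQCTKAHCGEDYIFYGFCRTGVACCKR
>VkBD41_VARKO
GVALPFQDDSVCIERGGRCMHLPCHPLRRIGRCLLNTYCCH
>VkBD42_VARKO
GSTQFIKLAHKCLDAGGRCQKQACDFRKSIGRCNDQELCCKR
>VkBD43_VARKO
DPVASCASQGGKCTPDICPSNFVLVGQCDQKLLCCKRDPVAHCKSQGGRCMQSRCASNNE
YLGDCGPAVWCCKM
>VkBD44_VARKO
GFAHMGINFREQCQWAEGKCQLYHCPAGWKKIGKCSKVVPCCSDK
>VkBD45_VARKO
GSNPKQCEQKRAQCMIVCPRTHKKVGHCGRSLSCCAQR
>VkBD46_VARKO
GYTSAVARCRRRGGKCHFGRCPQGKNRIGLCFLGTPCCTR
>VkBD47_VARKO
GFTTEIRRARTCIEANGKCRLATCLHDPWERIGKCGDKRFCCKK
>VkBD48_VARKO
GHTFGFLRCRRNGGHCFPRGCPVGWKPRGRCIGRFTCCVRQGKRPAMEKARQ
>VkBD49_VARKO
GHTFGVGECRDQFGSCKFAVCRNGWRRVGWCFLAVPCCRR
>VkBD50_VARKO
GTGQTPGALRCQRNGGLCFPWGCPPGWRPRGRCFGRFTCCIR
>VkBD51_VARKO
GRTSGLVACQRKRGICLVGRCRPGWRQVGWCSRGVSCCKW
>VkBD52_VARKO
GQKPVILRCLRNGGRCFSWRCPSGWMLRGPCLRPFICCVR
>VkBD53_VARKO
GRTFGPPRCRRIGGFCIPRRCPSGWRQRGPCLGPFTCCKR
>VkBD54_VARKO
GTARTFGPARCRRIGGLCIPWGCPSGWRRRGRCFGRFTCCKR
>VkBD55_VARKO
GGSSDGQPVSAPSSARLMRRCRSFYSPCKTCPVLLKELSCQVVHHPCCPPLKLLHL
>VkBD56_VARKO
GCLGVYEKGRRQCCTRNGHCYFLFCKKGTVKIGTCNFFSRCCSR
>VkBD57_VARKO
GLAGENELDQRGCRRRCLVRHCTRRGRFYVCRRYYICCGR
>VkBD58_VARKO
ECLGVYVKGRRQCRTQNGHCYFFYCKKDTYKIGICNFFTICCSR
>VkBD59_VARKO
VSSPEECGRHGGLRLAGPRFSCWSGLLTGHCDAKHRCCKR
>VkBD60_VARKO
ECHGMYVNGKRQCHTQNGHCYFLYCKKDTYKIGTCNFFSRCCSR
>VkBD61_VARKO
GFSWSNDATLRCRYTGGYCDSLICRWPLRNAGFRCKNNRPCCKR
>VkBD62_VARKO
GSARTPRSDLECQVHKGMCFPHGCPAQWSRIGSCSVRKHRCCR
>VkBD79_VARKO
PGPYPCNWVCHTSPGVQSVCSAMPVRLKLLLGLASVCISVSTLCCFRQH
>VkBD80a_VARKO
GRCRRLKGVCRHTLCHPVEVYVGRCNNGMGNCCVDDAEDIRKHIK
>VkBD80b_VARKO
GRRRRLKGVCRHTLCHPVEVYVGRCNNGMGNCCVDDAEDIRKHIK
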