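>Cathelicidin2_VARKO
MELFLLGVTLLMLGVPGATSPPLDAPSALLPRDVARMAVEDFNQEAEGQAVFRLLKLKHT
HKVKFRWGFHFSLNFTIKETHCRKSDNYRIENCRYKTKGPIQDCSAQVSVLNFMPDSPLT
SVKCRRGNGRGSRKAQPSAMLQAEERQPQVHVEVYLPSAYSIAALSVAEEEPSRPAARPH
>Cathelicidin4.1_VARKO
MASPWALPLMLLLLGMVGAAPSTAPPSSYDQVIAAAVDIYNQQQKPEYAFRLLEAEPQPD
WNSSAQTNQVLRFSIKETVCRPSEKADLSQCDYKPDGVDRDCSGFYSPQQSPPTIMVQCE
DVDQELDRVTRFRWRRFFRKAKRFLKRHGVSIAIGTVRLLRRFG
>Cathelicidin4.2_VARKO
MASPRALLLMLLLLRTVGAAPSAAPPSSYEQVIAAAVDTYNQQQKPAYAFRLLEAEPQPD
WNPSAGTTQPLRFSIKETVCRPSEKADLSQCDYKPNGVDRDCSGFYSPQQQSPPTILVQC
EDLDRVTRRRWRRFFQKAKRFVKRHGVSIAVGAYRIIG
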