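>K18_WT tau microtubule-binding domain fragment, 2N4R numbering 243-372
LQTAPVPMPDLKNVKSKIGSTENLKHQPGGGKVQIINKKLDLSNVQSKCGSKDNIKHVPG
GGSVQIVYKPVDLSKVTSKCGSLGNIHHKPGGGQVEVKSEKLDFKDRVQSKIGSLDNITH
VPGGGNKKIE
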