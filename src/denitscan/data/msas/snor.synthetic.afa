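>seq1
DVWQAWYDQDKE--RWWWGQRHWALLEPPMMWFIGWPSDCAHL-VLQANMHQMVKQPIMH
WTEQNI-NSPGALEHTCSRVIPHTPRLECFQGDKSDGIVEQ
>seq2
IVLQAWYVQDKESRRWWWGQRHVATLEPNWMWQIGWPSCCAFF-HLQANMQQLVKQPRRH
WTNQMIMNSPWAPEHICSRNIPSTWRLQCFQGDASDGIVEW
>seq3
I--QAWYDQDKEMRRWWWGQRHWAMLEPPLMWFIGWPSDCAFL-HLQANMVQE--QPIMH
WTEQNIWNSPGAPEHICSRNIPETWRLIWLQGDKSDGIVEW
>seq4
IVIQAWYDQDKEMRRWWWGQPHWDTLENPMMWHIGWPSDCAFL-HGQACMHQEVKQPIMH
WTEQNIMNSPGEPEWICSRCIPSTWYLIKQQGDKSDGIVEW
>seq5
IVIQAWYDQDKMSRRWWLGHSHWITLEPPMEPFIGWPS--AFL-HIQANMHQEVKQPIMH
ATEQNIMN---AAEHICTANIPSTWRLILFQGCKSDGIVEW
>seq6
IVHQAWYWQ---MRRWIWGC--WATEEPPMMWFIGWPSDCAFL-RLQANMHQEVKQPIMH
WTEQ-IMNSPGAPEHICSRNIPSTSRLICFQGDKSD---EW
>seq7
IVIQAWYDQDSEMRRWWEGQRHWATLEPPMMCDIGWPSDCDFL-HLQAVMHHEWKWEIMH
WTEQNIMGSPGAPHHICSRNNPSTCREICDQGDKSDFIMEW
>seq8
FVIQAWYEQDSEMRRWNWGQRHWATKEPGMMWPIGLPSDDAFL-HLQANMHQEVKQPIMH
WTNQNIMSSPGAPEHICSRNIPSTWRLICFQGEKSWGIVEW
>seq9
IMIQEWYDQDQEMRRWWWGQRHWVTLEPPYMCFIGWPSLVAWLWHMQANIHQEVKQDIMH
WWEQNIMNEPGAPEHICSRNIPSTWNLICFQGDKLDGIVEW
>seq10
IVIQLWYDLDKEMRRWWWGQRHLATLEPPMMWF-GWP--CAFL-HLPANMHQEHPQPLMH
WKEQNIMNQPIAPEHICSRNIPSTWRLICNAWDKSDGIVEW
>seq11
IVIQAWYDQDVEMRRWWWGQRHWATLEPPMMWFIGWPSDSAFL-HLQA---QPMKQPIMH
WTEQNISNSPGAGEHICSRLIPHTERMICFQGDKSDGIVEW
>seq12
I-IQALVDQDKEQRRWWLGQRDWATTEPPMMWFIGWPSDCAFN-HLQSNQHQEVKQPIIH
WTSQNIMNSPAAPEHGCQRNAPSTWRLIFFQGYKSDGIVEW
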