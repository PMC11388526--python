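>seq1
KNRVNEMVQRDTWMGGKKEVKTEWIDDCMSPAYNSEWN--VIFVCRPKIDGGASGDYHMK
PYAEMTDKVQGCNCPQMNMDYLAKNELHSCNSSHFSEIPYAGDMDFPLAPSGYPTDGMRH
K
>seq2
---VEELYQSHTMGGGKKEWKTEW--DCRSGAENEEWNHFMIFVCRPKIKSHASGDYIMK
PYLEYTYKVQGCNCPQVN-RSPAKNELHKWNSSSFSEDPYAGDMDFPLQPS---TDSMRH
K
>seq3
KNAPEEMVQSDTMGTLKKE---WWIDDCRSGAECPDWNHFVIFVCRPKISSFASGDYHM-
PYAEYTSKVQGCNCPQVN-RDLAMNELHNCNGSHLSACPYAGDMDFPGAPVEYPTDSMRH
-
>seq4
KNANEEMVISDTMGGGKKEWKTE--DDARSGAEPDESNHFVIFVCRPKIKSHASGDYHM-
-PAEYTDKFQHCNCPQIM-RSLPKNESHSCNSSHFSEDPYAKDMDCPTAWSEYPTDSMRH
K
>seq5
GTATEEEVHSDTGGGGKKEWKTEWIDDTRSIAENEEWNHFDIFVWRPKDKGHASGDWHMH
PYAEYTIKMQGCNCKQVN-RSLAKNELHSCNSSHFSWDPYAQDMDFPLAPSEYGTDSMRH
K
>seq6
KFAHEEYVQSCTMGGGKLEWKTENIDDCDSGAENEGWNWFVDFVCRPKIKSHASGDYHAM
PYAEYTDKVQGCNSPQVN-RMLAKNELHSCASSHVSPDPYAGDMDFPLAPDEYPTDSMRH
K
>seq7
KNAVEEM-----MGGGKKEWKTEWGEDKRHGAEQEEHNHFVIEVCRPKIKSHCSGDSHMK
PYAEYTDKVQGCNCPQVN-KYLAQNRLHPCNSAHCTEDPYAGDMDFPLAPSEYPTDSMRH
K
>seq8
KNADTEKVQSDTSGGCKKKWKTESIDDCRSGAENETWNIFVIFVCRPKFKSHASGYYHMK
PYAECTDKVQGCNCPQVN--SLAKNELHSCNSSHHSEDPYAGDMPFALAPHEYPTDSTRH
K
>seq9
KDAVE--DQVDTMGGGKCEWYTEMIDDKRSGAENEAWNHFVIFWCRPKIKSHASGDWHMK
PYAEHMDPVCGCNCSQVC-WSLAYPELHSCNSSHFSEDPNIGDMDFPLVYSEYPTDSMRI
A
>seq10
QNAVEEMHQSVTMGGGKFEWKKWWLDDCRSGAENEEWNHIVNFVCRPKIKSHASGDYLMY
PYAEYTDKVYGCNCPQVN-RSLAKNELHSCNASHFSEDLYAGDMDFPLAPSEYPTDSMRH
K
>seq11
KNANYEMDQSDTMGGGKKEWKTLWWDDCTSGALNPEWQHFVIFVCRPKIKSHASGDYHMK
PYAEYTDKVQGCNCPQVN-RSLAKNELHSCYKLHFSEDPYAGDNDFPLAPSEYPTDSMRH
K
>seq12
GNAVEEMVQSDTMGGGKKYWK--WIDDCREA-ENEEWNEFVSFVCRPRIKSHALGDYHMK
SQREYTDDV---QCPFVK-RSLAKNELHSCNSSHDEEDPFAGDMDFPL---KYPTDSKRR
W
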