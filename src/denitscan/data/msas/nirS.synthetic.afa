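>seq1
ISTITRC--PTADHINGNNPIANIVPSGCNMWWEE----HNKIPDTNCYGLETMLDNMGD
HDNWV-WSQWKSSHMTMFIWHHTTIMYSTLNYVATCGYWWWEVTYRPVFGWHSEPWRRIF
H
>seq2
CTQITRCIKPTAYHIEGNNPIPNIVPSSCSEKWEE-CIYHNKRPDTNCSGLITMGDNSCD
HDNWVCWSQWKRSHMTCFIWAEGTRNYSTLNQVATCGVWWGEVIYEPVFGWISYPWRCIF
H
>seq3
CSTICRCMKPTADHIEGNEPIPNIMPSSCNMTWEE-CIYHNKIPDTNCEGLETMVDNMCD
HDNWVCWSQWKRSHMTIFIEHETKRNYSTQNYVATCG---GEGTYRPVFGWRSEPWRRIF
H
>seq4
CSTITRCMKPTADIIEGNNPIPTIVPSSCNMKWEE-CIGHNKNPDTNCEGNETMGDNMCV
HNNWVEWSWWKRSHMTMHIVHE--RNYSTLNYVATCMYWWGEWTYRPVFGWHSCPFRRDV
H
>seq5
C-AITRCMKPTRDHIEGNNPCPNIVPSSCNMKWEE-CIYHNKIPGTNCFGLE--GSNMCD
HDNWVCWFQWKRSHMTMFIWHETTRNYSTKNYVATCGYWWGEVTYRPVFGWHSEPWRRIF
H
>seq6
VLTITRCMWPTADHIEGNNNIPNIVPSLCNMGWEE-KIRHNKIPDTACEVLETMLDWMCD
HDNWVCWSQWKRSHMTMFIYQETTRNASTLNAVATCGYWYLELTVRPVFGWQSEPWREIF
H
>seq7
CSTITRCMKATADHIEGRNPIPNIVPSSCNMKVEEHYIYHNKMPDTNCEGLETMGDNMCN
HDNWSCWSQWSVSHITMFIWHETTRNYSFLNYVATTGYWWGEVTYRPFFGWHSEPWRRIF
H
>seq8
CSTITPCMKPTIDHIAGPNPIPNIVPSSCNMKWEE-CIYHNKIPDTNCEGLETMGINMCD
HDNWVCWSQNKRSHMTMFIWHHTTRNMSTLCYVATCGQWWGEVTY-PVFGWHSEPWRRMF
H
>seq9
CSTATRCMKPTADHIEGCNPIPNSVPSSCIEKWEA-CIYHNKIPGTNSEGFETMGDNMCD
HDNYVCWSQWFWSHMTMFIWEHTTRNQSTLNYVATCGYWWCEFTYMPWFGWHSEPWRRIF
H
>seq10
CSTITRCIKPTADHIEGNNPIPNIVPSSCN---EE-CIYHNKTADTNWEGLETMGDNSCD
CDNWVCASQWKRSHMTMFRWHWTTRNYSTLNGRAVCGVWWGEV---PVFGWHSEPWKRIF
H
>seq11
CSCKTRCMCGTADHIETNGPEPNIVHSSCNMKWEE-CIYHNKIPDRNCEGLETKGDNMCM
HTNWVCGESWNRSHMTMF-WHETTRNYSTLNYVATCGYWWYEVTYRWVFGWHSEPWRRLM
H
>seq12
CSKITRCMKPTADHIEGNNPIPNIVPSSIRMKWEV-CIYHNKIPDTNCEGLETIGDNVED
HDNWVCWSQWKRSHMTMFIWHETTRNYSTLEYVATCGYWWGEVTYRPVFTWHSEPWRRIF
H
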