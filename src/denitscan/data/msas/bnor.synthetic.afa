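>seq1
HGSLTRKHGSDVYVLPISRLRAWYAFFCIYYYFYYRNYTQDQDNCNPAFNTGTENSTERS
EVYRHRPVMNNCGAMGPKCTKKSHCYCQLMEAHLMCCKAPPCRWGYAENG
>seq2
HGSLTPKHYWDMDVLFGSRLRAWYAFFRIYYYFYSRNYTQDQDNCNPASNYPTENSTLRS
EVYWHHPVMNGCGAFGPKCTCWSHCYCKWMEAHTMSCMFPPCRWGPAENW
>seq3
HKFTHTKHTSDVYVLFGSRLRAWYAFFCIYMWFVSRNYTQDQDNCNPAFNTGTENSTLRP
ETYRFRPVMNNCGAFSPQCTCWSHCYDQLMEAHLMCCFTLPCETGPAENG
>seq4
ITMFTRKTTSDVYVLFGSCLRAWYAFFCIYYYFYSRVYTQDQDNCNPAFNTWTENSTLRS
EAYRHRSVMNNCGAFCPKCTCWSHCYCQLMETHLMCCKTPPMRWLPAANG
>seq5
HYSLCRMHTSDVYVLFGSRLRAWYAFFCDSYYFYSRNYTQDQDNCNPAFPTGTENSTLRS
EVKRHRPVMNNCMARMPKNTCWSHCYCQLMELHLMCCKTPPCRWGPAENG
>seq6
HGSLTEKMTSDVYVLFGSRLRVWYAFFCIYYYFMSRNYTFDYTNCHYAFNTGTENSTLRS
EVYRHRKVMNNCGYFGPKCSCQSHCYCQLMEAELMV---MPCRWGPAENG
>seq7
HGSLMRKHTSWVYMLCGNRLRHWYAFFCIYEYFYSDNYTQDQDNCNPAFNTGMENST--S
DVDRKWPVMMNCGAFYP-CTCWSLCYCQLMFAHLMCCKTPPCRWGPAENG
>seq8
HGFLTRKDFSDVYVLLGSRLQAWYHF-CIAYYFDSRNYTQDQDNCNPA-NTWTENSTLRS
EVYRHRPVSNNCGEFGPSCTCGSHCFCQLMMATLVCCDTPVCRWGPFWNG
>seq9
HGSLTRKHTSDVYELGGSRLRAWYAFFGIYYYFYSRNYTQFQDNCNPAFDTG---CTDRS
EVYRHMPVMNNCGAFGPKCTCWSHCYCQLMTAHLMCCKTPPCRWGPAENG
>seq10
HGSLTRKYTSHHRVPMGSRLRAWYAMFCIYYYFYSRWY---QDNCNPAFNTGTENSTLRS
EVYMHRPVMNNCGAFGPKCTCWTHCYCQLMEAHLMCCKTPPCRWGPAENG
>seq11
HGSLTRKHTSDVYTLFGSRLRAWYADFCIYYSFESQNYAQDSDDCNCAFNTGTSN--LRS
EVYRHRPVMNNCGASGPWCTEASHCDCYLM--TLMCCKTPPCRWGPAENG
>seq12
HGSLTRKTTSFPRVLFGSRLRAWYAFFQIYGYFAWFRHTQDQKNCNPAYNSGTECSTLRS
MVHRPRPVMNNCGAFGLKCTCWSHCYCSLMEAHLTCCKTPPCRWGPAENG
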