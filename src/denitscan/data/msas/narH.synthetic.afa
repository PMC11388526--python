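>seq1
RALDMQPWPMGQAQYNSFV---CILPPVTAVTMWKELGICPDTSPCPEIVHDDGKQIEIQ
APGDDKYP-IGLGGAAGMLRCEVNSIQVMNVPVFTHTSCIKMTYYMITAS
>seq2
RELQMQPWPMGQAQYNSHVWLPCIYPPVSAVTMWKETGYCPDTSPCPPCQHDDGKHIEIQ
APGDDKYPDICLGGAAGMLRCEVNPISVMNVCSFYHTSCISMT---ITRS
>seq3
RALQMQPWLMGQAQYNMFVWLECRYPPVSAVTDWKEWGGCPDTSPCAPCVHKVGKHIEIQ
APGDGKYPDIPLGGAAGMLRCMVE---VMNVPEFYHTKCIKMTYYMITWS
>seq4
RAGQMQPWPMGQAQYNSFVWLPCIYQPVSAVTMWKERGYVPDTSPCVPCVHDVGKHIEIQ
APGDDKPPDQPLLGAAGMLRCEVNCLNVMNISSFYHTSCIDMTHYMITRS
>seq5
CALQMQNWPMGRAQINSFVWLPCIYPPVGHVTMWKETGLCPDTSPCPPCVEYDGKHITIQ
AYWDDKYPDIPLGGAAGMLRCEVMPISVMNVPPFYHTSCIKMTYYMITRS
>seq6
RALQILPWPMGQAQYTSFVWPPCIYPPVSAVTMWAETGYCPDTSICPPCVRAEGKHIEIQ
APGDS--PDIPLGGAAGMLRCETNPIKVGNVPSFYHTSCIKMEYYMITRS
>seq7
RALQMQPWPQGQAQYNSFVWLCCIGPPKCAVTMWKETENDPDTSPCPPCVHKDGKHIEIQ
APGDDKYPTIPLGGAAGMLSVEVKQISVMNDPSIYHTSCIKMTYYMITRS
>seq8
RALQMQPWPMGQAQYNSF-WLPCIYPPVSGVTMWVETGYCPDTSVCYPCVHDDGKHIEIQ
APGDDCYPDIPLGGAEGHLRCEVNPISVMNVPSFYHTSCIKMTVYMITRS
>seq9
RALQMQHWPHGQMQYISFFWCPCIYPPVSAVTMWKETGPCPDRTPCPPCFHDDGKTIYFA
AVGDDKYPDIPLGGAAGMERVEVNPISVDNVPSFYHYSCIKMTYLMITRS
>seq10
RALQMQPEPVGQAQFNSFVWLPCIYPPVVAVTMWKETGYCNDTSPTWPCVHDDGKHICIV
APGDDKYGDIPLGGAAGCLRCEVNPISVMNYPSFYHK-IIKMEYYMITRS
>seq11
RAVQMQPWPHGQAQYNSFVWLPCIVPPKSAVTMWKETEYQPDTKPCPPCVHDDGKHIEIP
APEGDKYPDIPLGGAAGMLRCEVNPIS---VPSFYHTSCIKMTPYQITRS
>seq12
PALLIQPWPMGTAQYNSFVCLPYIYPPVSAVTMWKETGGCPDTSPCPPCGHDDGKHIEIQ
APGYDKYPDIPTGGAAGMLRCCVNPISVMNVPSCYHTSCIKMTYYGITRS
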