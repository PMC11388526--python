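>seq1
DTLYMVAFHLWLALDRTSGTMWWTEGLTRTRATGDGVDAEQNASFILWWNALMKITHTMV
IQASGPREYLRLGCPIS--HFVGHAV-LEKA-CNKCCCITVSLTQISEADPTHRAGMQNS
N
>seq2
ETHYQVAFHLWAALDRTSGTMWWTKKAWRTRATGDGVDGEQNISFILWWNAIMKSFHTMV
WQASGDREFLRLYWPASHHHFMTHWNNHEKL-CWKTCHITVSLTQISEADPTHRAGWQNS
D
>seq3
ADHYQVAFHLWKALDRRSGTMWWTEGLTRTRATGDGVDAFQEAATILWWNAIMKITHTMI
DQASHPREFLRLGTPASHHHFVGHANNLEKA-VWKTCCIT---TQISEADPDHRAWKQNS
N
>seq4
DTHWQVAFHLWKTLDRTSGTM---EGLTRTRATHDGVDAEQNASFIM--NAIMKITHTMV
NHARTPREFLRLGGPAGVHHFGGHANNLEKA-CWKTCCITVSLTQISFADPTMRAGKGNS
N
>seq5
DTHYQNAKHWWKALDRTSGTMWETEGLTRTRRIGDGVDAEQNAGFILWWNAICKITHTMV
GQASWPREVLRLGCPAMHNHFVIHANNLEQA-FWKTCLITVSLTQGSEMDPTHRAGKQNS
N
>seq6
DYHYFMAFHFWKALDRTFSTMDWTEGLTRTAKTTDGVDNEGNASFILWCNAIMKITHTMI
GQASGPREFLRLGCPASHHHKVGHANNLEKM-CWRTCCITVSLTQISEACATHRAPKQNS
N
>seq7
DTHYQVAFHLWKALDRCSGTDWWTIGLTHTRATGDGVDAECNASFILEWN-KMKQRHTSV
GQLSGPWQFLRLGCPNSHHHFVGSANNLEKT-CWKTCCITVSLTQISEADPTHRAGKRNS
N
>seq8
VTHDQVALLLWMALDWTSGTMWWTEGLTRTRCTPDGV--EQNASFILW--AIMKITHTDV
GQNSGPREFLRLGCPASHHHHVCHANILPTAMHWKTCFIYVSLTQIKEFDPTHRAGKQNS
N
>seq9
DTEYQVAFHIWKALDRTSGTHA-TEGLTYTRTTGDGVDAEQNASFILWWNAIMKIMHTMV
AQH---REFLGAGCPASHHHFVIHANNLEKA-CWKTCCGTVVLTQISEDDPTHRAGKQNS
N
>seq10
DTHYQVAFHLWKALLATSGTHWWTERLTRTNAEGDQVDAEQHASFILWWNAIMKITHTMV
WQAGGPNEFLRLGCPASHSHFVGHASNLEKS-CWKTCCITNSLTQISEADPDHRAGKQNS
N
>seq11
DTHLQVAFHLWKALDRTSGTMWWTEGLTRTRATGDGVDAEQKASFNVWWNAIMKITHTMV
GGASGPREFLTLGCPASHHHFKGHANNLEKA-C-KTCCITVSVTQISEADPTHRAGKQNS
L
>seq12
DTHYQVAFHLWKALDRTSGTWWWTEELTRTRAMGDG-----NAMFILWWNAIMCITHTMH
GQASEPREFLRAGCPASHHHFVCQAFNLEKD-CWKTCCPTVSLMYDSEADPTHRAGKQNS
M
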