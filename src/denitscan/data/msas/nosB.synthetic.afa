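>seq1
DELLRPDQPCTAIWTICEQFCTAYEDASMKTAVYAGRGQANAYYSAMAHELPKYLPTAYM
QTEHTLVEFESKFYERLWPG
>seq2
DELLRPDTPCTQFWTICEQFCTAYEDASML---CAGRGQQPASYSAM--ELPKYLPVAYM
QTEHTLHYFERKFYEDVW--
>seq3
DELARPGLPCTKIWTVGEQFCTAYSDASMLTAERATRGQANAYYSAPLHKLPKYLPTAYM
QTEHTLLKFERKFYEQLWPG
>seq4
YELLRPDLPCNAISTICEQFCTAYEDASMLTAESAGRGQANAYYSAMAHELPFYLPTAYM
QTEHTWHYFERKFYERLWPG
>seq5
DELLRPDLPCTAIWTINEQFFTAYEDASMITAEYWGRPQKNAYYSWMYHEYPKYLPT---
QTEH-LHYFERKFYERLWPG
>seq6
DELLRPDLCCTAIWMICQQFCCAYEDASMPTCEAWGRGQANEYYSAM--ELPKYLPRAYM
QTSHTLHYFEMKGYARLWPG
>seq7
DEL---MLPCTAIWTICEQFCTAYEDASWLTAEYAGRGQANAYCSAMAHELKKYLPTAEM
QTGHTLHYFERKYLEQQWPG
>seq8
DRLLRPDLPCTAIWTICEQNCTAYEDASMLTAEYAGEGQANAYYSAMAHELPKMLPIAYM
QTEHTHLYFERKFYERLWWG
>seq9
DELLRQDLPCTAIWTICEQFCTAYEDASMKFAEQAGSHQANAYYSAVAHELPKYLPTAYM
KTEFLLHYFERKCYERLWFG
>seq10
DEWLRPDLPCTAAVTICEPFCTAYEAARMPTAEYAGRGQASAYYSAMAHLLPKYLPTPYM
QLEHTLHGFERKNKERLWPG
>seq11
DELSRPYHPCTAIWTICEQFCTMLEDASMLTDEYAGRGRANAYYSWMAHELPKYLPQVAM
QTEHTLHYMERKFYEDLWPG
>seq12
DELLRPDLP-TAIWRTPEQECTYYEDASCLTAEYAGRIQAKTYYSAMAHELPKYLPTTYM
QTEHTLHYFERPFYERLWPG
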