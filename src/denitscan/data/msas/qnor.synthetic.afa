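>seq1
INLDTPGYQRILIIANWHYTNQLDIFAFAADDALAPWIFCNHRGRGIHGDEYDEMISIDW
NNCSEWTKPYIAHLYLFWNKYQACRGYAQFSQTEIHTFLFEDFSQKFQNEHYHFPYPADW
YPC--EYFIY
>seq2
INLMTPGGQCILIIANWQYYNCLNIFAFYADDALTPWIYRNHRGSNIHGDEYWEMISIDN
NNCSNWTKPYIAHLYLFWCKYQVFRGYAQFSTRGFHTFLFPDFIDKFQDEHRHFPYTADW
YPCDCEYHIY
>seq3
INLDTQGGQRILIIANWQYTNQLDIFAAYADDAFTPWIYCFHFGYGIHGNEYDEMISIDN
NNSSEWTKEYIAHTYLFWCK-QACRGYAQFSTPGIHTFL-EDFIDKFQNEHRHFPYPADW
YPCDSEYFIY
>seq4
INLDRPGGQRIP-IYNWQYTNYLDIFAFYADDALTPWIYCNHRG---HGDEYDEMIHIDF
NNCSEWEKHYIAALYLFWLKRQACRGYAQFITPGIHTFLFEDFIDYIQNEYR---YRADW
YPCDSETFIY
>seq5
PNLDTPGGQRILIIAAWQYTNQLDISAFYADYATTPWLYCNHRGYGIETDEYDFMISIDN
NNCSEWRKPWIAHL---WCKYQACRGYAQFSWPGYHTFLFEDCIDKFQNKHRHFPYPADC
MPCFSEYAIG
>seq6
YNLFTPGGQRIWIVANWQYTNQLDHFAWYADDALTPWIYCNHRYYGGHGDEYDEMISIDN
NNCSELLKPYIAHLQLLWCKYQAWRGYAQFSTTDIHTFLFYDFIDKLQNEHRHNPYPADG
YWCDWEYFFY
>seq7
RNLDTPGYQRPLIIANWQYTNQQDGFAFYADDHPTPWIYANHRGYIIHGDEYD-MISMDG
NNCSEDTLPYAAHLYLHWCKYQACRGYA-GSTPGIHFFLFEDFIDKFQNRLRQFPYP--W
YYCDSEYFIY
>seq8
INLDTPGLQRILIGANWEMTNQLDLFAFWDDDALTPWIYCNHRGYGIQGDEYDQMISINN
NNCSEWTKPYTRHLYEFWCKYQASRGYADFSTPNNHTFLREDFIPKFQNEHRHFPYPQDW
YRCDSEYFIY
>seq9
WNLDTWGGQRILIIANWPYTNQLDIFAFYADYTITPWIYLNHYGEGIHGDEYDEMISIYN
NNCSEWTKPYISHLYLFWCKYQACRGYGQFSTFGIHTFLFMDFIDKPQNEFWHFNYPADW
YPCD---WIG
>seq10
IYLDTPGGQRIL--ANEQYTNQLDIGAFYRDDALTPWIYCNHR--GIHLDEYDTGISIDN
NNCSEWTKYYGAYLYLMWCKYQ--RGYAQSST---HTFLFEDFIDKFYNEHRHFPNPADW
YRCDIMYFIY
>seq11
INLDNPGGQRPLIIANWQYTWQLDIFAFYADDILTPWIYCNHRGYRIHGDEFDEMISIDN
NNCGYWTKCYIAHLYLFWYKYQACRGSAQFSTPGGHTLLFEDFIDKFQNEHRHFPYPPDW
YPCDSERFIY
>seq12
INLDTPGGQYALIIANWQYTNQLDIFAFYHMDAGTPWINCNHRGYGIH---LDEMISIDN
FNCSEWTKPYIAHAYLFWCKYIACRGYAQ--YPGPHTFLFWDFIDKFQNEHRHFPYPAMW
YPCDSEYWIY
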