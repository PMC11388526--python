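>seq1
TRAHWMTQCQGPGTAWNQCHRFIMRFPNN-WFYGTRMLHPPMWFNTPVLVCKDQQRGENQ
HWSIIVHNRYWNNGGWADTFKNQCDHCQVVMIFTYPMVVEHRTLDCYIQFRMNCDFRQPM
QMCTWQVGEGYKTPLCLPEDP
>seq2
TRAHWMTQVQGWGTVWNACARQIMWHMNN-WVYGTRWAHPPMIFNQLVLVYKDQQRGENQ
HWNQMVHNRYWNNGGWIDTFLNMCSKCQLCMMFTYPMVVEQRTLDIYIQFCMNCSFSQPM
YMCTWAIGHLYKTHSCLVEDP
>seq3
TRAHWMTQCQGWGTNWNQCARQIMELMNN-WVYGNRWLHPPMIFNTMVLVVNDQQRGENQ
HWNQMTHFRLWDNGGWIDTFLNMCVTCQLVMM-TYPMVVVHRALDCYIQFCMNCDFVQPM
QMCTWAIGELYKTPYCLVELP
>seq4
TRNHWMTQPQGWITNWNQCARQIMRPMGQEWVYGTRWPFPPGNFNTLVLVCGDQQQGENQ
HWNQMVINRYWNWGGWGDTFLNMCV---LVMMNTYPGVVEHRTLDCQKQFCSNCDFVQLM
QMCNWAILE--KTPLCLVEDP
>seq5
TRAHWMTQCQGWGTNWNQCARRKMRLQNN-WVYG--WLHRQMIFNTLVLVCKDQQRFEPQ
HWNQMVHNRWWNDLSWIDTILAMCSKCQNVMMFTYPGVVLHRTLDCYIQFCMNCDFVQPL
QMCTWAIQELYKTPLCLVEDV
>seq6
IRAHWMTQCQGKGTNGNQCARMIMYLMNN-WVIGTRWLHPPDIFNTLVEHAKDQQRGENQ
HWNQAVHNRYWTNGGWIDTLLNMCVKCQLVMMFTYPMKVEHRTLDCYVQFCMVCMFVQPM
FMCTWAIWELYKTPLCLVECR
>seq7
T---SMTQCQGWGTNWNQCMRQMMQLHNN-WVYGQRWLHPPMICNNLILCCRTQQRGENQ
HWNQMMHGRYMNNGGWIWTFLNMCVKCWLFMMFTYPMVVEHRTLSCYIQWCGNCDFVVPK
---VWAIVELYKTPLCLVTDG
>seq8
TRAHWMTQCFGWGQNWNQCARQIMRLMNN-NNYGGRWLHPPMTTKYLVLVCKDQQRGENQ
HWNQRVHNRYWNNHKMIRTFLNMEVKCGLCMMFTYFMVVEHRTLDCYIQFCMLCDFVQ--
-MCTWAIGELKKTPLCLVELP
>seq9
TCAHLITQCQGWGTNWNQCARQIKRLMNN-WVYGTRMLHPPMIFNTLVLVC--QQRSENQ
IWNQMVHNRYWNWGGWIDTFLNMC---ILVMMFTFPDVVGHRTLECPPAFCMNCDFVQIM
WMCTWAIGELYKKPLCLVEDP
>seq10
TRGHWMTQCQGWWTNWNLCARINMRLMNN-CYYGCRWLHP--IFITLVLVCKDQQQGENQ
HWNQMVHNRYWNNGGWIDTFLNMCVKCQLVWMYTYPYVVEVRVLDCYIQFCMNADFVQRM
QMCTWAIREFYKTELCLHEDP
>seq11
FRVHWMTQCRGWGTNWNQCARQIMRLMCN-WVYGTRWTHP-MIFNTLVLVCKDQQRGNHQ
HQKQMVHNRYWNNGGWIDTFLNMC---QEVMMSTYLMVVEHRTLDCYIQFCMNCDFLNPM
QMCTWAIGELYKTPLCAVMDA
>seq12
HRLHQMIQCQGWGTNWNQCDRQVMRLMNN-ANYGTRWLHPPMIFNTLVLHEKDQQRGENQ
HWNQPVENRYWNLGGWIDTFLNMCVKCSLYMMFFYPMVVEHRTCNCLIQFCMNCDFRWPM
TMCTWATGELYKTPYCCVEDP
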