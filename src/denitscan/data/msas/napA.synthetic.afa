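>seq1
EKKCKRIAQLTMNNHHKFDTYMRSIVLSMKTICNVVVAGLSWTEVMPSCDEAMADMCNCG
VDNAFAAHICYKFYKWKADGENNTHNSVWKACWCSLLARCQDVSWDAFLLKNCGGSRCRM
KIKWWYDVSE
>seq2
EKKCKRETQLTMNNLHKFITYWWSIDLSMKTICVAVKAGLSWTER--WCTEAMADMCNWG
VDYVFAAHLCYKFIKWCADIENNDHNSVWKACWCSLMARPQDVSWDAFLLKNCGGKRFQM
FQKWWCWNSE
>seq3
EKKCKRQAQDTHNNLHKFDTYMWSIDISMKTICVVVKAKLSWTEVMPSCTEAMACMCNWN
TDNVFAAHLCYKFYKKKADIENNDHYSVWKACWCILMARPQDVSWDAFLLKNCGGKRLQM
KQKWWCWVSE
>seq4
EKKCKRQAQLTFNNCHKFDDYMWSIDLSMWTICVVVKAGLSWTETMPICTEAMACMCNWG
VDNMFMAHLLDKFYKWKADIENNDGNSVWKMCWCSLMARPQDVAWDVFPLKNCCEKRLQM
K--WWCWVSE
>seq5
CKKCKRQAQLTMNNLHKFDTYWWSIDLVFSTICVVVKAGLSWTEVMPSCTEAMADMCNWG
VDNVVAAHGCYKFYKWKADHENNDHNSVAAAHALSLMARPQDVMWDAFLLKNCGGKRLQM
KQKWWCLVSE
>seq6
EHKCKRQAQYTMNNLHKPDTYMWSICTSMKTICVVVKAGLSWTEVMPSCTEAMADMCTWG
VDGVAAAGLCYKFYKWKAWIENNLHNSVWCACWCSLMAQPQDVSWDAFLLKNCDGKRLQM
KQKWWCAVSE
>seq7
EKKCKRQAQLTMNNLHKFATQMWSIDLSMKTICVDVKAGLSWDEVHPSCTECMADNCNWG
VDNVFAAHLCYKFYSWKADIENNDHNSVWKACWCSLMAYPQDVSGDAFLLKNCSGKRLQM
YQCWWCWVSE
>seq8
EKIYKRQAQVTTNNLHKFDTYMWSIDH---TICVVVLAILSWTEVMPSCTEAMADACNTG
VDNVKAAGLDYKFYKWKQGIAYNDHNSMWKACWCSLMACIVDNSWDAFLLKNRQGKRLQM
KQKWWCFVSE
>seq9
EPKCKRQAQLTDNNLHKFKDYAWSIDLSMKVICNAVKAGLSWTEVMPSCTEARADMCNWK
VDNVFAAFLCYKFYKQKADIENNDHNGVAKACKCYLMARPQD---D-FLLKNCGGKRLQM
KQKWWCWVNE
>seq10
KKKCKRQAQLTMNVLYKFDTYMWSIDLHMKTICVIVKAGLSWTEIDPSCTFVMADMCNGG
HDNVFACHLCYKFYKWKATIENNDHNSVWKPCWCSLMAHPQDVSWDAFLMKNCGLKDLQM
KDKWWCDVSE
>seq11
EKKVKRQAQLTINNLHKFDTYMDSIDLSMKTICVVVKAGLSWTEVMPSCTEAMADMCNWG
VDAVAAAWLCYKFAKWKADIENNDHNSVWKKCWCSLLARPQDVSWDAFLLK--QGKYLQM
KAKWWCWVSE
>seq12
SDKCKRCAQMTMNDLHKFDDYMWSIDDSMETICVVVKAGLSWTEVMPSCTEAMADMCNFG
VDNVFAAHLCDKFGKWKADIENNDHNSVWKACWCSLDCRPQAVSWDAPLLKNCGGKRLQM
KQKVWCWVGE
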