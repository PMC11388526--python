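>seq1
EAGRYWWNKYSCCNCTAFMMTKEWNHDMWTVCDSCRYNFHEMHYWKGIHNMNRRQQCLKE
HDDGKGNVMSFYRTTCMRNNPTEQKVAYFKREQKYFYEGV
>seq2
FAGRKWCNKYSCCNCWAPMFTKEWMHIRWTVCDSWDCNFHYMHYWKGI--MNTRQECLKE
HDDGKGNVMAVYNTTCMRSNPTEQEVAYFKREQKCQYEGV
>seq3
EAGWYVWSKYSCCNCCAPMFTKEWNHDRWTVCCPIDENFHECHYWKGIHEMTRRQECLKE
H--GKGNVMYVYRTTCMRSNWQEQKVAYFLRYQKCYYEGV
>seq4
EANQYRWNKYSNCNCCAPMFTKEWHRPSWNVCDSVDKNFHECHYWKGIHNMNRRQCCLKE
INDGK--VMAVYRTTCMRQNPAEQKVAYFKREQKC-YEYV
>seq5
EAGRYAWNKYLCCNCCAFMFTKEWNHDRWTVHDSVDENFHEMWYWKGIHTMNRRQECLKE
HDDNYPRVMAVYRTTCMRE-PTEQKVAYFKREQFCQYEYV
>seq6
EAQRYWWNKKSCCNYCAPMFTKEWNHDRWTVCDSVDENFHEMHYWKGIHLMNNRQECLKE
HDDG-GNDMGVYRTTCMRSNPTEQKVAYFKREQKNQYER-
>seq7
ECGRYWWNKYCCCNSCAPMFSKEWNHDRWTVYDSVDENFQEMHYNKGCHNMNRRQECLKE
HFDGKGNVMPVYRGTCMRSNPTEQKVAYSKREQDCQYEGV
>seq8
EAGFYWWNKYSSCNYCAPMFTKEWNHDCWGVCDSVDEEVHEMHVWFGIHNNNRRQECLKS
HDDGKGNVMAVYHTTVMRSNPTEQKVAYFKREQKCQYEGV
>seq9
EAGRYWWNQYLCSNCCAPMFTKEWNHDRWTVCDTVCENFHEMHYWKGIHNMNRIQECLKE
HDDGVGNVMAVYRTTCMRSNPTEQKVAYFKREQKCQYEGL
>seq10
EAGRYWWNKTSCHKCCAPMFTKEWNHDRETVCASVDENFHEMHYWKKIHNMNARDECFKE
HDDGKGDVFAVYTTTCMRSNPTEQKVAYFKREQKCYYEGV
>seq11
EAGRYWWNKYSYCNCCA---TKEWPHDRWFVCDSVDENMHEMHYWKGSYNMNRCQECLKE
VDDGKGGYMAVYRTTCMRSNPTEQKVDDFKREQECEYRGV
>seq12
EAGRVAWAKY-CCHCCAPMFTKWWNHDRWTVHDTVDENFHEMHYWKGIHNMNRRQECLKE
HDDWSGNCMAVTRTTCMRKNPTEQKVAYFKREQKCQYAGN
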