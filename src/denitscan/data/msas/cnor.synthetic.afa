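>seq1
HCAYNNQTICKRWCQLEDCDVMIGNHKILKMVMTDFRFNDERVIMLFNKYHSAISSKCCE
QRADWHRTSAPIRYQNGNLSSFMSLYADNWVVYPTRQYLKCSNQRDIEMV
>seq2
HWAYRLQTHCKRWDQLSLSDMQKFNHKIVKEVQTDFRFDDERVIMLFNKYHSAIRMKQEE
QRKDWHKWSAPERTDTYNLSSIMSLYSDNWVVYPTRQYLKCSIQRDIEMV
>seq3
HCANRGQTHCKRWCQVMDSDMHIYNHKILKEVHTDFRFDDERFIPHFNKYHSAKSSKNCE
CRADWHRTSAPIRYQNGNLSIIMSLYADNRVVDPTRQDLKCSIQRDISMV
>seq4
KCAYRLQTHCKHWCQLMDSDMHIFNHKILKEVHYKFRFDDARVIMLFNKYHQAIIDTQCE
QRPDRHPVSAPIRYQNGNVSSIMSLHADKSVVYVTRQYLKVSVQRKIEMV
>seq5
HCAFRLQTHGKRWCSLMDGD--IFNHKILKEHHTDFRLDDERVI-LFNYYHDAIISTQLE
QRADWHRTSAPCRYQNCNLSSIMSLYADNWVVYPTRQYLKMSIGRDILMV
>seq6
HCAYRLQTHCKRWHQKMDSDMHIFWHKAIKEVHNIFRFDDVYVIMYFNKYNCLIISKQCE
QRADWHRTSAPMRMQNGNLSSIMWLYADNWVVYPTRQYLKCSIQRDIEMV
>seq7
HCAYRLQTHVKRNCFLMDSDMHQFNHKILKEFHTSFRFDDERVIMLFCKYHWAI---QCT
QRADWHRTSAPIRYQNGRKSSVMSLYADSWVVYPTRQYLKCKIQRDIESV
>seq8
HCNYRLQTHCKRWCQLMTDDMHIFN--ILKEVHTTFRFDDERVRMLFCKYHSAIIEMQCE
PRADWHRTSAPIRVQNGNLSSMMSLYADNWVVYPTRQYLKCSIIRTIQMV
>seq9
HVAYRLQWHCKRWYFLMDSDMHIHNHKILKIVHTIFRFDDFRVIMLFNKKGSAFIQKQFI
QKADIHRTSANIFYHNGNLSSEMSWVADNWVVYPTRQYLALSIQRDIHMV
>seq10
HCAVRLQTHCKR-CQLMDSDMHDMNF--LFEVHTDFRFDDLSVIMPFNRYHSAIISKQFE
NRADWHRTSAPIHYQNGNLSSIMSLYQYNDVVYPDRQYQKCKIQRDIEMT
>seq11
HCAYRLPLHCKRECQLMQSDMHWFNHKILKEVHTDFCFFDEWVIMLVNSYHSIVISKKAE
QRADSHRHSRPIYYMNGNLSSIMSLYCDNWVVYPTRMYLKCSIDQGSEMV
>seq12
HDGYRLQTHCKRWCQLMDSDMHIFNHQILKEVHTDFRFDDSRVIMLFNKYPSSIISKQCS
QRADWERTSAPIRYQNVHLSSIMSLYADNWVVYYTRQYLKCSIYRYIEMV
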