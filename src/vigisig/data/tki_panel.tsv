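canonical_name	class	synonyms	reference_reports
afatinib	EGFR		9539
dacomitinib	EGFR		325
erlotinib	EGFR		20030
gefitinib	EGFR		7571
icotinib	EGFR		207
olmutinib	EGFR		372
osimertinib	EGFR		8115
rociletinib	EGFR		12
lapatinib	HER2		11005
neratinib	HER2		469
tucatinib	HER2		666
axitinib	VEGFR		10655
cediranib	VEGFR	cediratinib	143
tivozanib	VEGFR		164
erdafitinib	FGFR		240
futibatinib	FGFR		9
infigratinib	FGFR		19
pemigatinib	FGFR		46
asciminib	BCR-ABL	ascriminib	164
bosutinib	BCR-ABL		4742
dasatinib	BCR-ABL		19384
imatinib	BCR-ABL		39207
nilotinib	BCR-ABL		16465
ponatinib	BCR-ABL		4245
alectinib	ALK		2630
brigatinib	ALK		779
ceritinib	ALK		1996
crizotinib	ALK		8699
lorlatinib	ALK	lolatinib	1800
fedratinib	JAK		290
pacritinib	JAK		39
ruxolitinib	JAK		16025
acalabrutinib	BTK		1362
ibrutinib	BTK		29650
zanubrutinib	BTK		292
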