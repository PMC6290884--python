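# version: toy-met-seed2024
hmdb_id	canonical_name	kegg_id	pubchem_cid	metlin_id	synonyms
HMDB9000001	rafelu	C90001	900001	70001	rafelu figipine|rafelu rupemi
HMDB9000002	vudavafave	C90002	900002	70002	vudavafave dulatage|vudavafave sonovusifa
HMDB9000003	fipuru	C90003	900003	70003	fipuru rarutedu|fipuru ruzime
HMDB9000004	nirafi	C90004	900004	70004	nirafi memadepebe|nirafi depebi
HMDB9000005	zotipe	C90005	900005	70005	zotipe vufudedobi|zotipe zenunu
HMDB9000006	desite	C90006	900006	70006	desite dotuburele|desite zefisutu
HMDB9000007	vufegotiga	C90007	900007	70007	vufegotiga tonozo|vufegotiga vogutabenu
HMDB9000008	datize	C90008	900008	70008	datize fodamisapo|datize boduranu
HMDB9000009	vogeteni	C90009	900009	70009	vogeteni pavano|vogeteni gazola
HMDB9000010	nugufale	C90010	900010	70010	nugufale tufobira|nugufale fatatesu
HMDB9000011	fevupula	C90011	900011	70011	fevupula lutuzutezu|fevupula durafamo
HMDB9000012	demodedafo	C90012	900012	70012	demodedafo zaropo|demodedafo nemusavelu
HMDB9000013	lolugogi	C90013	900013	70013	lolugogi patilobi|lolugogi romafodo
HMDB9000014	vedipezi	C90014	900014	70014	vedipezi zarapuru|vedipezi niligivo
HMDB9000015	pimimuzi	C90015	900015	70015	pimimuzi ratefefi|pimimuzi mutova
HMDB9000016	leridi	C90016	900016	70016	leridi losufasuzu|leridi bigerataga
HMDB9000017	bagubo	C90017	900017	70017	bagubo talugevu|bagubo bazebu
HMDB9000018	befibu	C90018	900018	70018	befibu dofuze|befibu sonanolumo
HMDB9000019	basemopo	C90019	900019	70019	basemopo pesovomi|basemopo nofonivepa
HMDB9000020	supegi	C90020	900020	70020	supegi tuniregeno|supegi bidipe
HMDB9000021	pagamedose	C90021	900021	70021	pagamedose goradide|pagamedose tefuzu
HMDB9000022	meleba	C90022	900022	70022	meleba morame|meleba gobapirefu
HMDB9000023	pifosugazu	C90023	900023	70023	pifosugazu rivitu|pifosugazu bupubevi
HMDB9000024	zapofepe	C90024	900024	70024	zapofepe dunimona|zapofepe gilegi
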