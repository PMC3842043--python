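family	supergroup	dna_box	representative_domain
ASCa	A	CACCTG	KRNMMEKWRAMSVNLILSGLRKYDGKMSTNMGKCTPCCKHHKTWILNRAVRYINEL
ASCb	A	CAGCTG	RKCAWDERNRWIKINAHFMHLKTSTLMHYDECICNEHKQKITKGWKHHVLGLATGYVLLL
MyoD	A	CACCTG	KKHITCVERCRNKRLNVLIRFLRDTYASYWEAYCYYTQDEKFVKMSVLTPAIYYLKGL
E12/E47	A	CAGCTG	RRYMQTKERRREYWVNNYLDELKDCCPYIVTKMHYANLAWMRKDKAVTLCKAIKYVSNL
Ngn	A	CACCTG	KKEEGMFERHRSQNVNWHITLLKLCQNWEWVKPRCPMIRSINFRWYKQSILAVAILYIDHL
NeuroD	A	CAGCTG	RRLSIWFKERKRHTALNPEFCLLRIFRQWFPCTIQVCSHSPKDAKVLTLRYATRYLYWL
Mist1	A	CACCTG	KKVAQEKMRTEIINAAFEPLKWEISYAKKEEHTEDYMLTSKKRKSKKRILFDAVWYLEKL
Mist	A	CAGCTG	KRDLLEKNRRFYINVKFRVLKWNNNMDNIPHYHKWRNMQGRHNKITVLEAAINYLWDL
Beta3	A	CACCTG	KKHPHNERFRPRGLNGPFVPLRIQHMWETPQERHLGREDHRMQKTCTLHKATPYIPVL
Oligo	A	CAGCTG	KRCHSKEKRRTSWINVNLHDLKKHLPTMWPMTFRHCCLWMWGDKDGKNKTLWQATHYLTIL
Net	A	CACCTG	RKMEEIEKVRCFFINIFICGLKEEDYDNCFDMEDTCEYDSRNKKSSILGGAVHYVCHL
Delilah	A	CAGCTG	RKLEGACSEKQRANIVNYMLDILRFVCVMPGSIIGFVMMYEIRYIKQVVLINATSYILDL
Mesp	A	CACCTG	KRVGKYAFEKMRQTDVNDFIETLKTHGSPPHLLDPPTWKRPHLKPIKAGVLPQATKYIMTL
Twist	A	CAGCTG	RKFKNFYEKARHKPLNCTLSWLKLALICSELMMPPYRNQQERIRWGKEMTLMDAIQYVLQL
Paraxis	A	CACCTG	RRPYMNIAEKKRNRTINPSIEHLRWNSKWWSPMPGVWEMLISCRDIKGVILNHATNYVPYL
MyoRa	A	CAGCTG	KKHYCMCREKVRRNYVNFEILCLRYAPRHNSKEDDHKPCDMQRTHKAFTLLKAVVYVYLL
MyoRb	A	CACCTG	RKSGIIVERSRCMWVNQVFEFLRSKRIEELMTMKEPYADVIKKRCKSYTLPTAICYINHL
Hand	A	CAGCTG	KKPLHQTEKMRLMLLNIYLNDLKETRREKVWKHVEMFNRSANKHRKFNILLGATCYVPGL
PTFa	A	CACCTG	RRQSAFERVRHNDINCQLPMLRDMVTAAKNVFIMGVRHPRMRKKYVLRSATYYVSEL
PTFb	A	CAGCTG	RKSPLERWRGYAVNRAIVDLRFICCEHLMHLSGSVVFERIQRCTKNKILIWATGYLYEL
SCL	A	CACCTG	KRIGMERSRDLCINNHFEALKWSQKQQVIHWYFGCDPQCRKIAKYPTLLHATVYVARL
NSCL	A	CAGCTG	RKANKRAPEKYRKDNVNKALAALRLIPIHFHFNPLWKKFGTDCKLKKHDTLPKAVQYVGRL
Figα	A	CACCTG	KRKNNEKEREHNINSIFDHLKLRISWQLPCMRMSGHTHRRFKPITLPHAITYVTLL
MYC	B	CACGTG	RRATTYEKWRFCFLNKIIGWLKQFEWCAWHLDNTNGQAFCIYKSIKGDTLIMAVLYITSL
Mad	B	CATGTTG	RKKGDERIRALMLNEMISNLKDSVEEIAANYSKQSDRQITSRMNKCFTLHWATFYVDFL
Mnt	B	CACGTG	RRCLVLERLRDVDVNHILEQLRERIQPIGSATRGAWLQCPCPRKYPKITVLHYAVCYLMFL
MAX	B	CATGTTG	KKKQVQVPEKGRFVPLNYGLFMLRRNIHRHISYLQFAGKCTKWCKVRILQMAIVYICCL
USF	B	CACGTG	KKFSGPPAEKSRLQVINYYIRQLKDCEVIHEIEVGFFAPPEYLQKEGKPKTLTAAVQYLKAL
MITF	B	CATGTTG	RRADLLDEKNRPHEINIEIKCLKCFCWSEDKWEEIPAVNMVQCKFMKAFILQRAIMYIEPL
SREBP	B	CACGTG	KRMAENVEKPRHMALNEEIRPLRDHKCSSYTRVATIQNQHFQMVRIAKRQILSDAVTYVPGL
AP4	B	CATGTTG	RRNSDKERNRMVEVNSVFGYLKMYMQGNSDAHKRTLLWWSKFRWYKVAVLYDAIVYIYSL
Mlx	B	CACGTG	RRSWPRERHRFLCINLELWFLRKHAKGCRYYPCAYCQRVKKHFILIQAIPYILSL
TF4	B	CATGTTG	RRKHVQCGEKHRIKKINEKFYGLKTGGHGGLSFSNWCFVEKWVKVRTLMLAVWYLWGL
SRC	B	CACGTG	KRFKGCNERCRRIDVNVQFFKLKVRTMYWWWWHIDGDLQESEPKWEKITILGGATGYIAVL
Clock	C	ACGTG	RKNSFRVEEKCRCIRLNSRIKPLKLKTQDRQIKIQHIKAQGHRKHPKTLILTEATCYIQDL
ARNT	C	GCGTG	RKTAMFVDERFRLFDLNWCLEILKGQPFETEHPHEISWYQKKVKRDILFYAIGYVPTL
Bmal	C	ACGTG	KKIDNQPEKFRTRLVNVDIQRLRICSNFHKAAITHHWHKIYKFCILKFAVDYLYHL
AHR	C	GCGTG	RKYHVEKCRKYKVNMNIYKLKNVFKQGNCSWYWVRSCHLVCCTRVIKIIVLEKAIAYVNYL
Sim	C	ACGTG	KKVQIIEKDRLLDVNLELCYLKSIVEGRHTDLNQSMKRRILKPNTLVVAIIYINML
Trh	C	GCGTG	RRQHRSEKRRYVQVNYWILGLRNCLKETAHVTQMMMHHPMKHKNQKYLTLRQATFYIIML
HIF	C	ACGTG	KRWLTPQSEKERHANLNRLLLTLRMDMHQQTNFIIHWWHSFMIGRAYKQIILTPAINYINRL
Emc	D		KKEWSCTTEKHRHMNLNTNIKYLRAMLTPPMEQEVYTCYCGIILFKRPTKPAILCCATMYLEFL
Hey	E	CACGCG	KKYWHEKWRHPEINRQLKALKVWEGIARCPDQGIGHVDRDVKTIVLMIAVEYVNGL
H/E(spl)	E	CACGAG	RKCYQYEKGRMREVNWALDSLKTWKFRSVYKCLMYSDMYYCRSGKKQILLSATYYLGLL
Coe	F		KKVPGSERNRGTGLNKYLRMLKVKWKLCTWCGIALLPNPGKSLGKQHKMYVLNHATWYVTRL
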