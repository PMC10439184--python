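>AAG10475.1
MAMLDGIVVRYAFTWSYDWGLTANLIGLMPIIIFCSGGGSVVAMVAFAIGILLVLTRLAY
VFDWYNGNKVAKNVGYTLIVRVVKDHGFAQDTRTFLYPYDHVYNLACAGQIDIYLIGTHH
IVTGVTGLVNAKPTNYFYPFTFTLADTYTASMKRWLADIPGSGQYGMLGYGGSLGGDRGM
LSNLKLTIFIAGLTIFATIDNCLRLVTSGVDHPLKAGGKTLPALGLFTIAVIEVDLSVIV
FYWGPFANG
>AAK30179.1
MAMLDGFVVIYAFTWSYDWGLTANLIGLDPIIIFCSGGGSVVAMVAFAIGILLSLTRLHY
VFDWQNGNKVAKNVGYPLIVRVVKDGGFAQDTRTFLYPYDHVYNQACAGQIDIYLIGGHH
IVTGVTNLVNAKPTNYHYPFTCTLAATYTWSMKRWLADIPNSGQYIMLGYGNSLGGDRGM
LKNLKLTIFIAGLTICATIDNCLRKVTSGSTHPLKAGGKTLPALGLFTIAVIEVDLKVIV
FYWGPFANG
>BAN14807.1
MFMLDGIVVRYAFTWGYDWGLTANNWNHMPIMIVCSGGGSVVAMRAFAIGIELVLRRLAY
VFDWYNGNKVAYNSGQTLIVRVMKWHPFWQDTHFFLYPYDHCYKMACAGQIDIYLIGTHH
YVTGVTGLVMAKPTQYHYPGTWTLADTYTYSMKRWLADIPGSGQYGMLEYGGSFGGDRGM
LSNQKLTIFIAGLTIFATISNCLRAVTSGVQHYLKAGGTTQPAKGLFTIAVIIVDLSVIV
FYWGNFANG
>AAZ21446.1
MAMLDGIVVRCAFTWLYDWGHTANLIGLMPIIIFCSGLNSVVDMVAFAQGILLVCTRLAY
VFDWYNGNKDHKNVGYTLIVRDPDDAGFAKDTRCFLYPYDHVYNQACAGQWDIYLIGTHH
WVTGYTGNVNAKPTNYFYPFTFTIADTYTAGMKRFLADKPGSGQYGMLGYGGSLGGDHGM
LSNLKLTIEIAGLTIFATMDNRARLVYSGVDHPLKAGGWTHPALGLFTIAKIEVWLSVIV
FYWGPFANG
>SYNPR001
MAMLDGIVVRAAFTWLYDWGLTGSGIGLNPIIIFCSGNGSVVVHIVFAITELLVLCRLAY
IFDWRNGNKVAKMVGYTLEVTQVKDHGFFQDIRTFLYPYDHNYNLACAGAIDIYVIGTAH
IVTGGTWLVNLKMTNYFYPFTETWAPTYDASMKRWCADIPGSGQYTMLGYGGFPGGDIGM
PSNLTLTIFAAGLYIFMTIDNCLRLVTSGVDHPLNAGGKTLPALGLFTIAVIVVDLSVIV
FYWGGFAHG
>SYNPR002
MAMLDGIYVRCAFTWKYDWGLTENLITLMPIIIFISGGGLVWAMVHRDHGILMWLYILAY
VVDHYCINKVAYVIGYTLIKDVVKDHGFAQDTRTKLYPYDSVANMACAGQIDIYLITTHH
IVTGVTGLVNAKPTNVFYPFQCTLADTVTASYKRWDADIQQSGQYSMHGYGGSQGRDRGM
LSNLKYTIFIAGLTIFATIDACLRKTTSGVDHPWKAAPKTLPWLGLGETAVIENDLSVIV
FQWHPNANF
>SYNPR003
MAIFDGIVMRYAFTWPYMWGLRANLWGEMYIIIFCSGGGSVVAMVAFAIGICLVLTRLAY
VDDWYNGNKVAKNVGWTLIVRVVKDHVFAKDTRTFLYPSDHVYNLAKAGFIDIYLITTHC
IVTGVTGLVPAKTTNYFYPFTFTLADTYTASMKRWLAPLPGSGAVGMLGNGGSLGGDLGM
ISTLKLTIFIASLRIFATTDNELRLVTSGVDHPLKAGCKTLDALGLFTIAVIAVDLSVIV
FYWGPFANC
>SYNPR004
FAMLDGIVGRYAFTWWYSWGLYADLIGLMPIIIFCSGGGHVVAMVAFAIWILLVKTRWAY
VFDWYNGNKVACNVGYTLIVRVVKDLGFAQDTRTELTPYDHVYNQACAGQIDIYLIGTHH
ICAGVMGGVNAYPTNYNYPFTFTLNDTYTASMKRWEADIPGSGQYGRLAAGWSLGGDRGC
LSNLCLTIDIAGLTIFATIDNCLRLVDSGVDHPLKAGGKSLPALGLFTIAVIEVVLSRPV
FPFGPFANG
>AIN36550.1
VGCLEGGANRYDVTASRDWGHRLNLIGSQPIHQACSFGRWVRAHVDGGIKMLEELTRFTC
LMMTRPTCKVALWVDYTHIVRKISDIKFVSDTHVFLYQYVHELNLMCATIIDITLCWTTH
VDWFVKQVQTRKNTWTEYPFYREHADDYWAPQIGWLQDDGAKAQVKMNGYNTSGTGGTVQ
GYPLKLTIFRKVLVYEVVYFNPVRLVMSAVEYPTCPWGKGLVALACFTCARIDEELRAAM
AYCDPFACQ
>ADY17811.1
SGCLECTHNRYDRTAPADVGHRMNLIGSQLIHQACSMGRSRRAHVDGGIGMLCYLTTLTC
VMMTRVTPKVALWVDYTHIVRKISDHKFVSDTHCFLYQYVGELNLCCARSIGITLCFTTH
VDWFVQGVVCAKSTNYEYPFYREHADHYWAPQIGWPQDDAAIAQYKMNGYNTNEWGGTVQ
GYPRKLTIFRKVLVWEVVIRNQVRLVMSAAQYPTCPLGKGLVAAAQFTHAVIDEELRVAM
AYMDPFACI
>ADY17809.1
SGCLGCGHNRIDRTASCDWGHRANLRGSQPIHQACSFKRSVLEHVDGGIGMLEYLTRLTC
FGMARITDVVALYVDYPHIYNKISDHKFVSDTHVFLYQYVHELNLCCARTIGITFCRTTH
NDWFVKGVVTAKNTNYEQPFYFEHADHYWAPQIGWLQDDAADANYKMNGYNTSEWGKTVQ
GYCLKLTIFRKPLVYEVVIFNHVRDVDSAVEYPTCPWGKGLVAKAQFTHAVIDEELIVAI
AYCDPFACG
>ADY17808.1
SGCLECGHNRFDRHASCDWGHRANLIGAQPIHQACSFGRSVRAHVDGGIGMLHYLTHLTC
VMETRITWKVALWMDYAHIVRKISDHKFVSDTHVFLYQYVHELNLACARIIGITLCFTTH
VDWFVKGVITAKTTNYWYPFYSENADSYWAPQIGWLQDDAAKAQYKMNGYNTSEWGGTVQ
GYNLKLTIFRKVLVNEVRIFNHVRLVPSAVEMPRCMWGKGLVALIQFRHFSIDSELQVAM
AYCDSFACG
>ABV22426.1
SECLECGHNRYDTTASCDWGHRANLIGSQCIHQATKFGRSVRAHVDGGIGMLEYLTRLTC
VMMTRITIKVALWVDYTHKVRKDSDHKFVSDTHVFHYQYVHELRLACARIIGITLCFTTH
VDWFDKGYVTAKNTNQEYPFYRHHADYYWATQIGWLQDDAAKAQYKMNGYNTSEWGGTTQ
GLPLKLTIFRKYLVYEVPDFCPVRLVMSAVEYPTCPWGKGLVALAQFTHAVIDEELRPAM
AYCDPFRCG
>ABV22432.1
SGCLEPGHNRYDRTASCDWGHRYNMIGSQPIHQACSFGRSVRAHVDGGIGWLEYLGRLTC
VAMSKICWKVALWVDYTHIVRKISAHKFVSDTECFTYQYVHYLNLACARIIGITCYFTPH
VDWFVKGVVTAKNTNYEYPFYREHADHYWAPQIGWLQDDAAKAQYKMNGYNTSEWRGTVQ
GYPLKLTIFRKVLVYEVVIFNHVRLVMSVVEYPTCKWGKGLVASAQLTHAVIDEELRIAM
AYCDPFACG
>AAO14677.1
SSCLECGGNRQRRTASCDWQHRANLVRSQPIHQASSFGRSCRAHVDGGIGMQEYLTKLTC
VMMTKIIWKEALWVDQTHNVVKISAHKFVSDTQVNLYQYVHEINLACARIIGITLDVTTH
VDWFVQIVVNAKPTNYEYPFYREQADHYWAPQIGWLQDDAAKAQYKMNQYNTSEWGGTWQ
GYMLKLTIFRKVLVYEVVIWNHIRLVMSAKEYPTCPWGNGIVALAQFTHAVIDEELRVAM
AYCDPWACG
>AEF32711.1
SGCLECGHNRYDRTASCDWGHRANLIGNQTIMWACSFGRERRAHVDGGVGRLMYLVRLTC
VMMTRITWKMALWVDYTHIVRKISDHQIVSDTNVFLYGYVDELNLACIRIIGITLAFTTW
VDKFVDGVVTAKNTNYEYPQYREHADHYSAPDIGWLQDDAAKAQYKMNGYNTMEWGITVQ
GYPLKLTGFRKVLVYEVVSFNHVRLVMSAVEYPTCPNGKRLVAAAQFTCAFIDEESRVAM
AYCDPVACG
>ABV22427.1
SGCLEQCHNAVDRTYSCDWGHIANLIGSQPIHQKCSWGRSVRAHVDGGIGMHEKLTRIQC
VYMTLITEKVALWVDYTHIVRKISDHKFVSKTHVFRYKYIHELNLACARIIGITLCFTTH
VDWQVKGVWTAKYTNYEYPFYREHTTHYWAPQIGWLVVDAIKAQYKMNGYNTSIWGGTVQ
GYPLKLTIFRKVLVYEVWIFNHVRPVSSAVEYPTCCWGKGLHALLQFTHAVIDEEKRQAN
AVCDMFACG
>ADY17806.1
SGCLECGHNRYDREFSIDWGHHANLIGSQPIHQACSFGRSVNASVDGGIGRLEYLTRLTC
VMMTRITWKVALKVNYTHIVRKISDHKFVSDTHVFLYQYVHELNLACAEIIGITLCFTTH
VDWFVKGVVLAKNTLYWYPFYREHQDHYWAPQIGALQDDAQKAQYKMNHYNTSFWGGCVQ
GYECKLTIFRKVLVYEVVIFMHVRLVMSAVEYPTCPWGKGLDALALFTHNVIDEELRVAM
IYCDPFACG
>AJA37445.1
SGCINCGHNRYDRTAYCDWGVRQNLILSQPIHQACSFGRSVRAHVDCGIGMLEWLTRLTC
VMMTRITWWVALWVDYIHIVRKISDMKFVSDTHVFLYQYAHELNLACARIIGLTLCFGNH
VDWFVLGVETDTNTNYEYPFYREHADLYWAPQVGDLQDDAAKMQYKMNGYNTSEWGETVQ
GYPLKLTIFRKVLVYECVIFNHVRLVMSAAEYPTCPWGKGLVALAQFTHAEIDEEKVHAM
AFCDPFACG
>WP_011404249.1
SGCLECGHCRKDRTASCDWKHRANLIGSHPIHQACSFGRSVRAHVDGMIGMLEYLTRLTC
VMMYRITWEVALEVDYTHIVRKISDNKSVSDTHVFLYQYVHEENLACALIIGITLCFPTH
VDWKVKGVVTAKNTNYEYPFYREHADHYWCPQIGWLQRDIAKAQYSDVGYNTSEWGGTQQ
GYFLKLTIFRKQLVYEVWIFNHVRLVWSRVEQPTCPGGKGLVAQAQFTHAVIDEELREAM
TRCDPFACT
>AEP68177.1
SGCLECGHNRYDRTLSCDWGHRANLIGSQPIHQACSFGRPHRAHVDGGIGMLTYLTRLTC
VMMFRRTWFVALWVDYTHIPRKESDHKFVSDDHVFLYQYVHELNLACARIIGITPCFPTH
VLWFVKGVVTAKNQNYEVPFYREHADHYWAPQIGWLQDDAAKAQYKMNGYNTSEPGGTVQ
FYPLKLTIFRKVLVYCVVIINHVRLVMSAIEYPTCDWGKGLVFLAQFLHAVIDEELRVAM
AYCDNFACG
>AKG94905.1
SGCLECTHNRYDRMASCDWGHRWNLIGSQPIHQACSFGRSNIAHVDGGNGMLEYYTRLTC
VMMTRETWKVAPWVDYTHIYRKCSDHKFVSDTHVFLYQYVHELFLACERIIGITLCQTTH
QDWFVKPVVEAKNTNYHYPFYREHIDHYWAPQIGWYQDDAAKRQYKMNGYNTSETGGTGQ
GQPLKLTPYRKVLVYEVVIFNHVRLVMWAVEYPTCPKGKGLVALAQFQHAVIDEESRVLM
AYCDEFACG
>BAC88139.1
CGHLNCNAGRYQRTASCDSGHRAKLDGSVPRHQACSFGRTWRSYVEGGAGHAWYLTRLTC
VMETRNTYLRYLWPDYIHMLLFWSTPKFVPDTHMFLACYVHEFNLAPARIIKIHTPFTTL
VDWFVKGSVTAKNTNFEYPMYHEYAYENWALQIHWIMDDAAKAQYQFNGYKTHLWSGTCG
GAILCHTIRRKVLVYTSVIFNHVRLVCVVWERPTCPGGLHPVALPMFTVGVHDEECEMAT
AYCDDCHVG
>SYNBR001
HPKKTWRSHPNALPHMSIAELNLTWEKCRVHKIFEGWGWPVYLMLSYAFHCLLVLQRLAY
QMTWILKNEKLAQMHYSQFRKVVGNHGWAQPTLEVNLPFAHWLNLTLPEQIQAYLLGNYH
DVKTVSGAANALPSNYRMPFFKALADSYTCVMQDWPQEHNGSGEYGMRKYDKSTRARYQI
KMNNWLTEFGICLTIDHYTAFFYLCVIADTHVHGDAIHGSLLMLRRTCIEYNMPDMMTIS
KGGGMFANY
>SYNSRI001
HDKMRCAGHPNENHHMNCAGLYLYWNKCRVQAIFEDNGWWVYEMWKFAFVCLPKWRRLAY
QLDWYVLNVMKKAMHYKQVDAVVLNHGKMQMTKEVNFFFRFRLKLTSPWQRQPTLLKFVH
DVYLAGGPCDALPENTQMCFFDAYADIYKTAELDWPQEHGNSGEYLARKLDRNQRARLVI
KDNNWVCCFGICLHIDIYCDTFYLGVTNDQKNHQDYTHGYLLMERRTCIEYNRPDDMYIS
KGTGMFHAT
>SYNACTR001
VNMAIGAVTLWAFGFLRMWRQTFNMSFQFMDWWTQSFSEMPELDLMFVGQLLPVHTRKRC
QVMPENLNMRGRLVWLVFVIRVKQYMIFAQTTPHFEANYQSKYNLPSQGQIMRYLIYDNL
ICTRVDPYGNAGCNYEAYPARFLTCDTSTISESAWRNGIPGKAGYDTLGFYGSLGCTRVQ
LQYIICTTKEAGMTICAKVDNTYMLKRSSVMLACKAGKMTERALDLFIKDNLEVILSPGV
YDNQPLYNI
>SYNESR001
VWMESLPVTLWARGFLRMWAHFPNMGFQFMDHPHQYHSEMPELDIMFQGQLNPVATGKRK
QVDYLNGSKDIRGVWDVFVQRCKGYMINPQNFPRFKQNYQSQFNLPKQIQDMHYLFPDGL
ICYRVNPLGWCGCPYPAKHALSYTADYHLISEHAAVIQNTGAAGYDTLGCYGSLACWRVA
LQYIFCTTFEFWVTICATVANTCMALQSHVPLACKAGKRKWKPLCLHIKDNLEVTPRGGV
WDNQPEYYI
>SYNVIR001
MSWTCGNPGRYYFTWSWAWHLFIKSITVSPIPIYPANWGSVYQDHAKAIWICQNQSSLEY
DFDWVENNKGMKYTKYALMQTVCAYFGYACETITCREDYQHTYGLARAGQMDADEAGTVQ
QVELYVIMYNAKFWTWNYKGTEEDTTQATMSEFRWLMQIHPGGWIYFKYYNVWFPTPNGM
LCFFKLTEFVSQEHLWACIINIFRSNTSGIDVSLASGGRVTHKHMLAMIMVGEVEKSCIH
PCKVPHSFG
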