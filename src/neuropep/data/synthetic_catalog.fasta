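>PQ049256 AKH-1
FFSIPSWSTPPVVFFWWLVLVQVNFSPNWGKR
>PQ049257 AKH-2
TGFSIGAIMFWMPGTPLGQVNFSPNWGKR
>PQ049260 ACP
ILWFFAALIASVSVFPVWLSFFSMYNGKRYVGFMTPGNQLKRSEYIVDDINVWNIYNHFV
AFQHLSKRTVSHFDDILHLWQKRTNVLEMDPGQQFEVFWKR
>PQ049261 AT
IFGPGVVGLMAAWTPTIWSIWPAVTIEFFQTMNIIDHSWIVPDFAYTPYAASKRDMLMAP
PFTQKRGVMILNLVDGQQYWIDGKRSFDFQALNMNDWYKRLMMVPVFAWDDGGWVAEVQG
MIDHQGKR
>PQ049262 Ast-A
ALPFLTPSLAVIILSGPFSLIYFFVVFYDSVMAGKR
>PQ049263 MIP
WLLSPLLILSALAVMFAVLPIQMWTVSMHGYMTTVKR
>PQ049264 Ast-CC
VTGMWITFVGFMWTAVLGFPNVVSLQYEMVPFLPWFNGQWHGKRHTEAYLTVGINMHWSQ
MKRTDFAWWFHHMPANWPVNHWYEWHTKR
>PQ049265 Ast-CCC
WTPLWVPIWIGATMPMWWSGPFGIHDHYEHMYDIEDDHIIFQIGKRGHEPIHHYLDYKRD
MQWWHASNGTAIAGAITTMNMSPVIDKRSHWDFDLTLVKRHWYNGIIWIDSIDFPDGGQM
ALYIYDFMSAGKR
>PQ049266 Inotocin
MLGPIFFPVLATLLTFFTIHGTTMIQSNHIPYDDKR
>PQ049267 Calcitonin-B
GTPDWAGTAWMSNQQVMYPEFQWKR
>PQ049268 DH-31
GVMAFFTSWVALGPILVFIGAQETTDLPIHVIGIDTDSHLVSDQAAGALPKRHYSWWWFA
NKRAFSHDMSVESTIDPYVFSAFYAEAQVQLDKRLILYDPDHIEWYDEMKRSLPQSESMT
VVDVEWWKR
>PQ049269 DH-46
SSLAFVFLWPVSTPSAVVGMGMGGWQMNHGGETNVEVHNYYYVLKR
>PQ049270 CAPA-PVK
APFVSIFMVSVALIPTAVNWMINLVDWADQYNYFNDSQQNGKR
>PQ049271 CCHa-1
TIWTLWSLFTLIAPVMTMLGTMWAHGMPPSMYNYFLAPYANHPYTWYPNGKR
>PQ049272 CCHa-2
AMSSWFFLFWTMLWLAAPSPGGMYWINLLWNLMNDTEGYLHGKRLEYPLTVWPKRFAFYT
YFVDIQNFNVGKR
>PQ049273 CNMa-A
NLDDELDMITLAHGFYTQSDAKRYPHYSVAFQPFWKRMTWFNYNTLEVSHGKR
>PQ049274 CNMa-B
PIMPWTWFLWPFWISPSFPATFPIHWPKRDGNFETVKRLYFHASHNHFIENLLDFTPMGK
R
>PQ049275 Crz
FPGIGMWGIAPVTMISGIPMTWFIQMFGMEGKRVVAYFEYNGFVKRWDSQYENGNPPVLV
NYGIHLYHTITHVTFSGKRTYENTTADPVTKRVWHDLEGQKR
>PQ049276 CCAP
GAFWGVTVGSWGVGMAFLSMGHLLGDLGTWPEEKRFTQYTNLTHNDMSLVSKRNLAHEVF
DSVSHVQMGWKR
>PQ049277 CCRFa
LPLIPAGFLMIFTWWVMLAVMFVSQMTASDETVNQQAHALKRDPTTDIGNIEDYSFSYPK
RMVFYAQLFWYPGHDDENGKRSFGTFHDLFPDYWIPEKRHPDNDQGANSTSFQIGKR
>PQ049278 Elv
FGLVWVWFAAGTLTFAPPFLFSAHQDDIFTLMYMMMEFGKRLPINYITAIQHIWEPVKRI
HFTQHTHELWDVYYHLWSDEAYGFTNGKR
>PQ049279 FMRFa
IPIFMLSMVGLIIPTGVATVVNYDQEYEMDYLYPAHNQSQSVESGKRIHEMEWILEHKRH
PILWYVQYDQYYIQKR
>PQ049282 Hansolin
AFWAMISAPVGFWGTTLMGVFSSWMMTVTSQHSPLNVNSIDFSDVFTIYGKR
>PQ049283 ITG
VFLSGFLFGPMVWTSAGFTFAWPLINIVPGWVFTNMAVTQTDWIYVALSKRMSMADTSMH
QIKRLDSWWEIVADYESIDDMAIMWGTTTFDMSGKR
>PQ049286 Kinin
GLWWGMGWMIGWSAPVLFLPMMMFPDYTGFSYTSNLGKRGETAIFLEKRSNMGVVVTPWY
VNVAVKR
>PQ049287 MS
FVVGPPPVLFVGMFSLPPPWTEMNVMTLWNFYAYSQVTGTDPSPKR
>PQ049288 Nat
LIFFWTTGTFMMIGFSVTLIAPVTWSLTEEAEQGTKR
>PQ049289 NPF-1a
LTVTVWFTLMTIIATTLVMTVPAWAHEHTQLGMWMLSPYSFEVVIDMGKR
>PQ049290 NPF-1b
GFYHQILHNNIGKR
>PQ049291 NPF-2
TFFTFMVAMSPPIFMAAASLMFHDHTGEVPGKRTHEAAAQDKRFHNGPVPINWYPHHTVV
LVFGTYWYGKRWTMHELYIEPQDAYPIKRYYLYTQNGLTPQAEEYGMMALMSFNAGKR
>PQ049296 Orc-A
PAIIVSAPFSVGVFGPGFDMTFMIAGKR
>PQ049297 Orc-B
AVYHNGKRNQNTLAFEPNYIMPKRFILYYYNSKR
>PQ049298 PDF
SWASPLGSSSVLFGLPLMGLMNSEIINSLLGLPKVLNDAGKRFNTDHITFQVLKRDSVTI
AHHIMPMPLMGLEDVFDTYGWPGKRLWDSGLFLMGGIEFYLAKRSHGFLPEDFEFEDGWL
EIDDIAHIKR
>PQ049299 PK
PVGILFLVTMPMTVFMMLWPHDQIWWYYTGWYQFVHGKRSEVMPFSWTSPELEMKRWNFA
VQPGKR
>PQ049300 Proctolin
GVSWVSASVTFAPMSLGTLIPRYLPTKRNGEILDMGPELWPPQSPKRMAPWAHGQVWSTI
MDHAFKR
>PQ049301 RFLamide
LTTGLFAPLTMLVSLTPWMPNWITIMHGGTIQIQYTAPSGKRILYPAEHQEGVMGFKRHN
VAHPTESAFKR
>PQ049302 RYamide
GMVTWTFSPPIAAGTWMFIMAVGDQHDIGKRNGAAEIVPHDETQTFQKRNDITHAFLSFD
TTQADGWYGKRWSHYITGFMHWDGFLTQKRMMTPLGPQKR
>PQ049303 sNPF
LGVTFWTWIVGWTTPFTWGHMENIGKRWNEYTPIGVKRWSPHGYNSVHMLNYAGPMGKR
>PQ049304 SIFamide
PTMTLPPISFWSVAAVAGPGGFWNGNFLFTYGMIWHGSNFIHTEHVEFPKR
>PQ049305 SMYamide
TMFFSPAAFMIWMGVTSAPIPWNGQGPIAAVFMGFFSITLTSFPIVTKRDGSDGNEAIKR
NNPGNPVILQLIVSGKRNPLWTYDSFGHIFSYKRNVTNWLQFTKR
>PQ049306 SK
SPAIILLWGFMGAVGFFTWFAFLTWTQNTLMLYGKRGSTTPAKRDIPWDMAYMVDPSNPY
QKRDLILEQVSKRDSISLVTMHNTLDEIMIAKR
>PQ049307 TK
ITPPMMPLVPTIVFPPFVFPLVYNVTEGIHDFEWKRHPIAGPNYTMFPPNKRTAAMQTWN
QLKR
>PQ049308 Trissin
SVGLLSFVGVWLLWLGTMPWGLNFGFHGYLQDFPYHITQHNGKR
>PQ049258 ALP-1
VWFVAPLTFLTFPALIPLSMSTSVIGATQYHAFNLGLDTTLTGKR
>PQ049259 ALP-2
LTSLFTGKRYPTNLQHLPQNDDKRAFWWNKRVYSPEQKRYGHQQHNFSNQQTMAPSSLKR
>PQ049280 FERLQ-like
MSVGLSGAPVATSMVVTTTGPSVLHHHAEQKRWPWTDITGDHFPIGAWSKRMWPHNTMLT
YDNNGKR
>PQ049281 Flik
ATAWAIFPSSMASTIGMGFGTAGNQNWVGHGVYAPVSEDNQGPKRVWWTAEENNDKRWIY
LGFITATGAVSVFAQGKRGIPPYSAMLTFFVQKRFAFFADVSMYGQEDFGNGAFPNHMNP
DGKR
>PQ049293 NPLP-1
TTLPWMMPILMWFSSVSAIVPAAPVLLQNEHHPLGKRGDLDAVKRVVMNDFSWPDYGEVA
FMQYDWEKR
>PQ049294 CNPLP-1
ISLVAVVTMATPVFSGVVAFASVFAWQVGIYFTITWTQMSVYNVGSKRVDSHSEDIKRMV
LSFGWFVAHMEYLPQGHTTFHLQEKRVIWHGMQITVKRTWVGEFDSAFDEDNQWWQQEHA
GKR
>PQ300805 NVP-A
ASWIWSMPFWTWWIGVTLLSMDNSQWGGFAKDKR
>PQ300806 NVP-B
GGGPVTIGAVLIWMGIPSPWASVPMTEADEVLMFSFEIEMLWFIANAPLGSITSTKRTSW
QVIKRDVSDGGSEDLHVWNIMNHSGMAASMKR
>PQ049309 Bursicon-alpha
TIEWPWDGQWLQAHEEWPLFFATGTDSYHSLTLDQAPVPTDAYVYSIAFDTNWPPIFSSM
TFDMGATHFPFYAIFNLNSEDAVIPYMKR
>PQ049310 EH-1
GVTLAWPATLLLISSSTVAVVYMQMDTAAQLYFLQETMWFEAQPVSENVPEVTDELPSAF
EVTGLFNQVMYQSINPHIGVDPQTTFMVTTSANSAISIHFKR
>PQ049311 EH-2
PFFTIFMPMIVAFGPWSFFLGGNMNLWVQILDHWMQWATIWSMNTGNQYYNLLAQFEFEA
FLMGAVEIQVNYNFYSSHFYWWFPPWSWYNYVEKR
>PQ049312 GPA
VWSSVPAGITGPIVLFMIMSPSPLTDVEHMHTETLQDQEVDHHNHYQYHELNWPTIDYYE
TTDHGETIGIVVAFWQAKR
>PQ049313 GPB
MSMGVSVIWPVVMIGWILSSVVWFGYMHMEDSGPHFAAWGAWIHMWDYHIAAMYMGAFQS
VQGDPNQPSSMPAIHIYGYYPSWHYTTFQAPQVLDLMNNDQWSVFFNGEMNSGHAGTKR
>PQ300807 IDLP-A
GAWVGAWMIPVLALFTPWGLHAIFAYNLVNWELMGYWSYLVPTMLYYLPYMISQHNPQEM
TSTMWNNMEAAPFEHFSVSGHWTDMEFILHSFNHMASTNHNMWSYVALTAEMFADETMMH
SHNSKR
>PQ300808 IDLP-B
WITPMFPMFVWFFWVMTLAAWMPTTEIFYMMASPMGFMWYVPNVDYVFDFPSTLIDEIQH
TWVPQYQWGVMGWADMSATWNVLATLLVWQQADAIYMHNIVNIYSSFMTDQTFGDSQMLF
HIAVEDYQENIWWFAFQKR
>PQ049316 ILP-1
PMMILSLTVTLVPVPWTVFWPFTPAPMIMYHDTDEPYNGSQVWAQVTISWTLQENMQWYL
SAFIQYPYGYGMPVKR
>PQ049317 ILP-2
MLASAPTGISPPMLSFLAWFVGTSEHMVTYSSAPMLFIMWFYFWHLSGSEPSDVVFDIGL
YMAPFASFPHTYIHEKR
>PQ049318 ILP-3
NPNGEFNENIALEVSHQNDMTQSIDSTYPELAEMSLQFPPAPVVSFFHEYQLSMTTYMIV
EPYHHYQQPKR
>PQ049319 ILP-4
MITVWGWTFFFLGIWITWGGHAYFLNLTLIPLQDTDDPSHTTQQGDDYWQYPTYGIPAQD
VWSGDVIWGAQSVLMWFSMFHGFSMASFSMEPQAMDHMVWFSWAYQNPYTLFTVVSDNQA
HANPWLYGTVQKR
>PQ049320 ILP-5
AGPSFFGWMGWPILSPTGTMIQYWTATEQDAINSLQEDGYHYLIGWIGQVQVNSNPMFDA
ANVLGFEHSGWNWDTYLLFDTDHEEMLDWKR
>PQ049321 ILP-6
TMAISWMSLFFVFVILWGFFFWGIAHIQTALTFPAEDSEYMEMAIMQLSFGLQFQDLSEG
FTYEVDWGPQLQAMEETMQTWKR
>PQ049284 ITP
APWPPVWFLMSIPGLGPAMLSALFDNTAHITNSHHVFNLPMLEHGIIGHFNFLDPQQGYF
LWTFFEIWSASISGSHLHTQVVDNYLAFNGNDWHGMGLQQDFNNGWLHLLYWFIHGLAIT
LFHKR
>PQ049322 Neuroparsin
YGQPNVQWQMMWELWQNAFVWPFLPSIEEHYYVPWHHWANWDVMGGNQLNNESLVIWEAM
NAAVIGGFHNGEAQINALEWHQIPPEETIHWSMQAAVSWNVTFYGSAHEIQINYTNKR
>PQ049323 PTTH
GVFLGSGFSLIMTWTIITTMMVHSAHLEGPIGQFAAGYLYWDPPYIQDFSFEFYTSGLLL
FVNIFQNMEIHLWHENDMFFSMIPHTIFYQSEKR
>PQ049324 iPTH
MPVSFMTLFFPPVPFMAVVAAFWTWHIYWWEAIAENIHDTHATEHLHSDHMENYGSNEFS
QLFIDAHMNNDSFIPQQEEALLFGDEWSVTHFPDSVQLATNGEPAHILKR
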