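>MT-ND1 synthetic mtDNA-encoded protein stand-in
PFFAAILMVGNEVLFTQHVITFPMALVAVVPMRVNTSFATMGTPILMMRRGRSVVNRCEM
TPVASTGHTLVPAWRGIPVLRFRGITLDMLYWFNPATIGIFIFGKAKIWAKEAAAVLGAK
CILMGMANGDLHKMVPAMYPEVLPSVPINLIGCTGMMDGQQKELICGMHMIFAKAVKVDT
GMPRMVHKLYPFGYLLAFAVVPRGLHYARWIVPVLMVSVFQAFMFIIPMLFAVAPMWMYM
FGGDNIVPMMFPCITHGMIVMVQEEVAPVTLEPLGADTNFPYMVPCARDMILYYNNVHNG
QAERAFVLGLLMEGVGTY
>MT-ND2 synthetic mtDNA-encoded protein stand-in
FLQIPIQAHGVKKRPASGAMDTIAPFLAKNDAKRQTMPMVNYMFMRVKTLMIMEPTPTRT
IIKGMLWKWLLDIVMLFMIMRSRALVAKIFYAFPMIGEKGETYILTMSHPLYVYWEMLTY
QNCIMDYLAGMIIMIDVNLRDGNAPHLEVGMTAIFMIGGGTAGFTHKRVIARGGFTLSRP
ILTKKRKTPCGMGVKMRGIQKRVLKTNLFPIFVTEMDDWNTRAMTMASLMMGLMMMYNET
IVVEIPIEPQARHKSLLFPAWYQTGLTSVNLTTVLFDERSFQQVILTFIIATMAGYPIAL
ESRIPMGEILLRNTMGAMLGALDNLNRLMMPTNKYKYHYFGKLTLNL
>MT-ND3 synthetic mtDNA-encoded protein stand-in
CTICMAMRFVLIIAFNCKPIGGTPPWDLPGMEVVTHTAQFCGQCGAAMIKTMACKRLMYI
YLLELNLVGAGVTGLESAYRDAEWSRRMNPAMCVLKPQISAGHASMTMGNTSPAV
>MT-ND4 synthetic mtDNA-encoded protein stand-in
MFAHHMFGFPYMIWMAECTAVVMMTHNVAHLVSTRPWMTPFGSADFIKGETTNVFTRALL
WVAEYMVPCIGPMNLEWSGGYHIAKTREYCMIMMKLTNATYFMGFLGGTLMKGRRLLGRP
VWIKVGYAARLVRVPQPFQAYLGFRQRGAHGKGYAATEARVLMIMHCVLFVYYLEQLGTV
SDEEWVQVLYQAPLFFMAATGANGEVPPNCTMTVALPLKTGWIFMIMKITMIYAKMLKVG
PLAKFIERMMTMITMCLKYLEELHADKYFAVMKALFPWVTIFEFVIEMKKRMPREGNLIS
FHGRLGNKIKGRSRARNFVILADMQMKCMWFTFVYLFAFATIRGAQYMDFHLFKAGVKFM
GYEMLRFWMNGMQKAVYVVDCAMQSIRANNYPRRMINCNDLTGTGGIKCDFHTTQVIFCN
GDPMDALTILTFNIALNHPVTNRCMVMALIINYPAVDMI
>MT-ND4L synthetic mtDNA-encoded protein stand-in
APQRTGNQTCSGMTTVMHKNTVMIVMDFFSLMPAIMKMIDKFSSMIPANAVDLTEYMVTP
AENLELIKVAARFAQICMEIPAVGRVVGINTPTGITLV
>MT-ND5 synthetic mtDNA-encoded protein stand-in
TPARMAKTRTLDTQMTIELPMWFRMTVNMFITVLLLMVKKYNTTFPIDTELVQRVGTYFV
MFDVEEINMMIGNHSLVEQVNDATINLTVMGYVLLNTGLNVTKENAYYNGGECLRGAGCQ
PFLYINNMFMPTAFWSWKYIVNAFGEMPADKTLAPPNIGSHAESMPTRPQMKFVAKFNFA
ADYVGPATFVKVLMVLGAYFIEDAAFLIEEVSMLNPVDFGMVLCKAAFGCTVRNPYQQQH
VLAPIMGVVMGWNNFGVTAGMYMTDPHYCLMSKLYRIMMCYMAADFHSSWQILEFNYGIA
TYYLGVIVSAIVAMPLMAFRGLPMMAALFFWSTDFRIIMLPWMRVNAVYTMNLGTGMRSK
ARCIVAQRNTVWFSMIPLEMRIILDQGEATWMVAKTVVTAVRSGMKAFANAGLFLMAPTL
MEELGWLHALYMMMMEPLREYYAIIVLGFYYMITLNPLITYMFSTEFLPRMYQMAREVFM
YEMEPESTTPTQMTTMPNLEMTTFIHQLALGRMTLLLFANQPPDEPNTSVPTMRMTPYQM
AGRMSLMYLYYADRVCEADRTLKLQFLFLAYAAHTINSAMKAAVGGYAMTMAYRHEAGFT
KSC
>MT-ND6 synthetic mtDNA-encoded protein stand-in
LLGAMLADPPTIWQKIILVLNGAWLMVPCVGDEVTAGLRERVDNTRTCIMHSRNLLLKSG
KMIMQVINIYTSGHYVSNYGEMWDMPYFGFLMEKTAMRWHHNALNTFPPAYKYKGLVCMV
LLPLVEAPLMDWKTRYAFTALSKPDTAQVMVSNVLKYGVVMSIMPYKLYTKIAI
>MT-CO1 synthetic mtDNA-encoded protein stand-in
MYVTAGVVRMFLELLKLVDIEMIWVAGRALLCWYTYIMVMNRTDKLNMIYMRFKRYGKWH
GYKVYFMVFTAFHRTSLTEPQVNIMLAFIMVTLRMMGGRLNLEGYTDHIDAPFFVGFAFV
KIFVREKILYAMAMCKPGVVLKSCMPYELVPAFIWRTYLLGPTVMYMMFLMIWMASVYLI
IHMMMPIFSAVLINTGNMVKIAYVKNTVFNCVGKPMTMKTNLVGMCAHIGPGPATMSMTA
NTRAGYCSFVPIFSGLRTKALEMARAEVPFDNHIMVYAMSVVQFVKALICRYMRSYAPSM
WRLPKGYMVVIGIGIDKINPMGVLNTLYMTEMRLVRNIPDINDGNRLPVIMMRAILINMY
IRRRGGNPYVVSSGKTRRLTHYFQRKAEMFTIGTFMVRGVHNGLMMRTWYAMRVYIAYLY
LLWMMMATMMSRIFVPAKMGEEGNHAGPVREAPKPTIARPDKRIMMDKMFLMGVKKQFFM
MAMFPMSNIYVGISMMQMQGKRQRIWKSVVPLG
>MT-CO2 synthetic mtDNA-encoded protein stand-in
MTNLKLNFIGQETEDAVVLITQKRIVMHPEMYVVMYYRGLMMLMGKAWGVMNMVARMIQT
RVMTNVHILHFLPKVITRVPPARFLHLAYMRTLIGLDRCHYFTRARLYPGGFLGKPDTLT
WAQIWPMYFCEKISSMEMLRTFPMTPRMVMMGCNIYYEADMMKVYYAYANVPELNHIAFL
DILIIDWMCMIRPPIYEMAVPVYLMSPKVYGFNFKVTAMMWYFFIFM
>MT-CO3 synthetic mtDNA-encoded protein stand-in
CYLTVTIMADNPFIFFDHMPMIFANFETVTLLPVSAMTILLVVRPLVDRYAYCYMRFKNF
GVAEGFYLRMNMMGCDYFLYCNFVMVCAEIVFILSLMSWMLGFVTKQAMNPGAWAAGPWI
PGHMYLWEANQKWKRAIMAEEIMVNSAMLVGLGMNGRRWKMHPATRYLLGMVIAKIEKDN
LYTMGAQWGSLPPNCIATTPIGLGHKNMALCLTKVILNMNWVEVDLTRVAKLYFYKFPPG
TMFVYKQRDKRAFNFTPGLSD
>MT-ATP6 synthetic mtDNA-encoded protein stand-in
APDPGVVMMLSLCSEQIRFMKKFEKVAYNMTYAGTNIFVLPAYMYVTCGAYKVRFTAMEV
RLIEAVMLGRTGQRYDMCASKSNFCMRNFICYTAYIFLNPVVRMVIMLIENGHSNVTEAL
RVSTMIAMPVTVYFRLLFRTQKGLMGGRKRDYKWSDSPIGRPYLTWPVYVLSACVVTRLL
VARGVYGVSAIATMAWAQGNLCHLKLEYPGIMAVAFVGSLMMDMLR
>MT-ATP8 synthetic mtDNA-encoded protein stand-in
MPPYPMHITAAPFSMTVCLYMKVRFIMTGTQRQVFSENLAEVMVAMKNCEVRLKMSESIY
LLTMMVMW
>MT-CYB synthetic mtDNA-encoded protein stand-in
NALVRFSMLVRFMADLVPGIQNRKHMLTAPSSNFGRTLMMSMLVFRMAMETATVMPMLRM
KANVGVSRFITFWYTNTTWFLFLPPAVGVTKMYLDMQYKRHPVNYVAKVVMCAREILDAE
ALTRMFRFNRLSCKMADPALNFSYDLIKGMALKVGRNAKMHEIFMALNAIRFDRNLTKYE
TLIFSVVLFNVLNTELMMYATAQLIIYIPLNLNCMFVLAAFMVCFIMLDPTMHKKRLYVI
DKLQYNIRAIKYKEIESMAKLNMLPYMLMRHAKAALMTPFQRTAYHTCMFKQTKFVVNMG
AMFIPRWMGPTIDLMTMVANGTCLYRKDMMDMKLTLPRFFEDFIMCKVYEIYDKGRMNMR
AMLETCRNGWIRPRLANIAV
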