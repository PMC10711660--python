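>BmGtsf1L
MDDPFVSCPYNPIHRVPRSRLQRHIVKCEWINPTMIACPYNATHRYTQED
MKFHVLNCPSKTSIFPIEKPPKTVASITTPKIILQKEYLPETDPNHEIWDD
>BmVreteno
MSNHSRPQRRREWDPMRDDFNEHTYDVQYADDNAGEQVQLDHTKLYIINI
PRGLSEDGIRAAFSKHGKVLSARLSKNPNKRFAIVQFETASEAKLAMMKM
NGSEPLNLKISIAHKTIRKTQHDNKDRNYSTSRNGHCSRDEASSISSKGW
NMRNLDDVMNNDEIDEIDDMIHEDHDDNLDLELDMLTLKQLKIKEEQLMC
KRRLLLRHAEKRQVAPHSSAGRSVLPDGRIVVRNNANETDSAEVEPSFAG
AGSESLKTPGLERNASRQCVKCGAPADWYCSRCAITPYCSQTCQTRDWTE
RHKSVCHYLAPLKTAGGFEAEATSSKSVSNSTPMRSSHSPPTKQQRGEAD
ETDNKAKNIQEPRQNYHRPSNSGPNKNIPGKNQDPRRPATSREAIEEETE
ERGARNPKPAEATKDKHHPMNPVTFQRRQLKSNPVVDAQPAPREQQQPAA
TRAPEASPTEQRESTRRTLVPDRCLIDSLSEGDVVLVSVELKASECCTKQ
GGYVCLSMHEKYESDYQKLCEDYVLDCEADSDEYKIITGDTFSYLSPEDG
GWYRARALNTTMAALLDGSKVVYLRMNDKVKKLPAKYSGIPEFCCVLNAD
VEVGLNLKCSLLSKTPNGFKVTLENVETEANVGEGEITRWIPEVDYPPPV
KNVPVQRSVEIPEVPRPEIKNKSRVILVDATDVQRVFVRPADTRSQKAFD
NILQDVLLYGTTAEPLKEPPSKGQTVVSKYTDNLHYRALCKRTSVNKNKY
LLEYIEYGNIEITQLNRLYPCPEHLSVTSLASLTSHVQLDTTVGELTPRA
LEYIETIKEEEMILTLSSGGDTAQSGAALVNLTLVKNNDNVNKRIEELCT
PEWKKLELKGVDVIETERLMYGTALDYIELPAAPFDLQVLDEVGLDSGNI
SGCPTNSDYVRYVMTKLPARMREYCESEFGRQPYLPAAEELCIAQLPPSS
EWHRAVVLEQILGPGGGTARVLFVDHGNVAEVPVSSLRKMLAEFVTDLPA
VACQIVIEDFPKQATAEMLAKARRFMSGPDKARAAQLPVRGCDKQDVGIY
AIRVPELLEAMTE
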