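family	entry_id	signal	propeptide	mature_core	amid_tails
A	A1	MYNQYHQHEIVIVIVIVLLGEA		QHQQDDECKMWECNKCCTSNKHTCFVPFCAACTLYYWCMLKCTFDQAGCIYI	
B	B1	MYEYNKIVIVIVIVLQAQA		EEDNNNNCQLEHCHEFCCHDTMCQGQHVWCCDKCYISCGHAMFCFW	
B	B2	MYEHHKWIVIVIVIVWLALA		DQDEEHHCMMFDSCHAHCCNTFHCNDPNCCGMLEICASDGFCNDCSFH	
C	C1	MKKWYQHIVIVIVIVWLANA		EEQEEHECHSGCWNYCFDECTSGCTMDHMCCMKMSQGCAEMGCWNCGWCVMDWDCQN	
C	C2	MHEEWYIVIVIVIVFVGEA		NKQQHEHCYPCFSYPCAFIGFCYTPVKCYIPDGCYHIGLCPGEDIVCWGTATCQASCAIA	
C	C3	MQKYYWYKIVIVIVIVLLAEA		QQHDKNNCDKTLCFQQCYMMDCESDHCWPPIPHCDHCLSCKTMNCLKICWVLMDGCHLCWMQSM	
D	D1	MQQEEEEYEYIVIVIVIVFLAQS	HDHHHDKNQPEPEEAR	SFWHTCQYCVDCCIMCELCPEWAP	
D	D2	MEEYWIVIVIVIVLLSQS	NDDHHKENIIQVVESEER	DAIFCDMQMLCLMGWCCEEDLIQCPECHPCEEKWYKCQNIAF	
E	E1	MKQYKKKHIVIVIVIVFVGLA	EDNQQHHEAWMHSEER	FMHCLLGCKIECCYYYCDEQYAHCWGEASDCSNTPCWH	G
E	E2	MKKEEENNWIVIVIVIVWLTQA	HHEKEDHKIKLAEEPR	KDIPECWYSTMDCPPAPPCCKYNLYECFYCYICKGGVSSCNSSPS	G
E	E3	MKNYKWWWYHIVIVIVIVFLSLS		HNDQDHKDCGIALCSAGCCNLMCAQYCTGCMPLPQCKW	G
F	F1	MWNYQWEWWIVIVIVIVWLTLS	DHNDQKHQMIEMIFEAER	NHGVQCKLSCITDEWWCCITACFVAYCIITEALCQIDCMP	G
F	F2	MHNNKYQWIVIVIVIVWVGLA	QEHDQKKELMNEAER	DICWGNYMWCSHVCCTPCQLGFGMCAKCNGCDIIH	G
F	F3	MQNHNKYKQEIVIVIVIVFQALS	KNNNDDKNWDFESPR	SFFVSCAPKNHCGECCEHELMCYYVNNWCNKGTFGCSTWLLCHMMT	
G	G1	MEKNHHIVIVIVIVWLSLS		DHNKKHCATPIPGCMFQCCWINFIQCNWFHCSTLPCFPMGIFCKDDPW	
G	G2	MKHKQIVIVIVIVFQSLS		QQNDHDCWFWCKKYDCCDFPNCHLAVTCYAECVTGQHCAFT	
G	G3	MNWYWKYYIVIVIVIVWVAQS	EQEDNQENVWEEAR	ILFQCATKGNYCYDHKPCCVIVNPICSYCILEICMVGCWW	
G	G4	MENQQYHKIVIVIVIVWVTES		DQKKDHDNCGYNQPCGYDIFCCWKTVVCYITGYDCTPCGDTFEQCQLM	
H	H1	MHNEENYIVIVIVIVFLSLA		HEQQKQQCGDNPVYCSWYFPPCCAYTLCSESCAQVHTCDKKKLCQTCMILQS	
H	H2	MNNYENEIVIVIVIVLVSLS	EHENNNEQEAER	DIMPCNVEWCPEPKMLCIDVNAYCCKYKDHSCIFMCNFHCQSPECAIPYLACIN	
H	H3	MEEQQEHYQNIVIVIVIVFLGLS	NHQQENEENSEER	AQKWCTPWIMFCPEMCMDKCCEQILCVQPSPWCDPCLATCYLTFQCYMALHSCIKCEVPHE	G
I	I1	MNHWEEWQHWIVIVIVIVWVGNA	QEEDKHEKATEEAR	PDCQLYTCAWLEDCGWKYCCDTCSMDGFDCKSAIDGCMSWHCQSCDGCLYVFCIWHCNEEVGMCAL	G
J	J1	MQWWKWKWIVIVIVIVFQANA	EHDDHKKDPNYESPR	GVHCLPHIDCKETICYQCQVICYETHCVSNACDTWSFPCEYFVD	G,GK,GGK
J	J2	MKQYNYKIVIVIVIVFLTLS	EDEEDQQNESPR	YICADAHCYGCCSGIANGCSWCKMYCMYLKCIET	G,GK
K	K1	MKYHNEYYIVIVIVIVFVTES		KQDQDNCSNHCDTDM	
K	K2	MHKNWYQIVIVIVIVFQANA		HNNQNECIPNCAECAIQPSMCVVWSF	
K	K3	MYWYNYQKIVIVIVIVWLTLS		ENEDDKNDCWNFCHLICTDCKIDCASICCLNCHVD	
K	K4	MHEWQEYHEKIVIVIVIVFVSLS		HNKHDDQDCSPLTEQCGIGSCCTSWTHWCQMCMYLCAMYWGCLMGMSCVPNYCPKPQ	
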