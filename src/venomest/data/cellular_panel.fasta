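>actin-like-1 synthetic housekeeping-like exemplar
MPHMDYWIDKAWCWPFHTYSIYHGMGFILFQQPEIVSCWNCVALMCMASQRCINPDGGEA
FGQWHWNTNCHGWAGDGHCVITTGKYPGYAFLVVIPWTQGRYCTSFVNFAPDLYFPYVWY
FGCKFSAECSPI
>tubulin-like-1 synthetic housekeeping-like exemplar
MKQEDYLNMQNEGCEFAFRQYSMLEEGQDNQYLRHKENVWRALFLLPERQNDNDDVSSFY
ITTWELEFHDYAHESHADINTWQKQSDIEQEFGEKYKEFVKQPPVWPCYDNIMLLVKCLD
GHTSYSQHMDIWKDGIWHGYSACCHTAKTMKVIRFESKWVKCKNAYWQAKLTPNLVWEKY
DAWLGPCLPAYPY
>ribosomal-like-L7 synthetic housekeeping-like exemplar
MQTPQDGFMPTSEERNYKWELTITDYKSAPPNEYYASLGNQWKTKKHVHNFYMHRHDAIC
VVSRVWTKVEHEDWQFKHFNAGWHEIIAYPHNKHSLICLSETEPPYVNAAHCHNRYHNFV
LYKSAGMWISGGWPLACKVHMQTQNWNNSCMLFWMSWTLQFDSPALARCGRVCISMDTDS
EGDPDEII
>ef1a-like synthetic housekeeping-like exemplar
MYVKKCWLIPRNQMSNCSQTSFREKTMGKFCAIGTLGDWYVTIKDRVHGDEQPPATGSYF
SNQTHPITSYNVPVAVHSHRLAEKIFHFFQTASCFEGAYAYTLTYYMTLYKIMEQGFDIC
SRSCEKSHCVIQEDGNFEDWTFFRWVIGYH
>hsp70-like synthetic housekeeping-like exemplar
MLAQRMVYAHIDHWDYKWMDQRGLEQKWFWRSAMWRQGPMQWHDAHIPVGFRYEHLFLGQ
CTLEVAFPVPMSVQSFYIAWESGPCEFQHSNKISGGMARLMSFGFDAILVWCVGDFQADS
EKNWHASNGNMNCEMY
>atp-synthase-like synthetic housekeeping-like exemplar
MKCYLMNCNENAASPCDNQASKSTYDGRNPQHTWVQMNSYVCIIWAPFALTYNWNTWKYF
RMRVDRIQLDKPYPTPEDMGHADWKFQMGGMPMPFCSAENVLFSCKKEQYVSTQDSPWGH
PSADYKEHHHY
>ferritin-like synthetic housekeeping-like exemplar
MDGITYTMYLQWCVPSGQYTLSVWGAYLTTNLQWFTNVEDAEHSVWQLMLRHQPQCISQA
PKDFGCNHFLCIGKMNWHWPGNESKTTIMMHYKPSDTARALTFTTMDEVYTHYKTLCHGQ
AVVQYTYPVCNAQRFIIQEPRIDATTEYHFHMPDFCYQEAPVRGMATIFLHFANPIFKYH
KW
>cytc-oxidase-like synthetic housekeeping-like exemplar
MHCHDHYHTPHFSVPDAYPGNQWLLVWFYFVPQVTDFCVTEIVIQWRGCCWGDKRQQTQD
EWEPFNPAYNLQEDMWYQWHYTIIGINYDVTMEFVFLSMHEHHWFDWTNMNNQYCPPHRR
MYNCTQSKNVNMSNAKEVYIKYTGIVNGHFVQKHYSLMHWDTDFA
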