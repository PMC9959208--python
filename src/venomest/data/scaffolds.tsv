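motif	n_cys	adjacency	pairs	description
ICK6	6	3	1-4,2-5,3-6	inhibitor cystine knot, 6 cysteines; C3-C6 threads the C1-C4/C2-C5 ring
ICK8	8	3	1-4,2-5,3-8,6-7	ICK with a fourth stabilising bond C6-C7
FamA10	10	3	1-4,2-5,3-7,6-9,8-10	10-cysteine scaffold assigned by similarity to U31-ctenitoxin-like frameworks
FamI14	14	4	1-5,2-6,3-10,4-9,7-8,11-12,13-14	14-cysteine scaffold assigned by similarity to omega-ctenitoxin-like frameworks
FamJ8	8		1-4,2-8,3-7,5-6	8-cysteine non-adjacent scaffold assigned by similarity to U2-lycotoxin-like frameworks
DDH	6		1-3,2-5,4-6	disulfide-directed hairpin
Kunitz	6		1-6,2-4,3-5	Kunitz protease-inhibitor fold
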