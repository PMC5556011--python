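gene	fpkm_control	fpkm_tsc	log2_fold_change	p_adj	direction
PLA2G2A	0.2128	10.6491	5.6454	0.0044	over
PRPH	0.8807	35.6832	5.3404	0.0044	over
C21orf62	0.3509	13.9016	5.3081	0.0044	over
CCL4	1.6944	58.3646	5.1063	0.0044	over
CCL4L1	2.7548	69.1906	4.6505	0.0044	over
LTF	2.0545	50.5365	4.6204	0.0044	over
CCL3	2.5844	58.6895	4.5052	0.0110	over
SLC47A2	0.1928	4.2615	4.4660	0.0044	over
CHI3L2	7.0674	152.6110	4.4325	0.0044	over
CCL3L3	1.9783	39.4745	4.3186	0.0044	over
HEATR6	892.7690	5.4155	-7.3650	0.0044	under
SLC30A2	2.8143	0.0575	-5.6137	0.0159	under
SLC22A8	2.8123	0.0609	-5.5293	0.0044	under
IL1RL1	19.0343	0.7561	-4.6539	0.0044	under
HSPA6	68.4820	2.9318	-4.5459	0.0324	under
SERPIND1	2.6156	0.1329	-4.2992	0.0159	under
SLC13A4	9.6643	0.6905	-3.8069	0.0044	under
SLC5A5	1.0909	0.0895	-3.6078	0.0044	under
DCX	10.8126	1.1125	-3.2808	0.0044	under
ST8SIA2	3.7169	0.5488	-2.7598	0.0044	under
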