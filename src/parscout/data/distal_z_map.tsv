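# Best-order genetic map of the distal Z chromosome of the collared flycatcher,
# cumulative map positions in cM (sex-averaged, female, male).  Female
# recombination is confined to the three terminal pseudoautosomal scaffolds
# N00298, N00378 and N02597.
marker	cum_sexavg	cum_female	cum_male
N00298:53720	0	0	0
N00298:169577	0	0	0
N00298:235485	1.3	6.6	0
N00378:45469	4.4	6.6	1.5
N00378:115359	7.9	14.1	1.5
N00378:154206	17.1	44.9	2.6
N02597:626	31.1	64.3	7.3
N00781:8697	31.1	64.3	7.3
N00497:36583	31.6	64.3	9.5
N00058:5243596	32.4	64.3	11.4
N00058:5170038	33.0	64.3	12.8
N00058:5137590	33.3	64.3	13.6
N00058:5074792	33.7	64.3	14.4
N00058:4983582	34.5	64.3	16.0
N00058:4856163	34.8	64.3	16.6
N00058:4693005	35.0	64.3	17.2
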