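# Scaffolds of the distal collared flycatcher Z chromosome, in chromosome
# order.  Lengths in bp where published (the three PAR scaffolds and N00058);
# empty where unknown.  The assembly gap between consecutive scaffolds is
# conventionally padded with 5 kb.
scaffold	length	role
N00298	436000	PAR
N00378	182200	PAR
N02597	2300	PAR
N00781		Z_diff
N00497		Z_diff
N00058	5300000	Z_diff
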