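# Synthetic stand-in for the 24-residue GTP/GDP-binding region of RALA
# (206 aa). The authoritative residue set is not machine-readable from
# published material, so downstream statistics accept a user-supplied
# residue list; this file exists only so the pipeline runs end-to-end.
# It was constructed from the canonical small-GTPase G-box motifs mapped
# onto RALA numbering and includes the five disease-variant residues
# (25, 128, 130, 157, 158). 24 residues, one 1-based index per line.
21
22
23
24
25
26
27
28
45
46
47
68
69
70
71
127
128
129
130
156
157
158
159
160
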