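gene	residue	phenotype	citation
KRAS	14	Noonan syndrome	germline missense reports in four unrelated individuals
HRAS	117	Costello syndrome	germline missense reports in two unrelated probands
HRAS	146	Costello syndrome	germline missense reports in at least three patients; recurrent somatic variant in colorectal cancer
ARF1	127	brain malformations with developmental delay	de novo missense report (K127E)
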