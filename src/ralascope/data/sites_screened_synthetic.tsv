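# Synthetic split of the 16,086 screened trio probands across sequencing
# sites. Only the total (16,086 probands = 32,172 alleles) is published;
# the per-site counts below are an invented partition for testing, and
# SiteC is marked outside the screened-trio denominator (a diagnostic-
# setting site without a trio cohort of >= 400).
site	n_probands	in_denominator
SiteA	1500	yes
SiteB	900	yes
SiteC	0	no
SiteD	1200	yes
SiteE	5000	yes
SiteF	7486	yes
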