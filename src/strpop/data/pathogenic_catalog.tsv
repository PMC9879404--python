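# Known disease-associated STR expansion loci (hg19, 1-based).
# pathogenic_length_bp: published allele length above which the expansion is disease-associated.
gene	chrom	pos	repeat_unit	ref_len_bp	pathogenic_length_bp
RFC1	4	39350045	AAAG	44	4000
DIP2B	12	50898785	GGC	21	600
TCF4	18	53253385	CTG	75	150
DMPK	19	46273463	CTG	60	150
ATXN10	22	46191235	ATTCT	70	4000
AR	X	66765160	GCA	66	114
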