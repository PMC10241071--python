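# Explicit diplotype -> phenotype maps for genes whose phenotype vocabulary is a
# function label rather than a metabolizer class (drug targets, transporters and
# CYP4F2, whose *4 allele has unknown function). Pairs are unordered; alleles are
# given in a canonical sorted order. Genes absent from this table use either the
# activity-score bins (CYP2D6) or the generic function-pair rules.
gene	allele1	allele2	phenotype
VKORC1	*1	*1	Normal function
VKORC1	*1	T	Possible decreased function
VKORC1	T	T	Decreased function
ABCG2	*1	*1	Normal function
ABCG2	*1	T	Decreased function
ABCG2	T	T	Poor function
IFNL3	*1	*1	Favorable response
IFNL3	*1	T	Unfavorable response
IFNL3	T	T	Unfavorable response
CYP4F2	*1	*1	Normal function
CYP4F2	*1	*3	Possible decreased function
CYP4F2	*3	*3	Decreased function
CYP4F2	*1	*4	Indeterminate
CYP4F2	*3	*4	Indeterminate
CYP4F2	*4	*4	Indeterminate
SLCO1B1	*1	*1	Normal function
SLCO1B1	*1	*1B	Possible normal function
SLCO1B1	*1B	*1B	Possible normal function
SLCO1B1	*1	*20	Increased function
SLCO1B1	*1B	*20	Increased function
SLCO1B1	*20	*20	Increased function
SLCO1B1	*1	*15	Possible decreased function
SLCO1B1	*15	*1B	Possible decreased function
SLCO1B1	*15	*15	Poor function
SLCO1B1	*15	*20	Indeterminate
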