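# Bundled star-allele definition table for 19 pharmacogenes (one row per defining
# variant; reference and whole-gene-deletion alleles have a single row with empty
# variant columns). Synthetic curation: a deliberately small, unambiguous subset of
# the public PharmVar/CPIC definitions, restricted to the alleles that segregate in
# the founder-cohort simulator. Columns: gene, allele, chrom, pos (1-based GRCh38),
# ref, alt, function (Normal/Decreased/No/Increased/Unknown/Possible decreased),
# activity (per-allele activity value, NA = unknown), is_deletion, frequency
# (bundled population frequency used for simulator defaults and tie-breaking).
gene	allele	chrom	pos	ref	alt	function	activity	is_deletion	frequency
CYP2D6	*1					Normal	1.0	0	0.667
CYP2D6	*2	22	42127941	C	T	Normal	1.0	0	0.05
CYP2D6	*131	22	42129754	G	A	Unknown	NA	0	0.043
CYP2D6	*5					No	0.0	1	0.24
CYP2C9	*1					Normal	1.0	0	0.58
CYP2C9	*3	10	94981296	A	C	No	0.0	0	0.42
CYP2C19	*1					Normal	1.0	0	0.38
CYP2C19	*38	10	94852785	G	A	Normal	1.0	0	0.25
CYP2C19	*2	10	94781859	G	A	No	0.0	0	0.25
CYP2C19	*3	10	94780653	G	A	No	0.0	0	0.12
CYP2B6	*1					Normal	1.0	0	0.46
CYP2B6	*5	19	41012316	C	T	Normal	1.0	0	0.04
CYP2B6	*6	19	41006936	G	T	Decreased	0.5	0	0.39
CYP2B6	*6	19	41007013	A	G	Decreased	0.5	0	0.39
CYP2B6	*9	19	41006936	G	T	Decreased	0.5	0	0.04
CYP2B6	*22	19	41016810	T	C	Increased	1.5	0	0.07
CYP3A5	*1					Normal	1.0	0	0.06
CYP3A5	*3	7	99672916	T	C	No	0.0	0	0.94
CYP4F2	*1					Normal	1.0	0	0.24
CYP4F2	*3	19	15879621	C	T	Decreased	NA	0	0.36
CYP4F2	*4	19	15878023	A	C	Unknown	NA	0	0.40
CYP4F2	*4	19	15879621	C	T	Unknown	NA	0	0.40
VKORC1	*1					Normal	NA	0	0.90
VKORC1	T	16	31096368	C	T	Decreased	NA	0	0.10
NUDT15	*1					Normal	1.0	0	0.95
NUDT15	*3	13	48045719	C	T	No	0.0	0	0.05
UGT1A1	*1					Normal	1.0	0	0.95
UGT1A1	*6	2	233760498	G	A	Decreased	0.5	0	0.03
UGT1A1	*80+*28	2	233759924	C	T	Decreased	0.5	0	0.02
ABCG2	*1					Normal	NA	0	0.97
ABCG2	T	4	88131171	G	T	Decreased	NA	0	0.03
SLCO1B1	*1					Normal	1.0	0	0.65
SLCO1B1	*1B	12	21176804	A	G	Normal	1.0	0	0.22
SLCO1B1	*15	12	21176804	A	G	Decreased	0.5	0	0.02
SLCO1B1	*15	12	21178615	T	C	Decreased	0.5	0	0.02
SLCO1B1	*20	12	21128222	G	A	Increased	1.5	0	0.11
IFNL3	*1					Normal	NA	0	0.89
IFNL3	T	19	39248147	C	T	Decreased	NA	0	0.11
CFTR	*1					Normal	1.0	0	1.0
RYR1	*1					Normal	1.0	0	1.0
CACNA1S	*1					Normal	1.0	0	1.0
TPMT	*1					Normal	1.0	0	1.0
DPYD	*1					Normal	1.0	0	0.9988
DPYD	HapB3	1	97573863	G	A	Decreased	0.5	0	0.0012
CYP2C8	*1					Normal	1.0	0	0.999
CYP2C8	*3	10	95038992	T	C	Decreased	0.5	0	0.001
G6PD	*1					Normal	1.0	0	0.989
G6PD	A-	X	154536002	C	T	No	0.0	0	0.011
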