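# Default clinical-actionability rules: one row per gene-phenotype pair that carries
# a non-default prescribing recommendation in CPIC/DPWG guidance. The short tag is a
# machine-readable summary, not clinical text. CYP3A5 poor metabolizers (nonexpressers)
# receive the standard tacrolimus starting dose and default to non-actionable; this is
# exposed as a switch in count_actionable because guideline readings differ.
gene	phenotype	actionable	tag
CYP2D6	IM	1	reduce_dose_or_alternative
CYP2D6	PM	1	reduce_dose_or_alternative
CYP2D6	UM	1	alternative_drug
CYP2C9	IM	1	reduce_dose_monitor
CYP2C9	PM	1	reduce_dose_monitor
CYP2C19	IM	1	alternative_antiplatelet
CYP2C19	PM	1	alternative_antiplatelet
CYP2C19	RM	1	dose_adjust_ppi
CYP2C19	UM	1	dose_adjust_ppi
CYP2B6	IM	1	reduce_efavirenz_dose
CYP2B6	PM	1	reduce_efavirenz_dose
CYP3A5	NM	1	increase_tacrolimus_dose
CYP3A5	IM	1	increase_tacrolimus_dose
CYP3A5	PM	0	standard_dose
NUDT15	IM	1	reduce_thiopurine_dose
NUDT15	PM	1	reduce_or_alternative_thiopurine
UGT1A1	PM	1	alternative_atazanavir
VKORC1	Decreased function	1	reduce_warfarin_dose
CYP4F2	Decreased function	1	increase_warfarin_dose
ABCG2	Decreased function	1	adjust_statin_allopurinol
ABCG2	Poor function	1	adjust_statin_allopurinol
SLCO1B1	Decreased function	1	reduce_statin_dose
SLCO1B1	Poor function	1	reduce_statin_or_alternative
SLCO1B1	Increased function	1	adjust_statin_dose
IFNL3	Unfavorable response	1	weigh_peginterferon_benefit
DPYD	IM	1	reduce_fluoropyrimidine_dose
DPYD	PM	1	avoid_fluoropyrimidine
TPMT	IM	1	reduce_thiopurine_dose
TPMT	PM	1	reduce_or_alternative_thiopurine
CYP2C8	IM	1	monitor_response
CYP2C8	PM	1	adjust_dose
G6PD	IM	1	caution_oxidative_drugs
G6PD	PM	1	avoid_oxidative_drugs
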