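# 21-modifier reference table, reconstructed from the published per-protein
# results of the ataxin-1 fragment overexpression screen.  Class memberships
# (toxicity/aggregation quadrants, ATXN3 cross-reactivity, coiled-coil and
# Q-rich/polyQ flags) follow the published counts; gene ids not named per
# quadrant in the text are SYNTHETIC placeholders (ENH*/SUP*).
# toxicity_class/aggregation_class: enhancer | suppressor | none
modifier	toxicity_class	aggregation_class	atxn3_modifier	has_cc	q_rich	polyq
ATP6V1E	enhancer	enhancer	0	1	0	0
MED15	enhancer	enhancer	0	1	1	1
NAPA	enhancer	enhancer	0	1	0	0
ATP5F1	enhancer	enhancer	0	1	0	0
PSMD7	enhancer	enhancer	0	1	0	0
VPS4B	enhancer	enhancer	1	1	0	0
RAN	enhancer	enhancer	1	0	0	0
RPLP0	enhancer	enhancer	1	0	0	0
C16orf70	enhancer	enhancer	0	0	0	0
ENH10	enhancer	none	0	0	0	0
ENH11	enhancer	none	0	0	0	0
ENH12	enhancer	none	0	0	0	0
PSMB6	suppressor	suppressor	0	0	0	0
SNRPB	suppressor	suppressor	0	0	0	0
PUM1	suppressor	none	0	0	1	0
EIF2G	suppressor	none	0	0	0	0
SUP17	suppressor	none	0	0	0	0
DNAJB4	suppressor	enhancer	0	0	0	0
AFG3L2	suppressor	enhancer	0	0	0	0
NEK8	suppressor	enhancer	1	0	0	0
CRK	suppressor	enhancer	0	0	0	0
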