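# ALARM: 37-node patient-monitoring network (46 arcs), literature arities
node	HISTORY	2
node	CVP	3
node	PCWP	3
node	HYPOVOLEMIA	2
node	LVEDVOLUME	3
node	LVFAILURE	2
node	STROKEVOLUME	3
node	ERRLOWOUTPUT	2
node	HRBP	3
node	HREKG	3
node	ERRCAUTER	2
node	HRSAT	3
node	INSUFFANESTH	2
node	ANAPHYLAXIS	2
node	TPR	3
node	EXPCO2	4
node	KINKEDTUBE	2
node	MINVOL	4
node	FIO2	2
node	PVSAT	3
node	SAO2	3
node	PAP	3
node	PULMEMBOLUS	2
node	SHUNT	2
node	INTUBATION	3
node	PRESS	4
node	DISCONNECT	2
node	MINVOLSET	3
node	VENTMACH	4
node	VENTTUBE	4
node	VENTLUNG	4
node	VENTALV	4
node	ARTCO2	3
node	CATECHOL	2
node	HR	3
node	CO	3
node	BP	3
arc	LVFAILURE	HISTORY
arc	LVEDVOLUME	CVP
arc	LVEDVOLUME	PCWP
arc	HYPOVOLEMIA	LVEDVOLUME
arc	LVFAILURE	LVEDVOLUME
arc	HYPOVOLEMIA	STROKEVOLUME
arc	LVFAILURE	STROKEVOLUME
arc	ERRLOWOUTPUT	HRBP
arc	HR	HRBP
arc	ERRCAUTER	HREKG
arc	HR	HREKG
arc	ERRCAUTER	HRSAT
arc	HR	HRSAT
arc	ANAPHYLAXIS	TPR
arc	ARTCO2	EXPCO2
arc	VENTLUNG	EXPCO2
arc	INTUBATION	MINVOL
arc	VENTLUNG	MINVOL
arc	FIO2	PVSAT
arc	VENTALV	PVSAT
arc	PVSAT	SAO2
arc	SHUNT	SAO2
arc	PULMEMBOLUS	PAP
arc	PULMEMBOLUS	SHUNT
arc	INTUBATION	SHUNT
arc	INTUBATION	PRESS
arc	KINKEDTUBE	PRESS
arc	VENTTUBE	PRESS
arc	MINVOLSET	VENTMACH
arc	DISCONNECT	VENTTUBE
arc	VENTMACH	VENTTUBE
arc	INTUBATION	VENTLUNG
arc	KINKEDTUBE	VENTLUNG
arc	VENTTUBE	VENTLUNG
arc	INTUBATION	VENTALV
arc	VENTLUNG	VENTALV
arc	VENTALV	ARTCO2
arc	ARTCO2	CATECHOL
arc	INSUFFANESTH	CATECHOL
arc	SAO2	CATECHOL
arc	TPR	CATECHOL
arc	CATECHOL	HR
arc	HR	CO
arc	STROKEVOLUME	CO
arc	CO	BP
arc	TPR	BP
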