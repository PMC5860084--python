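induce	VC_CAUSE
cause	VC_CAUSE
trigger	VC_CAUSE
promote	VC_CAUSE
stimulate	VC_CAUSE
enhance	VC_CAUSE
inhibit	VC_SUPPRESS
suppress	VC_SUPPRESS
block	VC_SUPPRESS
prevent	VC_SUPPRESS
attenuate	VC_SUPPRESS
reduce	VC_SUPPRESS
activate	VC_ACTIVATE
upregulate	VC_ACTIVATE
overexpress	VC_ACTIVATE
phosphorylate	VC_ACTIVATE
downregulate	VC_DEACTIVATE
silence	VC_DEACTIVATE
degrade	VC_DEACTIVATE
observe	VC_REPORT
show	VC_REPORT
demonstrate	VC_REPORT
indicate	VC_REPORT
suggest	VC_REPORT
report	VC_REPORT
measure	VC_EXPERIMENT
treat	VC_EXPERIMENT
incubate	VC_EXPERIMENT
transfect	VC_EXPERIMENT
expose	VC_EXPERIMENT
migrate	VC_PROGRESS
invade	VC_PROGRESS
metastasize	VC_PROGRESS
proliferate	VC_PROGRESS
differentiate	VC_PROGRESS
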