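# Chains predicted to be common in mammalian membrane glycerophospholipids,
# used by the best-prediction search filter.  Editable: one "linkage c:u"
# per line.  Default list: the prevalent mammalian fatty acyl chains
# (palmitate/palmitoleate, stearate/oleate/linoleate/linolenate,
# arachidonate, docosahexaenoate).
acyl 16:0
acyl 16:1
acyl 18:0
acyl 18:1
acyl 18:2
acyl 18:3
acyl 20:4
acyl 22:6
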