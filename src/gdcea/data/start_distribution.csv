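strategy,state,fraction
no_ert,asymptomatic,1.0
ert_base,asymptomatic,1.0
ert_historical,asymptomatic,1.0
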