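group,share,citation
children,0.34,editable default; replace with census shares for the study region
women,0.33,editable default; replace with census shares for the study region
men,0.33,editable default; replace with census shares for the study region
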