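# Seeking help in more than one facility
"another" ++ G:facility_noun
"second" ++ G:facility_noun
"referred" + G:facility_noun
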