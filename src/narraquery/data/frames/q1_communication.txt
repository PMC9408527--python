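# Language-communication difficulty frames
G:communication_noun + G:difficulty_noun
"not" ++ G:communication_verb
"no" ++ G:communication_noun
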