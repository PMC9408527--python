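# Illness or injury as the reason for the visit
G:illness_noun
"sick"
"ill"
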