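#semantic=difficulty,syntactic=noun
problem, problems, difficulty, difficulties, barrier, barriers, trouble, troubles
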