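#semantic=language and communication,syntactic=verb
speak, speaks, spoke, speaking, understand, understands, understood, explain, explains, explained, translate, translates, translated, communicate, communicates, communicated
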