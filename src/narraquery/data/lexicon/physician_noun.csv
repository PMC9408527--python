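#semantic=physician,syntactic=noun
doctor, doctors, physician, physicians, surgeon, surgeons, specialist, specialists, orthopedist, dermatologist, pediatrician
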