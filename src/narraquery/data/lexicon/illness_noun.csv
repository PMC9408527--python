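#semantic=illness or injury,syntactic=noun
illness, illnesses, fever, flu, infection, infections, injury, injuries, pain, pains, fracture, fractures, cough, allergy, allergies, accident, accidents, wound, wounds, sickness
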