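# Default query configuration: five dichotomous questions, each backed by
# an illustrative frame file.
queries:
  - id: Q1
    question: Does the text mention any difficulties in language communication?
    frames: [frames/q1_communication.txt]
  - id: Q2
    question: Does the text mention illness or injury as a reason for contact with a healthcare facility?
    frames: [frames/q2_service.txt]
  - id: Q3a
    question: Does the text mention any physicians involved in providing health services?
    frames: [frames/q3a_physicians.txt]
  - id: Q3b
    question: Does the text mention personnel other than physicians involved in providing health services?
    frames: [frames/q3b_personnel.txt]
  - id: Q4
    question: Does the text mention seeking medical help in more than one healthcare facility?
    frames: [frames/q4_facility_change.txt]
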