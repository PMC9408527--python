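#semantic=non-physician personnel,syntactic=noun
nurse, nurses, receptionist, receptionists, paramedic, paramedics, pharmacist, pharmacists, assistant, assistants, staff, attendant, attendants, technician, technicians, lady
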